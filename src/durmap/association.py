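"""Marker-trait association: GLM-Q scan, confirmation, declaration.

The scan fits, for every retained marker, a general linear model of the
response on an intercept, the population-membership proportions (Q, the
structure covariates, last column dropped to avoid rank deficiency with
the intercept) and the marker, and tests the marker with an
extra-sum-of-squares F test against the reduced model without it.

A marker becomes a declared marker-trait association (MTA) only when
the scan is significant at P < 0.0005 in at least one environment and
the association is confirmed:

* qualitative traits: Pearson chi-square of marker state x trait class
  at P < 0.01 within at least one subspecies;
* quantitative traits: simple linear regression of the per-environment
  accession values on the marker at P < 0.05 in a set of cells spanning
  more than one environment or more than one subspecies.

All thresholds are strict inequalities.  Only markers with less than 5%
missing calls enter the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MarkerDataset

SCAN_ALPHA = 0.0005
CHISQ_ALPHA = 0.01
REG_ALPHA = 0.05
MAX_MISSING = 0.05

_COLLIN_TOL = 1e-10


def association_filter(
    dataset: MarkerDataset, max_missing: float = MAX_MISSING
) -> list[str]:
    """Markers with missing fraction strictly below ``max_missing``."""
    frac = np.isnan(dataset.genotypes).mean(axis=0)
    return [mk for mk, f in zip(dataset.marker_ids, frac) if f < max_missing]


def _q_covariates(q_matrix: np.ndarray) -> np.ndarray:
    """Structure covariates: all Q columns but the last (rows sum to 1)."""
    q = np.asarray(q_matrix, dtype=float)
    return q[:, :-1] if q.shape[1] > 1 else np.empty((q.shape[0], 0))


def glm_q_scan(
    response: np.ndarray | pd.Series,
    dataset: MarkerDataset,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-marker GLM-Q F tests of *response* over the whole collection.

    *response* is aligned to ``dataset.accession_ids`` (a Series is
    reindexed; an array must already be aligned).  Returns a DataFrame
    indexed by marker with columns F, p, r2 (partial R^2 of the
    marker), n, and a status ('ok', 'monomorphic', 'collinear',
    'too_few').
    """
    if isinstance(response, pd.Series):
        y_all = response.reindex(dataset.accession_ids).to_numpy(dtype=float)
    else:
        y_all = np.asarray(response, dtype=float)
    if markers is None:
        markers = list(dataset.marker_ids)
    qcov = _q_covariates(dataset.q_matrix)
    k_pop = dataset.q_matrix.shape[1]
    mk_index = {mk: j for j, mk in enumerate(dataset.marker_ids)}

    out = []
    for mk in markers:
        x_all = dataset.genotypes[:, mk_index[mk]]
        ok = ~(np.isnan(y_all) | np.isnan(x_all))
        n = int(ok.sum())
        df2 = n - k_pop - 1
        if df2 < 1:
            out.append((mk, np.nan, np.nan, np.nan, n, "too_few"))
            continue
        y = y_all[ok]
        x = x_all[ok]
        if x.min() == x.max():
            out.append((mk, np.nan, np.nan, np.nan, n, "monomorphic"))
            continue
        X_red = np.column_stack([np.ones(n), qcov[ok]])
        coef_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
        sse_red = float(np.sum((y - X_red @ coef_r) ** 2))
        # collinearity of the marker with the structure covariates
        cx, _, _, _ = np.linalg.lstsq(X_red, x, rcond=None)
        x_resid = x - X_red @ cx
        if float(x_resid @ x_resid) < _COLLIN_TOL * float(x @ x):
            out.append((mk, np.nan, np.nan, np.nan, n, "collinear"))
            continue
        X_full = np.column_stack([X_red, x])
        coef_f, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
        sse_full = float(np.sum((y - X_full @ coef_f) ** 2))
        if sse_full <= 0:
            out.append((mk, np.inf, 0.0, 1.0, n, "ok"))
            continue
        f_stat = (sse_red - sse_full) / (sse_full / df2)
        p = float(stats.f.sf(f_stat, 1, df2))
        r2 = (sse_red - sse_full) / sse_red if sse_red > 0 else np.nan
        out.append((mk, f_stat, p, r2, n, "ok"))
    return pd.DataFrame(
        out, columns=["marker", "F", "p", "r2", "n", "status"]
    ).set_index("marker")


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni-adjusted p-value(s): min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    adj = np.minimum(1.0, np.asarray(p, dtype=float) * m)
    return float(adj) if adj.ndim == 0 else adj


def chisq_confirm(
    classes: np.ndarray | pd.Series,
    marker: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-square of marker state x trait class in a group.

    No continuity correction.  Raises when the group table is
    degenerate (a single class or a single marker state); warns when
    any expected count is below 5.
    """
    cl = np.asarray(classes, dtype=object)
    x = np.asarray(marker, dtype=float)
    if mask is not None:
        cl, x = cl[np.asarray(mask, dtype=bool)], x[np.asarray(mask, dtype=bool)]
    ok = ~np.isnan(x) & (cl != None)  # noqa: E711 - object array
    cl, x = cl[ok], x[ok]
    table = pd.crosstab(x.astype(int), cl)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (single class or state)")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5 in chi-square table", stacklevel=2)
    return float(chi2), int(dof), float(p)


def regression_confirm(
    values: np.ndarray | pd.Series, marker: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Simple linear regression of accession values on a 0/1 marker.

    Returns (slope, R^2, two-sided p).  Raises when fewer than 5
    complete accessions or the marker is monomorphic in the cell (the
    latter feeds the monomorphic-concordance bookkeeping).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(marker, dtype=float)
    if mask is not None:
        y, x = y[np.asarray(mask, dtype=bool)], x[np.asarray(mask, dtype=bool)]
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if y.size < 5:
        raise ValueError("fewer than 5 accessions in cell")
    if x.min() == x.max():
        raise ValueError("marker monomorphic in cell")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


@dataclass
class MTARecord:
    """Association evidence for one marker x trait."""

    marker: str
    trait: str
    kind: str  # 'quantitative' | 'qualitative'
    chromosome: str
    #: scan-level GLM-Q p per environment (quantitative) or per class
    #: indicator (qualitative), whole collection
    scan_p: dict = field(default_factory=dict)
    scan_r2: dict = field(default_factory=dict)
    bonferroni_p: dict = field(default_factory=dict)
    #: per-(subspecies, environment) confirmation evidence
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    declared: bool = False
    rule: str = ""
    #: per fixed subspecies: True (concordant) / False / None (n.e.)
    concordance: dict = field(default_factory=dict)

    @property
    def scan_significant(self) -> bool:
        return any(p < SCAN_ALPHA for p in self.scan_p.values() if not np.isnan(p))


def declare_mtas(records: list[MTARecord],
                 chisq_alpha: float = CHISQ_ALPHA,
                 reg_alpha: float = REG_ALPHA) -> list[MTARecord]:
    """Apply the declaration rule to scan + confirmation evidence.

    Qualitative: scan P < 0.0005 and chi-square P < 0.01 in >= 1
    subspecies.  Quantitative: scan P < 0.0005 and the set of cells
    with regression P < 0.05 covers more than one distinct environment
    or more than one distinct subspecies.
    """
    declared = []
    for rec in records:
        rec.declared = False
        rec.rule = ""
        if not rec.scan_significant:
            continue
        cells = rec.cells
        if cells.empty:
            continue
        if rec.kind == "qualitative":
            sig = cells[(cells["testable"]) & (cells["p"] < chisq_alpha)]
            if len(sig):
                rec.declared = True
                rec.rule = "scan+chisq"
        else:
            sig = cells[(cells["testable"]) & (cells["p"] < reg_alpha)]
            n_env = sig["environment"].nunique()
            n_sub = sig["subspecies"].nunique()
            if n_env > 1 or n_sub > 1:
                rec.declared = True
                rec.rule = "scan+regression"
        if rec.declared:
            declared.append(rec)
    return declared


def associate_quantitative(
    dataset: MarkerDataset,
    blup_table: pd.DataFrame,
    trait: str,
    scan_alpha: float = SCAN_ALPHA,
    reg_alpha: float = REG_ALPHA,
    max_missing: float = MAX_MISSING,
) -> list[MTARecord]:
    """Full quantitative-trait pipeline: filter, scan, confirm, declare.

    ``blup_table`` is the wide accession x (trait, environment) table of
    predicted values.  Returns one record per scan-significant marker
    (declared or not); the declaration flag is set on each.
    """
    markers = association_filter(dataset, max_missing)
    envs = sorted({e for t, e in blup_table.columns if t == trait})
    if not envs:
        raise ValueError(f"no environments for trait {trait!r} in BLUP table")
    scans = {}
    for env in envs:
        scans[env] = glm_q_scan(blup_table[(trait, env)], dataset, markers)
    m_tested = len(markers)
    chrom_of = dict(zip(dataset.marker_ids, dataset.chromosomes))
    mk_index = {mk: j for j, mk in enumerate(dataset.marker_ids)}
    sub_labels = dataset.subspecies_labels()

    records = []
    for mk in markers:
        scan_p = {env: float(scans[env].loc[mk, "p"]) for env in envs}
        if not any(p < scan_alpha for p in scan_p.values() if not np.isnan(p)):
            continue
        rec = MTARecord(
            marker=mk,
            trait=trait,
            kind="quantitative",
            chromosome=str(chrom_of[mk]),
            scan_p=scan_p,
            scan_r2={env: float(scans[env].loc[mk, "r2"]) for env in envs},
            bonferroni_p={e: bonferroni(p, m_tested) for e, p in scan_p.items()},
        )
        x = dataset.genotypes[:, mk_index[mk]]
        rows = []
        for sub in sub_labels:
            mask = dataset.subspecies_mask(sub)
            for env in envs:
                y = blup_table[(trait, env)].reindex(dataset.accession_ids)
                try:
                    slope, r2, p = regression_confirm(y.to_numpy(), x, mask)
                    rows.append(
                        dict(subspecies=sub, environment=env, statistic=slope,
                             p=p, r2=r2, testable=True)
                    )
                except ValueError as e:
                    rows.append(
                        dict(subspecies=sub, environment=env, statistic=np.nan,
                             p=np.nan, r2=np.nan, testable=False, reason=str(e))
                    )
        rec.cells = pd.DataFrame(rows)
        records.append(rec)
    declare_mtas(records, reg_alpha=reg_alpha)
    return records


def associate_qualitative(
    dataset: MarkerDataset,
    classes: pd.Series,
    trait: str,
    scan_alpha: float = SCAN_ALPHA,
    chisq_alpha: float = CHISQ_ALPHA,
    max_missing: float = MAX_MISSING,
    min_class_size: int = 5,
) -> list[MTARecord]:
    """Full qualitative-trait pipeline.

    The scan runs on one-vs-rest class indicators (classes with at
    least ``min_class_size`` members); the chi-square confirmation uses
    the full multi-class table within each subspecies.
    """
    markers = association_filter(dataset, max_missing)
    cl = classes.reindex(dataset.accession_ids)
    counts = cl.value_counts()
    scan_classes = [c for c in counts.index if counts[c] >= min_class_size]
    if not scan_classes:
        raise ValueError("no class with enough members for the scan")
    scans = {}
    for c in scan_classes:
        indicator = (cl == c).astype(float)
        indicator[cl.isna()] = np.nan
        scans[c] = glm_q_scan(indicator, dataset, markers)
    m_tested = len(markers)
    chrom_of = dict(zip(dataset.marker_ids, dataset.chromosomes))
    mk_index = {mk: j for j, mk in enumerate(dataset.marker_ids)}

    records = []
    for mk in markers:
        scan_p = {c: float(scans[c].loc[mk, "p"]) for c in scan_classes}
        if not any(p < scan_alpha for p in scan_p.values() if not np.isnan(p)):
            continue
        rec = MTARecord(
            marker=mk,
            trait=trait,
            kind="qualitative",
            chromosome=str(chrom_of[mk]),
            scan_p=scan_p,
            scan_r2={c: float(scans[c].loc[mk, "r2"]) for c in scan_classes},
            bonferroni_p={c: bonferroni(p, m_tested) for c, p in scan_p.items()},
        )
        x = dataset.genotypes[:, mk_index[mk]]
        rows = []
        for sub in dataset.subspecies_labels():
            mask = dataset.subspecies_mask(sub)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    chi2, dof, p = chisq_confirm(cl.to_numpy(), x, mask)
                rows.append(
                    dict(subspecies=sub, environment="C", statistic=chi2,
                         p=p, r2=np.nan, testable=True, df=dof)
                )
            except ValueError as e:
                rows.append(
                    dict(subspecies=sub, environment="C", statistic=np.nan,
                         p=np.nan, r2=np.nan, testable=False, reason=str(e))
                )
        rec.cells = pd.DataFrame(rows)
        records.append(rec)
    declare_mtas(records, chisq_alpha=chisq_alpha)
    return records


def monomorphic_concordance(
    record: MTARecord,
    dataset: MarkerDataset,
    trait_values: pd.Series,
) -> dict[str, bool | None]:
    """Concordance of a fixed allele state with the subspecies phenotype.

    For each subspecies in which the MTA marker is monomorphic: from the
    segregating accessions, determine which band state associates with
    the higher trait value (quantitative) or with which majority class
    (qualitative); the fixed subspecies is concordant iff its own trait
    mean (or dominant class) matches the state it is fixed for.  None
    marks a not-evaluable subspecies (trait absent there).
    """
    mk_index = {mk: j for j, mk in enumerate(dataset.marker_ids)}
    x = dataset.genotypes[:, mk_index[record.marker]]
    vals = trait_values.reindex(dataset.accession_ids)
    out: dict[str, bool | None] = {}
    fixed_in = {}
    for sub in dataset.subspecies_labels():
        sel = x[dataset.subspecies_mask(sub)]
        sel = sel[~np.isnan(sel)]
        if sel.size and sel.min() == sel.max():
            fixed_in[sub] = int(sel[0])
    seg_mask = np.zeros(dataset.n_accessions, dtype=bool)
    for sub in dataset.subspecies_labels():
        if sub not in fixed_in:
            seg_mask |= dataset.subspecies_mask(sub)
    record.concordance = out
    if not fixed_in or not seg_mask.any():
        return out

    quantitative = record.kind == "quantitative"
    v = vals.to_numpy(dtype=object)
    for sub, state in fixed_in.items():
        sub_mask = dataset.subspecies_mask(sub)
        v_sub = vals[sub_mask].dropna()
        if v_sub.empty:
            out[sub] = None
            continue
        if quantitative:
            y = vals.to_numpy(dtype=float)
            m1 = np.nanmean(y[seg_mask & (x == 1)])
            m0 = np.nanmean(y[seg_mask & (x == 0)])
            if np.isnan(m1) or np.isnan(m0) or m1 == m0:
                out[sub] = None
                continue
            m_s = float(np.nanmean(y[sub_mask]))
            predicted = 1 if abs(m_s - m1) < abs(m_s - m0) else 0
        else:
            c1 = pd.Series(v[seg_mask & (x == 1)]).dropna()
            c0 = pd.Series(v[seg_mask & (x == 0)]).dropna()
            if c1.empty or c0.empty:
                out[sub] = None
                continue
            class1 = c1.mode().iloc[0]
            class0 = c0.mode().iloc[0]
            if class1 == class0:
                out[sub] = None
                continue
            dominant = v_sub.mode().iloc[0]
            if dominant == class1:
                predicted = 1
            elif dominant == class0:
                predicted = 0
            else:
                out[sub] = None
                continue
        out[sub] = predicted == state
    return out


def mta_records_to_frame(records: list[MTARecord]) -> pd.DataFrame:
    """One row per (marker, trait, subspecies, environment) evidence cell.

    Stable sort by trait, then chromosome, then marker.
    """
    cols = [
        "trait", "chromosome", "marker", "kind", "subspecies", "environment",
        "statistic", "p", "r2", "cell_significant", "scan_p_min",
        "bonferroni_p_min", "declared", "rule", "concordant_in",
    ]
    rows = []
    for rec in records:
        scan_min = (
            np.nanmin(list(rec.scan_p.values())) if rec.scan_p else np.nan
        )
        bonf_min = (
            np.nanmin(list(rec.bonferroni_p.values()))
            if rec.bonferroni_p
            else np.nan
        )
        alpha = CHISQ_ALPHA if rec.kind == "qualitative" else REG_ALPHA
        conc = ";".join(
            f"{s}={v}" for s, v in sorted(rec.concordance.items())
        )
        cells = rec.cells if len(rec.cells) else pd.DataFrame(
            [dict(subspecies="NA", environment="NA", statistic=np.nan,
                  p=np.nan, r2=np.nan, testable=False)]
        )
        for _, c in cells.iterrows():
            rows.append(
                [
                    rec.trait, rec.chromosome, rec.marker, rec.kind,
                    c["subspecies"], c["environment"], c["statistic"], c["p"],
                    c["r2"],
                    bool(c["testable"]) and not np.isnan(c["p"]) and c["p"] < alpha,
                    scan_min, bonf_min, rec.declared, rec.rule, conc,
                ]
            )
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["trait", "chromosome", "marker"],
                          kind="mergesort").reset_index(drop=True)
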