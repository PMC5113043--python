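import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import kstest

from conftest import build_dataset, small_sim_config
from durmap.association import (
    MTARecord,
    associate_quantitative,
    association_filter,
    bonferroni,
    chisq_confirm,
    declare_mtas,
    glm_q_scan,
    monomorphic_concordance,
    regression_confirm,
)
from durmap.simulate import generate_collection


def test_missingness_filter_strict_boundary():
    geno = np.ones((40, 3))
    geno[:1, 0] = np.nan  # 2.5% missing -> retained
    geno[:2, 1] = np.nan  # exactly 5% -> dropped (strict <)
    geno[:3, 2] = np.nan  # 7.5% -> dropped
    geno[5:, :] = np.tile([0.0, 1.0, 0.0], (35, 1))
    ds = build_dataset(geno, ["durum"] * 40)
    assert association_filter(ds) == ["m1"]


def test_filter_matches_ledger_prediction():
    cfg = small_sim_config(seed=31)
    ds, led = generate_collection(cfg)
    kept = association_filter(ds)
    expected = list(led.missingness.index[led.missingness["passes_filter"]])
    assert kept == expected


def _ols_f_oracle(y, X_full, X_red):
    """Dense normal-equations F test for the last column of X_full."""
    bf = np.linalg.solve(X_full.T @ X_full, X_full.T @ y)
    br = np.linalg.solve(X_red.T @ X_red, X_red.T @ y)
    sse_f = np.sum((y - X_full @ bf) ** 2)
    sse_r = np.sum((y - X_red @ br) ** 2)
    df2 = y.size - X_full.shape[1]
    f = (sse_r - sse_f) / (sse_f / df2)
    return f, stats.f.sf(f, 1, df2), (sse_r - sse_f) / sse_r


def test_glm_q_scan_matches_normal_equations_oracle():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    marker = np.array([[0.0], [0.0], [1.0], [1.0]])
    q = np.array([[0.8, 0.2], [0.8, 0.2], [0.2, 0.8], [0.2, 0.8]])
    # the marker is collinear with Q here, so perturb Q slightly
    q = np.array([[0.8, 0.2], [0.7, 0.3], [0.2, 0.8], [0.3, 0.7]])
    ds = build_dataset(marker, ["durum"] * 4, q_matrix=q)
    res = glm_q_scan(y, ds)
    X_red = np.column_stack([np.ones(4), q[:, 0]])
    X_full = np.column_stack([X_red, marker[:, 0]])
    f, p, r2 = _ols_f_oracle(y, X_full, X_red)
    assert res.loc["m1", "F"] == pytest.approx(f, abs=1e-10)
    assert res.loc["m1", "p"] == pytest.approx(p, abs=1e-10)
    assert res.loc["m1", "r2"] == pytest.approx(r2, abs=1e-10)


def test_glm_q_scan_perfect_association():
    rng = np.random.default_rng(0)
    marker = rng.integers(0, 2, 30).astype(float)[:, None]
    q = np.full((30, 2), 0.5)
    ds = build_dataset(marker, ["durum"] * 30, q_matrix=q)
    res = glm_q_scan(marker[:, 0], ds)
    assert res.loc["m1", "r2"] == pytest.approx(1.0)
    assert res.loc["m1", "p"] == 0.0


def test_glm_q_scan_collinear_marker_flagged():
    q = np.array([[0.9, 0.1]] * 5 + [[0.1, 0.9]] * 5)
    marker = np.array([1.0] * 5 + [0.0] * 5)[:, None]
    # marker exactly equals an affine function of Q -> collinear
    ds = build_dataset(marker, ["durum"] * 10, q_matrix=q)
    res = glm_q_scan(np.arange(10.0), ds)
    assert res.loc["m1", "status"] == "collinear"
    assert np.isnan(res.loc["m1", "p"])


def test_glm_q_scan_null_p_uniform():
    """Scan p-values are uniform for a marker-independent response."""
    rng = np.random.default_rng(1)
    pvals = []
    for _ in range(25):
        cfg = small_sim_config(seed=int(rng.integers(1 << 30)),
                               missing_enabled=False)
        ds, _ = generate_collection(cfg)
        y = rng.standard_normal(ds.n_accessions)
        res = glm_q_scan(y, ds)
        pvals += list(res["p"].dropna())
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_q_adjustment_removes_structure_inflation():
    """Structure-correlated null markers inflate p without Q adjustment."""
    rng = np.random.default_rng(2)
    p_adj, p_naive = [], []
    for _ in range(20):
        cfg = small_sim_config(seed=int(rng.integers(1 << 30)),
                               conc_subspecies=1.5, missing_enabled=False,
                               q_concentration=500.0)
        ds, _ = generate_collection(cfg)
        sub_effect = {"durum": 0.0, "turgidum": 1.5, "dicoccon": -1.5}
        y = np.array([sub_effect[s] for s in ds.subspecies]) \
            + rng.standard_normal(ds.n_accessions)
        p_adj += list(glm_q_scan(y, ds)["p"].dropna())
        flat = build_dataset(ds.genotypes, list(ds.subspecies),
                             chromosomes=list(ds.chromosomes),
                             positions=ds.positions,
                             q_matrix=np.full((ds.n_accessions, 2), 0.5),
                             marker_ids=list(ds.marker_ids),
                             accession_ids=list(ds.accession_ids))
        p_naive += list(glm_q_scan(y, flat)["p"].dropna())
    assert kstest(p_adj, "uniform").pvalue > 0.01
    assert kstest(p_naive, "uniform").pvalue < 0.01
    assert np.mean(np.array(p_naive) < 0.05) > np.mean(np.array(p_adj) < 0.05)


def test_bonferroni_adjustment():
    assert bonferroni(0.0001, 532) == pytest.approx(0.0532)
    assert bonferroni(0.5, 532) == 1.0
    assert bonferroni(0.123, 1) == pytest.approx(0.123)
    with pytest.raises(ValueError):
        bonferroni(0.1, 0)


def test_chisq_closed_form_and_degenerate():
    # 2x2 table [[10,0],[0,10]]: chi2 = 20, df = 1
    classes = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
    marker = np.array([1.0] * 10 + [0.0] * 10)
    chi2, df, p = chisq_confirm(classes, marker)
    assert chi2 == pytest.approx(20.0) and df == 1

    # proportional rows: chi2 = 0, p = 1
    classes = np.array(["a", "a", "b", "b"] * 5, dtype=object)
    marker = np.array([1.0, 0.0, 1.0, 0.0] * 5)
    chi2, df, p = chisq_confirm(classes, marker)
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    with pytest.raises(ValueError, match="degenerate"):
        chisq_confirm(np.array(["a"] * 10, dtype=object),
                      np.array([1.0, 0.0] * 5))


def test_chisq_statistic_at_printed_magnitude_is_significant():
    """A statistic of 104.81 clears P < 0.01 at any df <= 3."""
    for df in (1, 2, 3):
        assert stats.chi2.sf(104.81, df) < 0.01


def test_regression_confirm_oracle_and_guards():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 2, 10).astype(float)
    while x.std() == 0:
        x = rng.integers(0, 2, 10).astype(float)
    y = 2.0 * x + rng.standard_normal(10)
    slope, r2, p = regression_confirm(y, x)
    X_full = np.column_stack([np.ones(10), x])
    X_red = np.ones((10, 1))
    f, p_o, r2_o = _ols_f_oracle(y, X_full, X_red)
    assert p == pytest.approx(p_o, abs=1e-10)
    assert r2 == pytest.approx(r2_o, abs=1e-10)

    y2 = x + 3.0
    _, r2_exact, _ = regression_confirm(y2, x)
    assert r2_exact == pytest.approx(1.0)

    with pytest.raises(ValueError, match="fewer than 5"):
        regression_confirm(y[:4], x[:4])
    with pytest.raises(ValueError, match="monomorphic"):
        regression_confirm(y, np.ones(10))


def _quant_record(cells, scan_p=1e-5):
    rec = MTARecord(marker="m", trait="t", kind="quantitative",
                    chromosome="1A", scan_p={"C": scan_p})
    rec.cells = pd.DataFrame(
        [dict(subspecies=s, environment=e, statistic=1.0, p=p, r2=0.1,
              testable=True) for s, e, p in cells]
    )
    return rec


def test_declaration_rules():
    # significant in 4 environments within one subspecies -> declared
    rec = _quant_record([("durum", e, 0.01) for e in ("C", "N", "S", "S08")])
    assert declare_mtas([rec]) == [rec] and rec.rule == "scan+regression"

    # one significant cell only -> not declared
    rec = _quant_record([("durum", "C", 0.01), ("durum", "N", 0.2)])
    assert declare_mtas([rec]) == []

    # one cell in each of two subspecies, same environment -> declared
    rec = _quant_record([("durum", "C", 0.01), ("turgidum", "C", 0.04)])
    assert declare_mtas([rec]) == [rec]

    # scan not significant -> never declared
    rec = _quant_record([("durum", "C", 0.01), ("durum", "N", 0.01)],
                        scan_p=0.001)
    assert declare_mtas([rec]) == []

    # boundary p exactly at threshold is non-significant (strict <)
    rec = _quant_record([("durum", "C", 0.05), ("durum", "N", 0.05)])
    assert declare_mtas([rec]) == []
    rec = _quant_record([("durum", "C", 0.01)], scan_p=0.0005)
    assert declare_mtas([rec]) == []


def test_qualitative_declaration_rule():
    rec = MTARecord(marker="m", trait="t", kind="qualitative",
                    chromosome="1A", scan_p={"classA": 1e-5})
    rec.cells = pd.DataFrame(
        [dict(subspecies="durum", environment="C", statistic=12.0, p=0.003,
              r2=np.nan, testable=True)]
    )
    assert declare_mtas([rec]) == [rec] and rec.rule == "scan+chisq"
    rec.cells.loc[0, "p"] = 0.02
    assert declare_mtas([rec]) == []


def _concordance_dataset():
    # durum segregating (first 10), dicoccon fixed (last 4)
    x = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    sub = ["durum"] * 10 + ["dicoccon"] * 4
    return build_dataset(x[:, None], sub), x


def test_monomorphic_concordance_quantitative():
    ds, x = _concordance_dataset()
    rec = MTARecord(marker="m1", trait="t", kind="quantitative",
                    chromosome="1A")
    # band state 1 associates with higher values in durum; dicoccon is
    # fixed for 1 and has the highest mean -> concordant
    vals = pd.Series(
        [5, 5, 5, 5, 5, 1, 1, 1, 1, 1, 7, 7, 7, 7],
        index=ds.accession_ids, dtype=float,
    )
    flags = monomorphic_concordance(rec, ds, vals)
    assert flags == {"dicoccon": True}
    # same fixation but the lowest mean -> discordant
    vals2 = vals.copy()
    vals2.iloc[10:] = -3.0
    assert monomorphic_concordance(rec, ds, vals2) == {"dicoccon": False}


def test_monomorphic_concordance_qualitative():
    ds, x = _concordance_dataset()
    rec = MTARecord(marker="m1", trait="t", kind="qualitative",
                    chromosome="1A")
    vals = pd.Series(
        ["red"] * 5 + ["white"] * 5 + ["red"] * 4, index=ds.accession_ids
    )
    assert monomorphic_concordance(rec, ds, vals) == {"dicoccon": True}
    vals2 = pd.Series(
        ["red"] * 5 + ["white"] * 5 + ["white"] * 4, index=ds.accession_ids
    )
    assert monomorphic_concordance(rec, ds, vals2) == {"dicoccon": False}


def test_quantitative_pipeline_detects_planted_effect():
    """End-to-end scan + confirmation declares a strong planted marker."""
    cfg = small_sim_config(seed=41, n_durum=60, n_turgidum=20, n_dicoccon=8,
                           n_rows=10, n_cols=10, missing_enabled=False)
    ds, led = generate_collection(cfg)
    rng = np.random.default_rng(5)
    # pick a marker segregating at intermediate frequency in durum
    durum = ds.subspecies_mask("durum")
    freqs = ds.genotypes[durum].mean(axis=0)
    j = int(np.argmin(np.abs(freqs - 0.5)))
    x = ds.genotypes[:, j].copy()
    g = 1.2 * x + 0.5 * rng.standard_normal(ds.n_accessions)
    cols = {}
    for env in ("C", "N"):
        cols[("t", env)] = pd.Series(
            g + 0.5 * rng.standard_normal(ds.n_accessions),
            index=ds.accession_ids,
        )
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["trait", "environment"])
    recs = associate_quantitative(ds, table, "t")
    declared = {r.marker for r in recs if r.declared}
    assert ds.marker_ids[j] in declared
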