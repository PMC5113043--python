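"""Nei gene diversity, diversity loss (ΔGD) and monomorphic-marker scans.

For a dominant biallelic marker scored as band presence/absence the
allele frequency is taken as the band-presence frequency p directly (no
Hardy-Weinberg back-correction), and Nei's gene diversity is

    H = 1 - p^2 - (1 - p)^2 = 2 p (1 - p),

with maximum 0.5 at p = 0.5.  The relative diversity loss of a
subspecies against the whole collection is ΔGD = 1 - H_subsp / H_wc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerDataset, genome_of

SCOPES_ORDER = ("chromosome", "genome", "total")


def band_frequency(column: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Band-presence frequency among non-missing calls of a group.

    Returns NaN (with a warning) when the group has no non-missing call.
    """
    col = np.asarray(column, dtype=float)
    if mask is not None:
        col = col[np.asarray(mask, dtype=bool)]
    ok = ~np.isnan(col)
    if not ok.any():
        warnings.warn("all calls missing in group; marker skipped", stacklevel=2)
        return np.nan
    return float(col[ok].mean())


def nei_h(p: float | np.ndarray) -> float | np.ndarray:
    """Nei gene diversity of a biallelic locus with allele frequency p."""
    p = np.asarray(p, dtype=float)
    h = 2.0 * p * (1.0 - p)
    return float(h) if h.ndim == 0 else h


def delta_gd(h_subsp: float, h_wc: float) -> float:
    """Relative loss of gene diversity, 1 - H_subsp / H_wc.

    NaN when the whole-collection diversity is zero.  Negative values
    are possible when the subspecies exceeds the collection diversity.
    """
    if h_wc == 0 or np.isnan(h_wc):
        return np.nan
    return 1.0 - h_subsp / h_wc


@dataclass
class DiversityTable:
    """Per-scope gene diversity and diversity loss.

    ``h`` and ``dgd`` are DataFrames indexed by scope (chromosome
    labels, 'Genome A', 'Genome B', 'Total'); ``h`` has one column per
    group (whole collection first, then subspecies), ``dgd`` one column
    per subspecies.  ``marker_h`` holds per-marker H per group.
    """

    h: pd.DataFrame
    dgd: pd.DataFrame
    marker_h: pd.DataFrame
    band_freq: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.h.copy()
        out.columns = [f"H_{c}" for c in out.columns]
        for c in self.dgd.columns:
            out[f"dGD_{c}"] = self.dgd[c]
        out.insert(0, "scope", out.index)
        return out.reset_index(drop=True)


def aggregate_h(dataset: MarkerDataset) -> DiversityTable:
    """Gene diversity per chromosome, genome and overall, per group.

    Scope values are unweighted means of per-marker H over the markers
    in scope; markers whose calls are all missing within a group are
    excluded from that group's means; unmapped markers contribute only
    to the 'Total' scope.
    """
    groups = ["whole_collection"] + dataset.subspecies_labels()
    m = dataset.n_markers
    freq = pd.DataFrame(index=dataset.marker_ids, columns=groups, dtype=float)
    for g in groups:
        mask = None if g == "whole_collection" else dataset.subspecies_mask(g)
        col = dataset.genotypes if mask is None else dataset.genotypes[mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(col, axis=0)
        counts = (~np.isnan(col)).sum(axis=0)
        p[counts == 0] = np.nan
        freq[g] = p
    marker_h = freq.apply(nei_h)

    chroms = np.asarray(dataset.chromosomes, dtype=object)
    genomes = dataset.genomes()
    scopes: list[tuple[str, np.ndarray]] = []
    for c in sorted({c for c in chroms if c != "NA"}):
        scopes.append((c, chroms == c))
    for g in ("A", "B"):
        mask = genomes == g
        if mask.any():
            scopes.append((f"Genome {g}", mask))
    scopes.append(("Total", np.ones(m, dtype=bool)))

    h = pd.DataFrame(index=[s for s, _ in scopes], columns=groups, dtype=float)
    for scope, mask in scopes:
        sub = marker_h.loc[np.asarray(mask)]
        h.loc[scope] = sub.mean(axis=0, skipna=True) if len(sub) else np.nan
    dgd = pd.DataFrame(index=h.index, columns=groups[1:], dtype=float)
    for g in groups[1:]:
        dgd[g] = [delta_gd(h.loc[s, g], h.loc[s, "whole_collection"]) for s in h.index]
    return DiversityTable(h=h, dgd=dgd, marker_h=marker_h, band_freq=freq)


@dataclass
class MonomorphicReport:
    """Per-subspecies monomorphic marker sets and their overlaps.

    A marker is monomorphic (fixed) within a group iff all non-missing
    calls are equal and at least one call is present; fixation at 0 and
    at 1 both count, and overlap counts are on marker identity
    regardless of the fixed state.
    """

    sets: dict[str, set[str]]
    fixed_state: pd.DataFrame
    pairwise_overlap: dict[tuple[str, str], int]
    triple_overlap: int

    def counts(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.sets.items()}

    def union_count(self) -> int:
        out: set[str] = set()
        for v in self.sets.values():
            out |= v
        return len(out)

    def to_frame(self) -> pd.DataFrame:
        groups = list(self.sets)
        rows = []
        for mk in self.fixed_state.index:
            states = self.fixed_state.loc[mk]
            if (states != "NA").any():
                rows.append([mk] + [states[g] for g in groups])
        return pd.DataFrame(rows, columns=["marker"] + groups)


def monomorphic_scan(dataset: MarkerDataset) -> MonomorphicReport:
    """Scan each subspecies for fixed markers and count overlaps."""
    groups = dataset.subspecies_labels()
    sets: dict[str, set[str]] = {}
    state = pd.DataFrame("NA", index=dataset.marker_ids, columns=groups)
    for g in groups:
        sub = dataset.genotypes[dataset.subspecies_mask(g)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mn = np.nanmin(sub, axis=0)
            mx = np.nanmax(sub, axis=0)
        present = (~np.isnan(sub)).any(axis=0)
        fixed = present & (mn == mx)
        ids = {dataset.marker_ids[j] for j in np.flatnonzero(fixed)}
        sets[g] = ids
        for j in np.flatnonzero(fixed):
            state.iloc[j, state.columns.get_loc(g)] = str(int(mn[j]))
    pairwise = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    triple = len(set.intersection(*sets.values())) if len(groups) >= 3 else 0
    return MonomorphicReport(
        sets=sets, fixed_state=state, pairwise_overlap=pairwise, triple_overlap=triple
    )
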