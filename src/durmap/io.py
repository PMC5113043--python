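"""Reading and writing of the pipeline's on-disk artifacts.

Everything is UTF-8 tab-separated text with a header row.  The missing
token is ``NA`` (the empty string is also accepted on read).  Dominant
marker calls are 0 (band absent) / 1 (band present) / missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "NA"

#: subspecies labels used throughout; free strings are accepted, these are
#: the canonical ones for a Spanish tetraploid-wheat landrace collection.
KNOWN_SUBSPECIES = ("durum", "turgidum", "dicoccon")


class ValidationError(ValueError):
    """A file or in-memory object violates a structural invariant."""


def genome_of(chromosome: str) -> str:
    """Genome ('A' or 'B') of a wheat chromosome label, else 'NA'.

    The genome is the trailing letter of labels like ``1A`` .. ``7B``;
    arm suffixes (``3BL``, ``1AS``) are tolerated by looking at the last
    A/B in the label.
    """
    if not isinstance(chromosome, str) or chromosome == MISSING:
        return MISSING
    for ch in reversed(chromosome.upper()):
        if ch in ("A", "B"):
            return ch
    return MISSING


@dataclass
class MarkerDataset:
    """A collection of accessions scored for dominant biallelic markers.

    Attributes
    ----------
    accession_ids : list of unique accession names.
    subspecies : array of per-accession subspecies labels.
    genotypes : float array (n_accessions, n_markers); entries 0.0, 1.0
        or NaN (missing call).
    marker_ids : list of unique marker names.
    chromosomes : array of per-marker chromosome labels ('NA' = unmapped).
    positions : float array of per-marker cM positions (NaN = unmapped).
    q_matrix : float array (n_accessions, n_populations) of population
        membership proportions; rows sum to 1.
    """

    accession_ids: list[str]
    subspecies: np.ndarray
    genotypes: np.ndarray
    marker_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    q_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.subspecies = np.asarray(self.subspecies, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        self.q_matrix = np.asarray(self.q_matrix, dtype=float)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subspecies_mask(self, label: str) -> np.ndarray:
        return self.subspecies == label

    def subspecies_labels(self) -> list[str]:
        """Distinct subspecies labels, canonical ones first."""
        present = list(dict.fromkeys(self.subspecies.tolist()))
        ordered = [s for s in KNOWN_SUBSPECIES if s in present]
        ordered += [s for s in present if s not in ordered]
        return ordered

    def genomes(self) -> np.ndarray:
        return np.array([genome_of(c) for c in self.chromosomes], dtype=object)

    def validate(self) -> None:
        n, m = len(self.accession_ids), len(self.marker_ids)
        if len(set(self.accession_ids)) != n:
            raise ValidationError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        if self.genotypes.shape != (n, m):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} != ({n}, {m})"
            )
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.all((vals == 0.0) | (vals == 1.0)):
            bad = vals[(vals != 0.0) & (vals != 1.0)][0]
            raise ValidationError(f"genotype entries must be 0/1/missing; got {bad}")
        if self.subspecies.shape != (n,):
            raise ValidationError("subspecies labels must be per-accession")
        if self.chromosomes.shape != (m,) or self.positions.shape != (m,):
            raise ValidationError("map arrays must be per-marker")
        mapped = ~np.isnan(self.positions)
        if np.any(self.positions[mapped] < 0) or not np.all(
            np.isfinite(self.positions[mapped])
        ):
            raise ValidationError("mapped positions must be finite and >= 0")
        if self.q_matrix.shape[0] != n:
            raise ValidationError("Q matrix must have one row per accession")
        rowsums = self.q_matrix.sum(axis=1)
        off = np.abs(rowsums - 1.0) > 1e-6
        if np.any(off):
            acc = self.accession_ids[int(np.argmax(off))]
            raise ValidationError(
                f"Q row for accession {acc!r} sums to {rowsums[off][0]:.8f}, not 1"
            )


@dataclass
class TrialData:
    """Plot-level phenotype records of an augmented field design.

    ``records`` has columns: environment, row, col, entry, is_check,
    trait, value.  Qualitative traits store class labels as strings;
    quantitative traits store floats.  The same trait name never mixes
    the two.
    """

    records: pd.DataFrame
    check_ids: list[str] = field(default_factory=list)

    REQUIRED = ("environment", "row", "col", "entry", "is_check", "trait", "value")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"trial records missing columns {missing}")
        dup = self.records.duplicated(["environment", "row", "col", "trait"])
        if dup.any():
            r = self.records[dup].iloc[0]
            raise ValidationError(
                "duplicate plot for trait "
                f"{r['trait']!r} at ({r['environment']}, {r['row']}, {r['col']})"
            )
        checks = self.records[self.records["is_check"]]
        for (env, trait), grp in checks.groupby(["environment", "trait"]):
            counts = grp["entry"].value_counts()
            if (counts < 2).any():
                cid = counts.index[counts < 2][0]
                raise ValidationError(
                    f"check {cid!r} has <2 plots in environment {env} for {trait!r}"
                )
        for trait, grp in self.records.groupby("trait"):
            numeric = pd.to_numeric(grp["value"], errors="coerce").notna()
            if numeric.any() and not numeric.all():
                raise ValidationError(
                    f"trait {trait!r} mixes numeric and categorical values"
                )

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def subset(self, trait: str, environment: str) -> pd.DataFrame:
        sel = (self.records["trait"] == trait) & (
            self.records["environment"] == environment
        )
        return self.records[sel].reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_genotype_token(tok: str, path: str, row: int, col: int) -> float:
    if tok in ("", MISSING):
        return np.nan
    if tok in ("0", "1"):
        return float(tok)
    try:
        v = float(tok)
        if v in (0.0, 1.0):
            return v
    except ValueError:
        pass
    raise ValidationError(
        f"{path}: invalid genotype token {tok!r} at data row {row}, column {col}"
    )


def read_dataset(
    genotype_path: str | Path,
    map_path: str | Path,
    q_path: str | Path,
    subspecies_path: str | Path,
) -> MarkerDataset:
    """Read a MarkerDataset from its four tab-separated files.

    Markers present in the genotype file but absent from the map file are
    kept with unknown chromosome/position.
    """
    geno = _read_tsv(genotype_path)
    acc_col = geno.columns[0]
    accession_ids = geno[acc_col].tolist()
    marker_ids = list(geno.columns[1:])
    mat = np.empty((len(accession_ids), len(marker_ids)))
    for j, mk in enumerate(marker_ids):
        col = geno[mk].tolist()
        for i, tok in enumerate(col):
            mat[i, j] = _parse_genotype_token(tok, str(genotype_path), i + 1, j + 2)

    mp = _read_tsv(map_path)
    chrom_by_marker = dict(zip(mp.iloc[:, 0], mp.iloc[:, 1]))
    pos_by_marker = dict(zip(mp.iloc[:, 0], mp.iloc[:, 2]))
    chroms = np.array(
        [chrom_by_marker.get(mk, MISSING) or MISSING for mk in marker_ids],
        dtype=object,
    )
    positions = np.array(
        [
            np.nan
            if pos_by_marker.get(mk, MISSING) in ("", MISSING)
            else float(pos_by_marker[mk])
            for mk in marker_ids
        ]
    )

    sub = _read_tsv(subspecies_path)
    sub_by_acc = dict(zip(sub.iloc[:, 0], sub.iloc[:, 1]))
    try:
        subspecies = np.array([sub_by_acc[a] for a in accession_ids], dtype=object)
    except KeyError as e:
        raise ValidationError(f"accession {e.args[0]!r} missing from subspecies file")

    q = _read_tsv(q_path)
    q_by_acc = {r.iloc[0]: r.iloc[1:].astype(float).to_numpy() for _, r in q.iterrows()}
    try:
        q_matrix = np.vstack([q_by_acc[a] for a in accession_ids])
    except KeyError as e:
        raise ValidationError(f"accession {e.args[0]!r} missing from Q file")

    return MarkerDataset(
        accession_ids=accession_ids,
        subspecies=subspecies,
        genotypes=mat,
        marker_ids=marker_ids,
        chromosomes=chroms,
        positions=positions,
        q_matrix=q_matrix,
    )


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return MISSING
    return f"{x:.6g}"


def write_dataset(dataset: MarkerDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four-file representation of *dataset* into *out_dir*.

    Returns a dict with keys genotypes/map/q/subspecies mapping to paths.
    Column order is deterministic; missing cells are written as ``NA``.
    """
    if dataset.n_markers == 0:
        raise ValidationError("no markers to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "map": out / "map.tsv",
        "q": out / "q.tsv",
        "subspecies": out / "subspecies.tsv",
    }

    geno = pd.DataFrame(
        [
            [MISSING if np.isnan(v) else str(int(v)) for v in row]
            for row in dataset.genotypes
        ],
        columns=dataset.marker_ids,
    )
    geno.insert(0, "accession", dataset.accession_ids)
    geno.to_csv(paths["genotypes"], sep="\t", index=False)

    mp = pd.DataFrame(
        {
            "marker": dataset.marker_ids,
            "chromosome": [c or MISSING for c in dataset.chromosomes],
            "position_cM": [_fmt(p) for p in dataset.positions],
        }
    )
    mp.to_csv(paths["map"], sep="\t", index=False)

    k = dataset.q_matrix.shape[1]
    # round to 8 decimals but keep each row summing to exactly 1 as printed
    q_rows = []
    for row in dataset.q_matrix:
        head = [round(v, 8) for v in row[:-1]]
        tail = round(1.0 - sum(head), 8)
        q_rows.append([f"{v:.8f}" for v in head + [tail]])
    q = pd.DataFrame(np.array(q_rows), columns=[f"pop{i + 1}" for i in range(k)])
    q.insert(0, "accession", dataset.accession_ids)
    q.to_csv(paths["q"], sep="\t", index=False)

    sub = pd.DataFrame(
        {"accession": dataset.accession_ids, "subspecies": dataset.subspecies}
    )
    sub.to_csv(paths["subspecies"], sep="\t", index=False)
    return paths


def read_trial(path: str | Path) -> TrialData:
    df = _read_tsv(path)
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    df["is_check"] = df["is_check"].map(
        {"True": True, "False": False, "1": True, "0": False}
    )
    checks = sorted(df.loc[df["is_check"], "entry"].unique())
    return TrialData(records=df, check_ids=checks)


def write_trial(trial: TrialData, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = trial.records.copy()
    df = df.sort_values(["trait", "environment", "row", "col"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
    return path


def write_mta_report(records: list, path: str | Path) -> Path:
    """Serialize marker-trait-association records to one TSV.

    One row per (marker, trait, subspecies, environment) evidence cell,
    sorted by trait, then chromosome, then marker.
    """
    from .association import mta_records_to_frame  # local import: no cycle

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = mta_records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)
    return path


def read_mta_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    return df
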