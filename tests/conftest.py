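import numpy as np
import pytest

from durmap.io import MarkerDataset
from durmap.simulate import SimConfig


def build_dataset(
    genotypes,
    subspecies,
    chromosomes=None,
    positions=None,
    q_matrix=None,
    marker_ids=None,
    accession_ids=None,
):
    """Assemble a small MarkerDataset from plain lists (NaN = missing)."""
    genotypes = np.asarray(genotypes, dtype=float)
    n, m = genotypes.shape
    if accession_ids is None:
        accession_ids = [f"acc{i + 1}" for i in range(n)]
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(m)]
    if chromosomes is None:
        chromosomes = ["1A"] * m
    if positions is None:
        positions = np.linspace(0.0, 10.0 * (m - 1), m)
    if q_matrix is None:
        labels = sorted(set(subspecies))
        q_matrix = np.zeros((n, max(len(labels), 2)))
        for i, s in enumerate(subspecies):
            q_matrix[i, labels.index(s)] = 1.0
        empty = q_matrix.sum(axis=0) == 0
        q_matrix[:, empty] = 0.0
        q_matrix = q_matrix + 1e-9
        q_matrix /= q_matrix.sum(axis=1, keepdims=True)
    return MarkerDataset(
        accession_ids=list(accession_ids),
        subspecies=np.asarray(subspecies, dtype=object),
        genotypes=genotypes,
        marker_ids=list(marker_ids),
        chromosomes=np.asarray(chromosomes, dtype=object),
        positions=np.asarray(positions, dtype=float),
        q_matrix=q_matrix,
    )


def small_sim_config(seed=0, **overrides):
    """A reduced collection/trial configuration for fast tests."""
    defaults = dict(
        seed=seed,
        n_durum=20,
        n_turgidum=8,
        n_dicoccon=5,
        n_markers=60,
        n_populations=4,
        mono_fractions={"durum": 0.02, "turgidum": 0.1, "dicoccon": 0.3},
        mapped_fraction=0.5,
        missing_high_fraction=0.2,
        environments=("C", "N"),
        n_checks=2,
        n_rows=6,
        n_cols=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def toy_dataset():
    """12 accessions x 4 markers with known structure for diversity/LD."""
    geno = np.array(
        [
            # m1: p=0.5 everywhere; m2 fixed 1 in dicoccon; m3 fixed 0
            # in dicoccon and 1 in turgidum; m4 has a missing call
            [1, 1, 1, 1],
            [0, 0, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 1, np.nan],
            [1, 0, 1, 1],
            [0, 1, 1, 0],
            [1, 0, 1, 1],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 1, 0, 0],
        ]
    )
    subspecies = ["durum"] * 6 + ["turgidum"] * 4 + ["dicoccon"] * 2
    return build_dataset(
        geno,
        subspecies,
        chromosomes=["1A", "1A", "2B", "NA"],
        positions=[0.0, 5.0, 3.0, np.nan],
    )
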