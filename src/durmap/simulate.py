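"""Seeded synthetic collections and field trials.

The generator emulates the statistical structure of a structured
tetraploid-wheat landrace collection scored with dominant biallelic
(band present/absent) markers:

* three subspecies of very unequal size (defaults 132 durum, 38
  turgidum, 13 dicoccon) subdivided into populations (default 9) with
  hierarchically drawn band frequencies, so the Q matrix is
  block-structured;
* markers placed on 14 chromosomes (1A..7B) with uniform cM positions
  and distance-dependent LD induced by a first-order Markov copying
  process at scale ``tau_cm``;
* per-subspecies monomorphic marker sets planted by fixing the band
  frequency to 0 or 1 in every population of that subspecies;
* marker-wise missing calls, with a configurable marker subset pushed
  above the 5% missingness bound so the association filter is
  exercised;
* augmented field trials (unreplicated entries plus repeated checks on
  a row x column grid) with planted marker effects on quantitative and
  qualitative traits.

Every stochastic component draws from its own child stream of the
mandatory seed, so outputs are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerDataset, TrialData

CHROMOSOMES = tuple(f"{i}{g}" for i in range(1, 8) for g in ("A", "B"))


@dataclass
class PlantedQTL:
    """A marker effect planted on a trait.

    ``target_r2`` is the marker's target coefficient of determination on
    plot-level trait values within ``subspecies`` (the subspecies in
    which the marker must segregate).
    """

    marker: int | str
    trait: str
    target_r2: float
    subspecies: str = "durum"
    qualitative: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must be in (0, 1)")


@dataclass
class SimConfig:
    """Parameters of the synthetic collection and trials."""

    seed: int
    n_durum: int = 132
    n_turgidum: int = 38
    n_dicoccon: int = 13
    n_markers: int = 749
    n_populations: int = 9
    # per-subspecies monomorphic fraction targets (observed scale of the
    # emulated collection: 11, 80 and 265 of 749 markers)
    mono_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "durum": 11 / 749,
            "turgidum": 80 / 749,
            "dicoccon": 265 / 749,
        }
    )
    tau_cm: float = 5.0
    chrom_length_cm: float = 150.0
    mapped_fraction: float = 329 / 749
    # hierarchical frequency concentrations (subspecies | collection,
    # population | subspecies)
    conc_subspecies: float = 8.0
    conc_population: float = 30.0
    q_concentration: float = 50.0
    # missingness: markers in the "high" subset get >= 5% missing calls
    # and must fail the association filter; all others stay below 5%
    missing_high_fraction: float = 217 / 749
    missing_enabled: bool = True
    # trial structure
    environments: tuple[str, ...] = ("C", "N", "S", "S08")
    env_means: dict[str, float] = field(
        default_factory=lambda: {"C": 10.0, "N": 9.0, "S": 7.5, "S08": 8.0}
    )
    sigma2_row: float = 0.5
    sigma2_col: float = 0.5
    sigma2_acc: float = 1.0
    sigma2_e: float = 0.5
    sigma2_sub_env: float = 0.1
    n_checks: int = 4
    n_rows: int = 19
    n_cols: int = 12
    quant_traits: tuple[str, ...] = ("plant_height",)
    qual_traits: tuple[str, ...] = ()
    qual_class_props: tuple[float, ...] = (0.3, 0.4, 0.3)
    qtls: list[PlantedQTL] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, n in (
            ("n_durum", self.n_durum),
            ("n_turgidum", self.n_turgidum),
            ("n_dicoccon", self.n_dicoccon),
            ("n_markers", self.n_markers),
        ):
            if n <= 0:
                raise ValueError(f"{name} must be positive")
        for v in (self.sigma2_row, self.sigma2_col, self.sigma2_acc, self.sigma2_e):
            if v < 0:
                raise ValueError("variance components must be >= 0")

    @property
    def subspecies_sizes(self) -> dict[str, int]:
        return {
            "durum": self.n_durum,
            "turgidum": self.n_turgidum,
            "dicoccon": self.n_dicoccon,
        }

    @property
    def n_accessions(self) -> int:
        return self.n_durum + self.n_turgidum + self.n_dicoccon

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TruthLedger:
    """Ground-truth bookkeeping for recovery tests.

    All "realized" quantities are measured on the simulated data after
    generation, never assumed from the configuration.
    """

    #: marker x subspecies realized monomorphic status (pre-missingness)
    monomorphic: pd.DataFrame
    #: fixed band state where monomorphic ('0'/'1'), else 'NA'
    fixed_state: pd.DataFrame
    #: per marker: number of missing calls and whether the marker passes
    #: the strict <5% missingness association filter
    missingness: pd.DataFrame
    #: one row per planted QTL; realized R2 columns appended per
    #: environment by generate_trial
    qtls: pd.DataFrame
    #: pre-missingness genotype columns of planted QTL markers
    qtl_genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    #: latent accession genetic values per quantitative trait
    genetic_values: pd.DataFrame | None = None
    #: realized variance components per (trait, environment): the
    #: variances of the effects actually drawn, the recovery reference
    variance_truth: pd.DataFrame | None = None

    def monomorphic_sets(self) -> dict[str, set[str]]:
        return {
            s: set(self.monomorphic.index[self.monomorphic[s]])
            for s in self.monomorphic.columns
        }

    def write(self, path) -> None:
        frames = []
        mono = self.monomorphic.copy()
        mono.insert(0, "marker", mono.index)
        mono.insert(0, "table", "monomorphic")
        frames.append(mono)
        miss = self.missingness.copy()
        miss.insert(0, "marker", miss.index)
        miss.insert(0, "table", "missingness")
        frames.append(miss)
        if len(self.qtls):
            q = self.qtls.copy()
            q.insert(0, "table", "qtl")
            frames.append(q)
        pd.concat(frames).to_csv(path, sep="\t", index=False, na_rep="NA")


def _population_allocation(sizes: dict[str, int], n_populations: int) -> dict[str, int]:
    """Largest-remainder allocation of populations to subspecies (>=1 each)."""
    total = sum(sizes.values())
    raw = {s: n_populations * n / total for s, n in sizes.items()}
    alloc = {s: max(1, int(math.floor(r))) for s, r in raw.items()}
    while sum(alloc.values()) < n_populations:
        rem = {s: raw[s] - alloc[s] for s in alloc}
        alloc[max(rem, key=rem.get)] += 1
    while sum(alloc.values()) > n_populations:
        rem = {s: raw[s] - alloc[s] for s in alloc if alloc[s] > 1}
        alloc[min(rem, key=rem.get)] -= 1
    return alloc


def generate_collection(config: SimConfig) -> tuple[MarkerDataset, TruthLedger]:
    """Generate a seeded synthetic marker collection and its truth ledger."""
    sizes = config.subspecies_sizes
    n = config.n_accessions
    m = config.n_markers
    sub_labels = np.concatenate(
        [np.full(sz, s, dtype=object) for s, sz in sizes.items()]
    )
    accession_ids = []
    for s, sz in sizes.items():
        accession_ids += [f"{s}_{i + 1:03d}" for i in range(sz)]

    # --- marker map: markers spread as evenly as possible over 14
    # chromosomes, sorted uniform positions within each -----------------
    rng_map = config.rng(1)
    per_chrom = np.full(len(CHROMOSOMES), m // len(CHROMOSOMES))
    per_chrom[: m % len(CHROMOSOMES)] += 1
    chroms = np.concatenate(
        [np.full(k, c, dtype=object) for c, k in zip(CHROMOSOMES, per_chrom)]
    )
    positions = np.concatenate(
        [np.sort(rng_map.uniform(0.0, config.chrom_length_cm, k)) for k in per_chrom]
    )
    marker_ids = [f"mk{j + 1:04d}" for j in range(m)]

    # --- hierarchical band frequencies ---------------------------------
    rng_freq = config.rng(2)
    p0 = rng_freq.uniform(0.1, 0.9, m)
    sub_names = list(sizes)
    p_sub = {
        s: rng_freq.beta(config.conc_subspecies * p0, config.conc_subspecies * (1 - p0))
        for s in sub_names
    }
    pop_alloc = _population_allocation(sizes, config.n_populations)
    pop_of_sub: dict[str, list[int]] = {}
    pop_freq = np.empty((config.n_populations, m))
    k = 0
    for s in sub_names:
        pop_of_sub[s] = list(range(k, k + pop_alloc[s]))
        for _ in range(pop_alloc[s]):
            a = np.clip(config.conc_population * p_sub[s], 1e-3, None)
            b = np.clip(config.conc_population * (1 - p_sub[s]), 1e-3, None)
            pop_freq[k] = rng_freq.beta(a, b)
            k += 1

    # --- plant per-subspecies monomorphic sets --------------------------
    rng_mono = config.rng(3)
    protected: dict[str, set[int]] = {s: set() for s in sub_names}
    for q in config.qtls:
        idx = q.marker if isinstance(q.marker, int) else marker_ids.index(q.marker)
        protected[q.subspecies].add(idx)
    planted_mono: dict[str, np.ndarray] = {}
    for s in sub_names:
        n_mono = int(round(config.mono_fractions.get(s, 0.0) * m))
        eligible = np.setdiff1d(np.arange(m), np.array(sorted(protected[s]), dtype=int))
        if n_mono > eligible.size:
            raise ValueError(
                f"monomorphic fraction for {s} infeasible with planted QTLs"
            )
        chosen = rng_mono.choice(eligible, size=n_mono, replace=False)
        planted_mono[s] = np.sort(chosen)
        states = (rng_mono.random(n_mono) < p_sub[s][chosen]).astype(float)
        for pop in pop_of_sub[s]:
            pop_freq[pop, chosen] = states

    # --- accession -> population -----------------------------------------
    rng_pop = config.rng(4)
    pop_of_acc = np.empty(n, dtype=int)
    start = 0
    for s in sub_names:
        sz = sizes[s]
        pop_of_acc[start : start + sz] = rng_pop.choice(pop_of_sub[s], size=sz)
        # ensure every population is non-empty when the subspecies allows it
        for j, pop in enumerate(pop_of_sub[s]):
            if j < sz and not np.any(pop_of_acc[start : start + sz] == pop):
                pop_of_acc[start + j] = pop
        start += sz

    # --- genotypes: Markov copying along each chromosome -----------------
    rng_geno = config.rng(5)
    geno = np.empty((n, m))
    p_acc = pop_freq[pop_of_acc, :]  # (n, m) per-accession frequencies
    j = 0
    for c, k_c in zip(CHROMOSOMES, per_chrom):
        prev = None
        for local in range(k_c):
            fresh = (rng_geno.random(n) < p_acc[:, j]).astype(float)
            if local == 0 or config.tau_cm <= 0:
                geno[:, j] = fresh
            else:
                d = positions[j] - positions[j - 1]
                rho = math.exp(-d / config.tau_cm)
                copy = rng_geno.random(n) < rho
                geno[:, j] = np.where(copy, prev, fresh)
            # planted monomorphic states override the copy process
            for s in sub_names:
                if np.any(planted_mono[s] == j):
                    mask = sub_labels == s
                    geno[mask, j] = p_acc[mask, j]
            prev = geno[:, j]
            j += 1

    # --- realized monomorphic truth (pre-missingness) --------------------
    mono = pd.DataFrame(index=marker_ids, columns=sub_names, dtype=bool)
    state = pd.DataFrame("NA", index=marker_ids, columns=sub_names)
    for s in sub_names:
        sub_geno = geno[sub_labels == s]
        fixed1 = np.all(sub_geno == 1.0, axis=0)
        fixed0 = np.all(sub_geno == 0.0, axis=0)
        mono[s] = fixed0 | fixed1
        state.loc[fixed1, s] = "1"
        state.loc[fixed0, s] = "0"

    qtl_rows = []
    qtl_genotypes = {}
    for q in config.qtls:
        idx = q.marker if isinstance(q.marker, int) else marker_ids.index(q.marker)
        mk = marker_ids[idx]
        qtl_genotypes[mk] = geno[:, idx].copy()
        seg_mask = sub_labels == q.subspecies
        p_seg = geno[seg_mask, idx].mean()
        if p_seg in (0.0, 1.0):
            raise ValueError(
                f"planted QTL marker {mk} is monomorphic in {q.subspecies}"
            )
        qtl_rows.append(
            {
                "marker": mk,
                "trait": q.trait,
                "subspecies": q.subspecies,
                "qualitative": q.qualitative,
                "target_r2": q.target_r2,
                "band_freq_segregating": p_seg,
            }
        )
    qtls = pd.DataFrame(
        qtl_rows,
        columns=[
            "marker",
            "trait",
            "subspecies",
            "qualitative",
            "target_r2",
            "band_freq_segregating",
        ],
    )

    # --- missingness ------------------------------------------------------
    rng_miss = config.rng(6)
    n_missing = np.zeros(m, dtype=int)
    if config.missing_enabled:
        qtl_idx = {
            q.marker if isinstance(q.marker, int) else marker_ids.index(q.marker)
            for q in config.qtls
        }
        n_high = int(round(config.missing_high_fraction * m))
        eligible = np.setdiff1d(np.arange(m), np.array(sorted(qtl_idx), dtype=int))
        high = set(rng_miss.choice(eligible, size=min(n_high, eligible.size),
                                   replace=False).tolist())
        lo_max = max(int(math.floor(0.049 * n)) - 1, 0)
        hi_min = int(math.ceil(0.05 * n))
        hi_max = min(int(math.floor(0.15 * n)), n - 1)
        for jdx in range(m):
            if jdx in high:
                cnt = int(rng_miss.integers(hi_min, hi_max + 1))
            else:
                cnt = int(rng_miss.integers(0, lo_max + 1))
            if cnt:
                cells = rng_miss.choice(n, size=cnt, replace=False)
                geno[cells, jdx] = np.nan
            n_missing[jdx] = cnt
    missingness = pd.DataFrame(
        {
            "n_missing": n_missing,
            "missing_fraction": n_missing / n,
            "passes_filter": (n_missing / n) < 0.05,
        },
        index=marker_ids,
    )

    # --- Q matrix: true membership softened by Dirichlet jitter -----------
    rng_q = config.rng(7)
    alpha = np.full((n, config.n_populations), 0.5)
    alpha[np.arange(n), pop_of_acc] += config.q_concentration
    q_matrix = np.vstack([rng_q.dirichlet(a) for a in alpha])

    # --- hide the map for the unmapped fraction ---------------------------
    rng_hide = config.rng(8)
    n_mapped = int(round(config.mapped_fraction * m))
    mapped_idx = set(
        rng_hide.choice(m, size=n_mapped, replace=False).tolist()
    )
    out_chroms = np.array(
        [c if j in mapped_idx else "NA" for j, c in enumerate(chroms)], dtype=object
    )
    out_pos = np.array(
        [p if j in mapped_idx else np.nan for j, p in enumerate(positions)]
    )

    dataset = MarkerDataset(
        accession_ids=accession_ids,
        subspecies=sub_labels,
        genotypes=geno,
        marker_ids=marker_ids,
        chromosomes=out_chroms,
        positions=out_pos,
        q_matrix=q_matrix,
    )
    ledger = TruthLedger(
        monomorphic=mono,
        fixed_state=state,
        missingness=missingness,
        qtls=qtls,
        qtl_genotypes=qtl_genotypes,
    )
    return dataset, ledger


# ---------------------------------------------------------------------------
# field trials
# ---------------------------------------------------------------------------


def _qtl_beta(target_r2: float, var_x: float, sigma2_rest: float) -> float:
    """Effect size hitting a target plot-level R2 given background variance."""
    return math.sqrt(target_r2 / (1.0 - target_r2) * sigma2_rest / var_x)


def generate_trial(
    dataset: MarkerDataset, config: SimConfig, ledger: TruthLedger | None = None
) -> TrialData:
    """Simulate augmented-design field trials for the configured traits.

    Per environment each accession occupies exactly one plot; the
    remaining grid cells hold the repeated checks.  Plot values are
    mu_env + subspecies x environment shift + genetic value + row +
    column + residual with the configured variances.  If *ledger* is
    given, realized per-environment QTL R2 values and the latent genetic
    values are recorded in it.
    """
    n = dataset.n_accessions
    total_plots = config.n_rows * config.n_cols
    n_check_plots = total_plots - n
    if n_check_plots < 2 * config.n_checks:
        raise ValueError(
            f"layout {config.n_rows}x{config.n_cols} too small for {n} entries "
            f"plus {config.n_checks} checks replicated at least twice"
        )
    check_ids = [f"check_{i + 1}" for i in range(config.n_checks)]

    rng = config.rng(9)
    sub_labels = dataset.subspecies
    sub_names = list(dict.fromkeys(sub_labels.tolist()))

    sigma2_rest = (
        config.sigma2_acc + config.sigma2_row + config.sigma2_col + config.sigma2_e
    )

    # latent genetic values per quantitative trait
    qtl_by_trait: dict[str, list[tuple[str, PlantedQTL]]] = {}
    for q in config.qtls:
        mk = q.marker if isinstance(q.marker, str) else dataset.marker_ids[q.marker]
        qtl_by_trait.setdefault(q.trait, []).append((mk, q))

    def marker_column(mk: str) -> np.ndarray:
        if ledger is not None and mk in ledger.qtl_genotypes:
            return ledger.qtl_genotypes[mk]
        col = dataset.genotypes[:, dataset.marker_ids.index(mk)].copy()
        col[np.isnan(col)] = np.nanmean(col)
        return col

    genetic = {}
    betas: dict[tuple[str, str], float] = {}
    for trait in config.quant_traits:
        g = math.sqrt(config.sigma2_acc) * rng.standard_normal(n)
        for mk, q in qtl_by_trait.get(trait, []):
            if q.qualitative:
                continue
            x = marker_column(mk)
            seg = sub_labels == q.subspecies
            var_x = x[seg].var()
            if var_x == 0:
                raise ValueError(f"QTL marker {mk} monomorphic in {q.subspecies}")
            beta = _qtl_beta(q.target_r2, var_x, sigma2_rest)
            betas[(mk, trait)] = beta
            g = g + beta * x
        genetic[trait] = g
    check_effects = {
        trait: math.sqrt(config.sigma2_acc) * rng.standard_normal(config.n_checks)
        for trait in config.quant_traits
    }

    sub_env_shift = {
        (s, e): math.sqrt(config.sigma2_sub_env) * rng.standard_normal()
        for s in sub_names
        for e in config.environments
    }

    records = []
    var_rows = []
    for env in config.environments:
        mu = config.env_means.get(env, 0.0)
        # layout: a fresh randomization per environment
        order = rng.permutation(total_plots)
        entry_plots = order[:n]
        check_plots = order[n:]
        plot_entry = np.empty(total_plots, dtype=object)
        plot_entry[entry_plots] = dataset.accession_ids
        for i, p in enumerate(check_plots):
            plot_entry[p] = check_ids[i % config.n_checks]
        row_of = np.arange(total_plots) // config.n_cols
        col_of = np.arange(total_plots) % config.n_cols
        row_eff = math.sqrt(config.sigma2_row) * rng.standard_normal(config.n_rows)
        col_eff = math.sqrt(config.sigma2_col) * rng.standard_normal(config.n_cols)
        for trait in config.quant_traits:
            resid = math.sqrt(config.sigma2_e) * rng.standard_normal(total_plots)
            acc_values = np.array(
                [
                    genetic[trait][i] + sub_env_shift[(sub_labels[i], env)]
                    for i in range(n)
                ]
            )
            var_rows.append(
                {
                    "trait": trait,
                    "environment": env,
                    "realized_var_row": float(np.var(row_eff, ddof=1)),
                    "realized_var_col": float(np.var(col_eff, ddof=1)),
                    "realized_var_acc": float(np.var(acc_values, ddof=1)),
                    "realized_var_e": float(np.var(resid, ddof=1)),
                }
            )
            acc_index = {a: i for i, a in enumerate(dataset.accession_ids)}
            for p in range(total_plots):
                entry = plot_entry[p]
                if entry in acc_index:
                    i = acc_index[entry]
                    g = genetic[trait][i] + sub_env_shift[(sub_labels[i], env)]
                    is_check = False
                else:
                    g = check_effects[trait][check_ids.index(entry)]
                    is_check = True
                records.append(
                    {
                        "environment": env,
                        "row": int(row_of[p]) + 1,
                        "col": int(col_of[p]) + 1,
                        "entry": entry,
                        "is_check": is_check,
                        "trait": trait,
                        "value": mu + g + row_eff[row_of[p]] + col_eff[col_of[p]]
                        + resid[p],
                    }
                )

    # qualitative traits: latent threshold model, scored once (first env)
    qual_env = config.environments[0]
    thresholds = _class_thresholds(np.asarray(config.qual_class_props))
    for trait in config.qual_traits:
        latent = rng.standard_normal(n)
        for mk, q in qtl_by_trait.get(trait, []):
            x = marker_column(mk)
            seg = sub_labels == q.subspecies
            var_x = x[seg].var()
            if var_x == 0:
                raise ValueError(f"QTL marker {mk} monomorphic in {q.subspecies}")
            latent = latent + _qtl_beta(q.target_r2, var_x, 1.0) * x
        classes = np.digitize((latent - latent.mean()) / latent.std(), thresholds)
        order = rng.permutation(total_plots)
        entry_plots = order[:n]
        check_plots = order[n:]
        row_of = np.arange(total_plots) // config.n_cols
        col_of = np.arange(total_plots) % config.n_cols
        for i, p in enumerate(entry_plots):
            records.append(
                {
                    "environment": qual_env,
                    "row": int(row_of[p]) + 1,
                    "col": int(col_of[p]) + 1,
                    "entry": dataset.accession_ids[i],
                    "is_check": False,
                    "trait": trait,
                    "value": f"class{int(classes[i]) + 1}",
                }
            )
        for i, p in enumerate(check_plots):
            records.append(
                {
                    "environment": qual_env,
                    "row": int(row_of[p]) + 1,
                    "col": int(col_of[p]) + 1,
                    "entry": check_ids[i % config.n_checks],
                    "is_check": True,
                    "trait": trait,
                    "value": "class1",
                }
            )

    trial = TrialData(records=pd.DataFrame(records), check_ids=check_ids)

    if ledger is not None:
        ledger.genetic_values = pd.DataFrame(
            genetic, index=dataset.accession_ids
        )
        ledger.variance_truth = pd.DataFrame(var_rows)
        df = trial.records
        for env in config.environments:
            col = f"realized_r2_{env}"
            vals = []
            for _, qrow in ledger.qtls.iterrows():
                if qrow["qualitative"]:
                    vals.append(np.nan)
                    continue
                sel = df[
                    (df["environment"] == env)
                    & (df["trait"] == qrow["trait"])
                    & (~df["is_check"])
                ]
                y = (
                    sel.set_index("entry")["value"]
                    .astype(float)
                    .reindex(dataset.accession_ids)
                    .to_numpy()
                )
                x = marker_column(qrow["marker"])
                seg = sub_labels == qrow["subspecies"]
                vals.append(_ols_r2(x[seg], y[seg]))
            if len(ledger.qtls):
                ledger.qtls[col] = vals
    return trial


def _class_thresholds(props: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    cum = np.cumsum(props)[:-1]
    return norm.ppf(cum)


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or x.var() == 0 or y.var() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
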