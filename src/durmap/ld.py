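"""Pairwise linkage disequilibrium, permutation significance and extent.

LD between two dominant 0/1 markers is the Pearson correlation r of the
band columns over pairwise-complete accessions; R^2 = r^2 is the
thresholded quantity.  Pairs on the same known chromosome are syntenic
(with cM distance), pairs on different known chromosomes are unlinked,
anything involving an unmapped marker is unknown and excluded from both
classes.

The collection-level critical R^2 follows the square-root-transform
recipe: sqrt(R^2) of unlinked pairs is treated as approximately normal
and the parametric 95th percentile, squared back, is the critical
value.  The extent of LD is the distance at which a loess curve fit to
syntenic R^2 versus distance falls to that baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerDataset

Z_95 = 1.6449  # parametric 95th percentile of the standard normal

MIN_COMPLETE = 20  # minimum pairwise-complete accessions per pair


@dataclass
class ExtentResult:
    """Loess-intersection estimate of the extent of LD."""

    extent_cm: float
    estimable: bool
    grid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)


@dataclass
class LDResult:
    """Pairwise LD statistics plus collection-level summaries.

    ``pairs`` has one row per unordered evaluable marker pair with
    columns marker_i, marker_j, r, r2, distance_cm (NaN unless
    syntenic), linkage_class and, when computed, perm_p.
    ``grid_count`` is the size of the full ordered pair grid including
    self-pairs (the bookkeeping convention of the emulated analysis);
    statistics are computed once per unordered pair.
    """

    pairs: pd.DataFrame
    grid_count: int
    n_markers: int
    n_evaluated: int
    n_skipped: int
    median_r2: float
    critical_r2: float | None = None
    extent: ExtentResult | None = None


def _pairwise_corr(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r over pairwise-complete rows, with counts.

    Mask-aware cross products give, for every pair (i, j), the complete
    count and the moments needed for r without looping over pairs.
    """
    present = ~np.isnan(geno)
    a = np.where(present, geno, 0.0)
    b = present.astype(float)
    n = b.T @ b
    sx = a.T @ b  # sum of x over rows complete in (i, j): (i, j) entry
    sy = sx.T
    sxy = a.T @ a
    sxx = (a * a).T @ b
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        denom = np.sqrt(varx * vary)
        r = np.where(denom > 0, cov / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return r, n


def pairwise_ld(dataset: MarkerDataset, mapped_only: bool = True) -> LDResult:
    """Compute LD over all unordered marker pairs.

    With ``mapped_only`` (the default) only markers with a known map
    position enter, mirroring an analysis restricted to the mapped
    marker subset.  Pairs with fewer than 20 pairwise-complete
    accessions or a zero-variance column in the complete subset are
    skipped and counted as non-evaluable.
    """
    mapped = ~np.isnan(dataset.positions)
    idx = np.flatnonzero(mapped) if mapped_only else np.arange(dataset.n_markers)
    if idx.size < 2:
        raise ValueError("need at least two markers for pairwise LD")
    geno = dataset.genotypes[:, idx]
    ids = [dataset.marker_ids[j] for j in idx]
    chroms = np.asarray(dataset.chromosomes, dtype=object)[idx]
    pos = dataset.positions[idx]

    r, n = _pairwise_corr(geno)
    m = idx.size
    iu, ju = np.triu_indices(m, k=1)
    rr = r[iu, ju]
    nn = n[iu, ju]
    ok = (nn >= MIN_COMPLETE) & ~np.isnan(rr)

    ci, cj = chroms[iu], chroms[ju]
    known_i = ci != "NA"
    known_j = cj != "NA"
    cls = np.full(iu.shape, "unknown", dtype=object)
    same = known_i & known_j & (ci == cj)
    diff = known_i & known_j & (ci != cj)
    cls[same] = "syntenic"
    cls[diff] = "unlinked"
    dist = np.where(same, np.abs(pos[iu] - pos[ju]), np.nan)

    pairs = pd.DataFrame(
        {
            "marker_i": np.asarray(ids, dtype=object)[iu[ok]],
            "marker_j": np.asarray(ids, dtype=object)[ju[ok]],
            "r": rr[ok],
            "r2": rr[ok] ** 2,
            "distance_cm": dist[ok],
            "linkage_class": cls[ok],
            "n_complete": nn[ok].astype(int),
        }
    )
    return LDResult(
        pairs=pairs,
        grid_count=m * m,
        n_markers=m,
        n_evaluated=int(ok.sum()),
        n_skipped=int((~ok).sum()),
        median_r2=float(np.median(pairs["r2"])) if len(pairs) else np.nan,
    )


def permutation_p(
    col_i: np.ndarray,
    col_j: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the R^2 of two marker columns.

    One column is permuted across accessions ``n_perm`` times;
    p = (1 + #{permuted R^2 >= observed R^2}) / (n_perm + 1).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(col_i, dtype=float)
    y = np.asarray(col_j, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("both columns must be variable")
    obs = np.corrcoef(x, y)[0, 1] ** 2
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    nn = x.size
    perms = np.argsort(rng.random((n_perm, nn)), axis=1)
    r_perm = (yc[perms] @ xc) / nn
    exceed = int(np.sum(r_perm**2 >= obs - 1e-15))
    return (1 + exceed) / (n_perm + 1)


def critical_r2(unlinked_r2: np.ndarray) -> float:
    """Critical R^2 from the unlinked-pair distribution.

    sqrt(R^2) is treated as normal; the parametric 95th percentile
    (mean + 1.6449 sd), squared back, is the population-specific
    critical value beyond which LD is likely due to linkage.  With
    fewer than 30 unlinked pairs the empirical 95th percentile of R^2
    is used instead (with a warning).
    """
    v = np.asarray(unlinked_r2, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 30:
        warnings.warn(
            "fewer than 30 unlinked pairs; falling back to empirical percentile",
            stacklevel=2,
        )
        return float(np.percentile(v, 95)) if v.size else np.nan
    root = np.sqrt(v)
    return float((root.mean() + Z_95 * root.std(ddof=1)) ** 2)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.5,
    degree: int = 2,
    robustness_iters: int = 3,
) -> np.ndarray:
    """Locally weighted polynomial smoother (tricube weights).

    ``span`` is the fraction of points in each local neighbourhood;
    robustness iterations downweight outliers with bisquare weights on
    the residuals, as in classical loess.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    nn = x.size
    k = max(int(np.ceil(span * nn)), degree + 2)
    k = min(k, nn)

    robust_w = np.ones(nn)

    def fit_at(points: np.ndarray) -> np.ndarray:
        out = np.empty(points.size)
        for t, x0 in enumerate(points):
            d = np.abs(x - x0)
            cut = np.partition(d, k - 1)[k - 1]
            sel = d <= cut if cut > 0 else d <= np.finfo(float).eps
            h = max(cut, np.finfo(float).tiny)
            w = (1 - np.clip(d[sel] / h, 0, 1) ** 3) ** 3
            w = w * robust_w[sel]
            if w.sum() <= 0 or sel.sum() <= degree:
                out[t] = np.nan
                continue
            xs = x[sel] - x0
            basis = np.vander(xs, degree + 1, increasing=True)
            wsq = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(basis * wsq[:, None], y[sel] * wsq, rcond=None)
            out[t] = coef[0]
        return out

    for _ in range(robustness_iters):
        fitted = fit_at(x)
        resid = y - fitted
        s = np.median(np.abs(resid[~np.isnan(resid)]))
        if s <= 0:
            break
        robust_w = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
        robust_w[np.isnan(robust_w)] = 0.0
    return fit_at(np.asarray(x_eval, dtype=float))


def ld_extent(
    distances: np.ndarray,
    r2: np.ndarray,
    threshold: float,
    span: float = 0.5,
    degree: int = 2,
    grid_step: float = 0.1,
    robustness_iters: int = 3,
) -> ExtentResult:
    """Extent of LD: first loess-curve crossing of the critical R^2.

    The smoothed R^2-versus-distance curve is evaluated on a grid and
    the extent is the linearly interpolated distance of the first
    downward crossing of ``threshold``.  A curve starting below the
    threshold gives extent 0; a curve that never crosses is flagged
    not-estimable (the fitted curve is still returned).
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(r2, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(v))
    d, v = d[ok], v[ok]
    if d.size < 50 or np.unique(d).size < 2:
        return ExtentResult(np.nan, False, np.array([]), np.array([]))
    grid = np.arange(d.min(), d.max() + grid_step, grid_step)
    fitted = loess_fit(d, v, grid, span=span, degree=degree,
                       robustness_iters=robustness_iters)
    valid = ~np.isnan(fitted)
    grid, fitted = grid[valid], fitted[valid]
    if fitted.size == 0:
        return ExtentResult(np.nan, False, grid, fitted)
    if fitted[0] < threshold:
        return ExtentResult(0.0, True, grid, fitted)
    below = np.flatnonzero(fitted < threshold)
    if below.size == 0:
        return ExtentResult(float(grid[-1]), False, grid, fitted)
    j = below[0]
    x0, x1 = grid[j - 1], grid[j]
    y0, y1 = fitted[j - 1], fitted[j]
    extent = x0 + (y0 - threshold) / (y0 - y1) * (x1 - x0)
    return ExtentResult(float(extent), True, grid, fitted)


def analyze_ld(
    dataset: MarkerDataset,
    n_perm: int = 1000,
    seed: int = 0,
    span: float = 0.5,
    degree: int = 2,
    grid_step: float = 0.1,
    with_permutations: bool = True,
) -> LDResult:
    """Full LD analysis: pairwise r, permutation p, critical R^2, extent."""
    res = pairwise_ld(dataset, mapped_only=True)
    if with_permutations and len(res.pairs):
        rng = np.random.default_rng(seed)
        mk_index = {mk: j for j, mk in enumerate(dataset.marker_ids)}
        pvals = np.empty(len(res.pairs))
        for t, row in enumerate(res.pairs.itertuples(index=False)):
            pvals[t] = permutation_p(
                dataset.genotypes[:, mk_index[row.marker_i]],
                dataset.genotypes[:, mk_index[row.marker_j]],
                n_perm=n_perm,
                seed=rng,
            )
        res.pairs["perm_p"] = pvals
    unlinked = res.pairs.loc[res.pairs["linkage_class"] == "unlinked", "r2"]
    res.critical_r2 = critical_r2(unlinked.to_numpy()) if len(unlinked) else np.nan
    syn = res.pairs[res.pairs["linkage_class"] == "syntenic"]
    if len(syn) >= 50 and not np.isnan(res.critical_r2):
        res.extent = ld_extent(
            syn["distance_cm"].to_numpy(),
            syn["r2"].to_numpy(),
            res.critical_r2,
            span=span,
            degree=degree,
            grid_step=grid_step,
        )
    return res


def plot_decay(res: LDResult, path) -> None:
    """Scatter of syntenic R^2 vs distance with the loess curve and baseline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    syn = res.pairs[res.pairs["linkage_class"] == "syntenic"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(syn["distance_cm"], syn["r2"], s=4, alpha=0.3, label="syntenic pairs")
    if res.extent is not None and res.extent.grid.size:
        ax.plot(res.extent.grid, res.extent.fitted, "r-", label="loess")
    if res.critical_r2 is not None and not np.isnan(res.critical_r2):
        ax.axhline(res.critical_r2, ls="--", c="k", label="critical $R^2$")
    ax.set_xlabel("distance (cM)")
    ax.set_ylabel("$R^2$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
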