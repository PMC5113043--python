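"""REML mixed-model fits for augmented field designs, and BLUPs.

The per-environment model for one quantitative trait is

    y = X beta + Z_r u_r + Z_c u_c + Z_a u_a + e,

with fixed intercept and check contrasts in X, independent random row,
column and accession effects with variances (s2_row, s2_col, s2_acc)
and residual variance s2_e.  The REML criterion is maximized over the
log-variances with a Nelder-Mead scheme; BLUPs of the accession effects
are solved at the optimum from the mixed-model equations (equivalently
the conditional mean under the fitted covariance).

The reported accession value is intercept + accession BLUP, comparable
across accessions; check effects are fixed and excluded from the
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import TrialData

_LOG_FLOOR = -12.0  # standardized log-variance below this flags a boundary


@dataclass
class VarianceComponents:
    sigma2_row: float
    sigma2_col: float
    sigma2_acc: float
    sigma2_e: float
    reml_loglik: float
    converged: bool
    boundary: dict[str, bool]

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_row": self.sigma2_row,
            "sigma2_col": self.sigma2_col,
            "sigma2_acc": self.sigma2_acc,
            "sigma2_e": self.sigma2_e,
        }


@dataclass
class BlupSet:
    """Predicted accession values for one (trait, environment)."""

    trait: str
    environment: str
    intercept: float
    #: per-accession random-effect prediction (mean ~ 0)
    effects: pd.Series
    #: prediction-error variance of each accession effect
    pev: pd.Series
    #: fitted fixed check effects (deviation from intercept)
    check_effects: pd.Series

    @property
    def predicted(self) -> pd.Series:
        """Intercept + accession BLUP, the reported phenotypic value."""
        return self.intercept + self.effects


def _design(df: pd.DataFrame):
    """Build y, X (intercept + check contrasts) and the three Z matrices."""
    y = df["value"].astype(float).to_numpy()
    n = len(df)
    checks = sorted(df.loc[df["is_check"], "entry"].unique())
    X = np.ones((n, 1 + len(checks)))
    for k, c in enumerate(checks):
        X[:, 1 + k] = (df["entry"] == c).to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (check contrasts collinear)")

    def indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
        levels = sorted(labels.unique())
        Z = np.zeros((n, len(levels)))
        for k, lv in enumerate(levels):
            Z[:, k] = (labels == lv).to_numpy(dtype=float)
        return Z, levels

    Zr, rows = indicator(df["row"])
    Zc, cols = indicator(df["col"])
    acc_labels = df["entry"].where(~df["is_check"], other=np.nan)
    acc_levels = sorted(acc_labels.dropna().unique())
    Za = np.zeros((n, len(acc_levels)))
    for k, a in enumerate(acc_levels):
        Za[:, k] = (acc_labels == a).to_numpy(dtype=float)
    return y, X, [Zr, Zc, Za], acc_levels, checks


def reml_loglik(
    y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], variances: np.ndarray
) -> float:
    """Restricted log-likelihood at the given (s2_row, s2_col, s2_acc, s2_e)."""
    n = y.size
    V = variances[3] * np.eye(n)
    for s2, Z in zip(variances[:3], Zs):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = resid @ np.linalg.solve(V, resid)
    p = X.shape[1]
    return -0.5 * (logdet_v + logdet_x + quad) - 0.5 * (n - p) * np.log(2 * np.pi)


def solve_blups(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    variances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS fixed effects and accession BLUPs at known variances.

    Returns (beta, u_acc, pev_acc) where u_acc = s2_acc Za' V^{-1}
    (y - X beta) and pev is the diagonal of s2_acc I - s2_acc^2 Za'PZa.
    """
    n = y.size
    s2_e = max(variances[3], 1e-10)
    V = s2_e * np.eye(n)
    for s2, Z in zip(variances[:3], Zs):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    Za = Zs[2]
    s2a = variances[2]
    u = s2a * Za.T @ Vi @ (y - X @ beta)
    pev = s2a - np.einsum("ij,jk,ki->i", s2a * Za.T, P, Za * s2a)
    return beta, u, np.clip(pev, 0.0, None)


def fit_augmented_reml(
    trial: TrialData,
    trait: str,
    environment: str,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[VarianceComponents, BlupSet]:
    """Fit the augmented-design mixed model by REML for one trait/environment.

    Non-convergence after ``max_iter`` evaluations is flagged on the
    result, not raised.  Zero-variance traits return all-zero variance
    components and constant BLUPs.
    """
    df = trial.subset(trait, environment)
    if len(df) == 0:
        raise ValueError(f"no records for trait {trait!r} in {environment!r}")
    if df.loc[df["is_check"]].shape[0] < 2:
        raise ValueError("need at least 2 check plots")
    if df.loc[~df["is_check"], "entry"].nunique() < 3:
        raise ValueError("need at least 3 accessions")
    y, X, Zs, acc_levels, checks = _design(df)

    vy = float(np.var(y))
    if vy == 0.0:
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, True,
                                dict.fromkeys(("row", "col", "acc", "e"), True))
        zero = pd.Series(0.0, index=acc_levels)
        return vc, BlupSet(trait, environment, float(y[0]), zero, zero.copy(),
                           pd.Series(0.0, index=checks))

    theta0 = np.log(np.full(4, vy / 4.0))

    def negloglik(theta: np.ndarray) -> float:
        return -reml_loglik(y, X, Zs, np.exp(np.clip(theta, -30, 30)))

    opt = minimize(
        negloglik,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "fatol": tol, "xatol": 1e-6, "maxfev": 4 * max_iter},
    )
    variances = np.exp(np.clip(opt.x, -30, 30))
    standardized = np.log(variances / vy)
    boundary = dict(zip(("row", "col", "acc", "e"), standardized < _LOG_FLOOR))
    variances = np.where(standardized < _LOG_FLOOR, 0.0, variances)

    vc = VarianceComponents(
        sigma2_row=float(variances[0]),
        sigma2_col=float(variances[1]),
        sigma2_acc=float(variances[2]),
        sigma2_e=float(variances[3]),
        reml_loglik=float(-opt.fun),
        converged=bool(opt.success),
        boundary=boundary,
    )
    beta, u, pev = solve_blups(y, X, Zs, variances)
    blups = BlupSet(
        trait=trait,
        environment=environment,
        intercept=float(beta[0]),
        effects=pd.Series(u, index=acc_levels),
        pev=pd.Series(pev, index=acc_levels),
        check_effects=pd.Series(beta[1:], index=checks),
    )
    return vc, blups


def blups_to_table(blup_sets: list[BlupSet]) -> pd.DataFrame:
    """Wide accession x (trait, environment) table of predicted values.

    Cells are NaN where an accession was absent from an environment.
    Conflicting duplicate (trait, environment) entries raise.
    """
    seen = set()
    cols = {}
    for b in blup_sets:
        key = (b.trait, b.environment)
        if key in seen:
            raise ValueError(f"duplicate BLUP set for {key}")
        seen.add(key)
        cols[key] = b.predicted
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["trait", "environment"])
    return table.sort_index()


def write_blup_table(table: pd.DataFrame, path) -> None:
    flat = table.copy()
    flat.columns = [f"{t}:{e}" for t, e in flat.columns]
    flat.insert(0, "accession", flat.index)
    flat.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_blup_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df = df.set_index("accession")
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns],
        names=["trait", "environment"],
    )
    return df
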