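"""Supporting trait statistics.

Carbon isotope discrimination transforms, subspecies x environment
ANOVA (Type II sums of squares, appropriate for the very unbalanced
subspecies sizes) and normality-gated trait correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DELTA_AIR_PERMIL = -8.0  # current deviation of free atmospheric CO2 (PDB scale)


def delta13c_from_ratio(r_grain: float, r_standard: float) -> float:
    """Stable carbon isotope composition in per mil.

    delta13C = (R_grain / R_standard - 1) * 1000, R being the 13C/12C
    ratio against the PDB standard.
    """
    if r_grain <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_grain / r_standard - 1.0) * 1000.0


def ratio_from_delta13c(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta13c_from_ratio`."""
    return r_standard * (delta / 1000.0 + 1.0)


def discrimination(delta_s: float, delta_a: float = DELTA_AIR_PERMIL) -> float:
    """Carbon isotope discrimination in per mil.

    Delta13C = (delta_a - delta_s) / (1 + delta_s / 1000); both deltas
    are in per mil, hence the per-mil-aware denominator (the only
    reading that produces plant-material values around 17 per mil from
    grain delta around -25).
    """
    return (delta_a - delta_s) / (1.0 + delta_s / 1000.0)


@dataclass
class AnovaTable:
    """Two-way ANOVA decomposition for one trait."""

    table: pd.DataFrame  # index: subspecies, environment, interaction, residual
    interaction_dropped: bool = False

    def __getitem__(self, row: str) -> pd.Series:
        return self.table.loc[row]


def two_way_anova(
    values: np.ndarray | pd.Series,
    subspecies: np.ndarray | pd.Series,
    environment: np.ndarray | pd.Series,
) -> AnovaTable:
    """Unbalanced two-way ANOVA with interaction, Type II sums of squares.

    F statistics test each term against the residual mean square.  When
    some subspecies x environment cell is empty the interaction is
    dropped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "sub": np.asarray(subspecies, dtype=object),
            "env": np.asarray(environment, dtype=object),
        }
    ).dropna()
    if df["sub"].nunique() < 2 or df["env"].nunique() < 2:
        raise ValueError("need at least 2 levels of each factor")
    counts = df.groupby(["sub", "env"]).size().unstack(fill_value=0)
    dropped = (counts.to_numpy() == 0).any()
    if df["y"].nunique() == 1:
        idx = ["subspecies", "environment"] + ([] if dropped else ["interaction"])
        idx += ["residual"]
        tbl = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": np.nan, "p": np.nan}, index=idx
        )        # degenerate constant response: all SS zero by definition
        n = len(df)
        tbl.loc["residual", "df"] = n - df["sub"].nunique() * df["env"].nunique()
        return AnovaTable(table=tbl, interaction_dropped=bool(dropped))
    if dropped:
        warnings.warn(
            "empty subspecies x environment cell; interaction dropped",
            stacklevel=2,
        )
        model = smf.ols("y ~ C(sub) + C(env)", data=df).fit()
    else:
        model = smf.ols("y ~ C(sub) * C(env)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {"C(sub)": "subspecies", "C(env)": "environment",
              "C(sub):C(env)": "interaction", "Residual": "residual"}
    aov = aov.rename(index=rename)
    aov = aov.rename(columns={"PR(>F)": "p"})
    return AnovaTable(table=aov[["sum_sq", "df", "F", "p"]],
                      interaction_dropped=bool(dropped))


def correlation_matrix(
    table: pd.DataFrame, alpha_normal: float = 0.05, min_pairs: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise trait correlations with a normality gate.

    Per pair of columns (pairwise-complete): Shapiro-Wilk on both
    variables at ``alpha_normal``; Pearson when both pass, Spearman
    otherwise.  Returns (correlations, p-values, methods); constant
    variables or pairs with fewer than ``min_pairs`` complete rows give
    NaN cells with method 'NA'.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    method = pd.DataFrame("self", index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = table[[a, b]].dropna()
            if len(sub) < min_pairs or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                method.loc[a, b] = method.loc[b, a] = "NA"
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = (
                    stats.shapiro(sub[a]).pvalue > alpha_normal
                    and stats.shapiro(sub[b]).pvalue > alpha_normal
                )
            if normal:
                rv, pv = stats.pearsonr(sub[a], sub[b])
                meth = "pearson"
            else:
                rv, pv = stats.spearmanr(sub[a], sub[b])
                meth = "spearman"
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
            method.loc[a, b] = method.loc[b, a] = meth
    return r, p, method
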