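"""Statistical procedures of the morphometric analysis.

LOESS curves of parameters against germline area (with bootstrap
confidence bands), genotype comparison by multiple linear regression with
a germline-size x genotype interaction term and a main-effects fallback
when the interaction is not significant, two-way ANOVA on critical-size
grouping with Sidak-corrected contrasts, and the linear regression of the
interface angle on Eya intensity whose 90-degree crossing estimates the
zero-affinity Eya level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "RegressionResult",
    "AngleEyaFit",
    "LoessFit",
    "loess_curve",
    "compare_genotypes",
    "critical_size_anova",
    "angle_vs_eya",
]


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    used_interaction: bool
    n: int
    formula: str = ""


@dataclass
class AngleEyaFit:
    slope: float  # degrees per arb. unit
    intercept: float  # degrees
    eya_at_90: float  # arb. unit (NaN when the slope is ~0)
    slope_se: float
    n: int
    undefined: bool = False

    def ci_band(self, eya: np.ndarray, level: float = 0.95) -> np.ndarray:
        """Pointwise CI half-width of the fitted line at the given Eya."""
        e = np.asarray(eya, dtype=float)
        tcrit = sps.t.ppf(0.5 + level / 2.0, max(self.n - 2, 1))
        x = self._x
        resid_var = self._resid_var
        xbar = x.mean()
        sxx = np.sum((x - xbar) ** 2)
        se = np.sqrt(resid_var * (1.0 / len(x) + (e - xbar) ** 2 / sxx))
        return tcrit * se

    _x: np.ndarray = None
    _resid_var: float = 0.0


@dataclass
class LoessFit:
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float
    level: float


def loess_curve(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    level: float = 0.95,
    n_grid: int = 100,
    n_boot: int = 200,
    seed: int = 0,
) -> LoessFit:
    """Locally weighted regression with a pointwise bootstrap CI band.

    The curve is evaluated on a uniform grid over the x-range; the CI is a
    residual-bootstrap percentile band (the smoother itself provides no
    analytic standard errors).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a LOESS curve")
    grid = np.linspace(x.min(), x.max(), n_grid)

    def fit_on(xs, ys):
        sm_out = lowess(ys, xs, frac=span, return_sorted=True)
        return np.interp(grid, sm_out[:, 0], sm_out[:, 1])

    fitted = fit_on(x, y)
    base_at_x = np.interp(x, grid, fitted)
    resid = y - base_at_x
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        yb = base_at_x + rng.choice(resid, size=resid.size, replace=True)
        boots[b] = fit_on(x, yb)
    alpha = 1.0 - level
    # centre the percentile band on the fit itself: the raw bootstrap centre
    # is the twice-smoothed curve, which carries extra smoothing bias
    dev = boots - boots.mean(axis=0)
    lo = fitted + np.quantile(dev, alpha / 2.0, axis=0)
    hi = fitted + np.quantile(dev, 1.0 - alpha / 2.0, axis=0)
    return LoessFit(grid=grid, fitted=fitted, ci_low=lo, ci_high=hi,
                    span=span, level=level)


def compare_genotypes(
    data: pd.DataFrame,
    response: str,
    size_col: str = "germline_area",
    genotype_col: str = "genotype",
    alpha: float = 0.05,
) -> RegressionResult:
    """Interaction regression of a parameter on germline size and genotype.

    Fits ``Y ~ size + genotype + size:genotype`` (genotype coded 0/1); when
    the interaction p-value is >= alpha the model is refitted without the
    interaction and the genotype main effect is reported.
    """
    levels = sorted(pd.unique(data[genotype_col]))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 genotype levels, got {levels}")
    df = data[[response, size_col, genotype_col]].dropna().copy()
    df["g"] = (df[genotype_col] == levels[1]).astype(float)
    df = df.rename(columns={response: "y", size_col: "size"})

    full = smf.ols("y ~ size + g + size:g", data=df).fit()
    p_int = float(full.pvalues["size:g"])
    if p_int < alpha:
        coefs = {
            "intercept": float(full.params["Intercept"]),
            "germline_size": float(full.params["size"]),
            "genotype": float(full.params["g"]),
            "germline_size:genotype": float(full.params["size:g"]),
        }
        pvals = {
            "intercept": float(full.pvalues["Intercept"]),
            "germline_size": float(full.pvalues["size"]),
            "genotype": float(full.pvalues["g"]),
            "germline_size:genotype": p_int,
        }
        return RegressionResult(
            coefficients=coefs,
            p_values=pvals,
            used_interaction=True,
            n=len(df),
            formula="Y ~ germline_size + genotype + germline_size:genotype",
        )
    reduced = smf.ols("y ~ size + g", data=df).fit()
    coefs = {
        "intercept": float(reduced.params["Intercept"]),
        "germline_size": float(reduced.params["size"]),
        "genotype": float(reduced.params["g"]),
    }
    pvals = {
        "intercept": float(reduced.pvalues["Intercept"]),
        "germline_size": float(reduced.pvalues["size"]),
        "genotype": float(reduced.pvalues["g"]),
        "germline_size:genotype": p_int,
    }
    return RegressionResult(
        coefficients=coefs,
        p_values=pvals,
        used_interaction=False,
        n=len(df),
        formula="Y ~ germline_size + genotype",
    )


def critical_size_anova(
    data: pd.DataFrame,
    critical_size: float,
    response: str,
    size_col: str = "germline_area",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Two-way ANOVA of size group (below / above critical) x genotype.

    Returns the ANOVA table augmented with Sidak-corrected per-group
    genotype contrasts (Welch t-tests within each size group).
    """
    df = data[[response, size_col, genotype_col]].dropna().copy()
    df["group"] = np.where(df[size_col] < critical_size, "below", "above")
    levels = sorted(pd.unique(df[genotype_col]))
    if len(levels) != 2:
        raise ValueError("need exactly 2 genotype levels")
    counts = df.groupby(["group", genotype_col]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("empty or near-empty group x genotype cell")

    df = df.rename(columns={response: "y", genotype_col: "geno"})
    model = smf.ols("y ~ C(group) * C(geno)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rows = []
    m = 2  # number of contrasts for the Sidak correction
    for grp in ("below", "above"):
        a = df.loc[(df["group"] == grp) & (df["geno"] == levels[0]), "y"]
        b = df.loc[(df["group"] == grp) & (df["geno"] == levels[1]), "y"]
        t, p = sps.ttest_ind(a, b, equal_var=False)
        p_adj = 1.0 - (1.0 - min(p, 1.0)) ** m
        rows.append(
            {
                "term": f"genotype within {grp}",
                "estimate": float(b.mean() - a.mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_sidak": float(p_adj),
            }
        )
    contrasts = pd.DataFrame(rows)
    table = table.reset_index().rename(columns={"index": "term"})
    table["p_sidak"] = np.nan
    out = pd.concat([table, contrasts], axis=0, ignore_index=True)
    return out


def angle_vs_eya(
    data: pd.DataFrame,
    angle_col: str = "interface_angle",
    eya_col: str = "eya_mean_at_ncob",
) -> AngleEyaFit:
    """OLS of interface angle on Eya; the 90-degree crossing solves the
    zero-affinity Eya level, flagged undefined when the slope vanishes."""
    df = data[[angle_col, eya_col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 (Eya, angle) pairs")
    x = df[eya_col].to_numpy(float)
    y = df[angle_col].to_numpy(float)
    res = sps.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    undefined = abs(slope) < 1e-12 or (
        np.isfinite(res.stderr) and abs(slope) < 2.0 * float(res.stderr) * 1e-6
    )
    eya_at_90 = float("nan") if abs(slope) < 1e-12 else (90.0 - intercept) / slope
    fit = AngleEyaFit(
        slope=slope,
        intercept=intercept,
        eya_at_90=float(eya_at_90),
        slope_se=float(res.stderr),
        n=len(df),
        undefined=bool(abs(slope) < 1e-12),
    )
    fit._x = x
    resid = y - (intercept + slope * x)
    fit._resid_var = float(resid @ resid / max(len(x) - 2, 1))
    return fit
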