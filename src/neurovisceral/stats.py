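"""Group-comparison and correlation-network statistics.

The statistical layer mirrors common practice for case-control
psychophysiology tables: iterative studentized-residual outlier masking
(Bonferroni-guarded, the ``car::outlierTest`` procedure), Shapiro-Wilk
screening to choose between an ordinary linear model and a gamma GLM with
log link for positively skewed outcomes (spectral powers, path lengths),
group contrasts with IQ as covariate and partial eta-squared effect sizes,
a condition-index collinearity guard (threshold 30), and per-group Spearman
correlation networks with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

__all__ = [
    "GroupComparisonResult",
    "CorrelationNetworkResult",
    "CollinearDesignError",
    "remove_outliers",
    "choose_model",
    "group_contrast",
    "pooled_t_from_summary",
    "partial_eta_squared",
    "condition_index",
    "bh_adjust",
    "spearman_fdr",
]

ALPHA = 0.05
CONDITION_INDEX_LIMIT = 30.0


class CollinearDesignError(ValueError):
    """Raised when the covariate design is too collinear to use."""


@dataclass
class GroupComparisonResult:
    variable: str
    model: str  # "linear" or "gamma-glm"
    t: float
    p: float
    eta_p2: float
    df_resid: float
    covariates: tuple
    n_case: int
    n_control: int


@dataclass
class CorrelationNetworkResult:
    edges: pd.DataFrame  # var_i, var_j, r, p, p_fdr, kept
    group: str | None = None


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------

def remove_outliers(
    table: pd.DataFrame,
    variables: list,
    alpha: float = ALPHA,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively mask extreme observations per variable.

    For each variable the largest-magnitude externally studentized residual
    from a group-means model (or intercept model if no group column) is
    tested against a Bonferroni-corrected two-sided threshold; while
    significant at ``alpha``, that cell is set to NaN and the test repeats.
    Masking is cell-wise: a subject flagged on HF keeps their other values.

    Returns the masked table and a removal log (variable, id, value, p).
    """
    out = table.copy()
    log_rows = []
    for var in variables:
        n0 = out[var].notna().sum()
        if n0 < 10:
            raise ValueError(f"need >= 10 observations for {var}")
        while True:
            mask = out[var].notna()
            y = out.loc[mask, var].astype(float)
            if group_col in out.columns:
                X = pd.get_dummies(
                    out.loc[mask, group_col], drop_first=True, dtype=float
                )
                X = sm.add_constant(X)
            else:
                X = pd.DataFrame({"const": np.ones(mask.sum())}, index=y.index)
            res = sm.OLS(y, X).fit()
            test = res.outlier_test(method="bonf")
            worst = test["bonf(p)"].idxmin()
            if test.loc[worst, "bonf(p)"] < alpha:
                log_rows.append(
                    {
                        "variable": var,
                        "index": worst,
                        "value": out.loc[worst, var],
                        "bonf_p": float(test.loc[worst, "bonf(p)"]),
                    }
                )
                out.loc[worst, var] = np.nan
            else:
                break
        n_masked = n0 - out[var].notna().sum()
        if n_masked > 0.2 * n0:
            warnings.warn(f"heavy-tailed variable: >20% of {var} masked")
    return out, pd.DataFrame(log_rows, columns=["variable", "index", "value", "bonf_p"])


# ---------------------------------------------------------------------------
# Model choice and contrasts
# ---------------------------------------------------------------------------

def choose_model(values: np.ndarray, alpha: float = ALPHA) -> str:
    """Pick ``"gamma-glm"`` for non-normal strictly positive data, else
    ``"linear"`` (Shapiro-Wilk screen at ``alpha``)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    _, p = sstats.shapiro(x)
    if p < alpha:
        if np.all(x > 0):
            return "gamma-glm"
        warnings.warn("non-normal but not strictly positive; falling back to linear")
    return "linear"


def condition_index(design: np.ndarray) -> float:
    """Largest condition index of a design matrix.

    Columns are scaled to unit norm; the index is the square root of the
    ratio of the largest to the smallest eigenvalue of X'X.  Rank-deficient
    designs give infinity.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("design must have at least 2 columns")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        return float("inf")
    Xs = X / norms
    eig = np.linalg.eigvalsh(Xs.T @ Xs)
    eig = np.clip(eig, 0.0, None)
    if eig[-1] <= 0:
        return float("inf")
    if eig[0] <= np.finfo(float).eps * eig[-1]:
        return float("inf")
    return float(np.sqrt(eig[-1] / eig[0]))


def partial_eta_squared(t: float, df: float) -> float:
    """Partial eta-squared effect size: t^2 / (t^2 + df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return t * t / (t * t + df)


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Classical pooled-variance two-sample t from group summaries."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def group_contrast(
    table: pd.DataFrame,
    variable: str,
    covariates: list = ("IQ",),
    group_col: str = "group",
    model: str | None = None,
) -> GroupComparisonResult:
    """Case-vs-control contrast for one variable, with covariates.

    Fits OLS (normal data) or a gamma GLM with log link (skewed positive
    data) of ``variable`` on group + covariates; reports the group
    coefficient's Wald t, two-sided p, and partial eta-squared
    t^2/(t^2 + df_resid).  The design is refused if its largest condition
    index exceeds 30.
    """
    covariates = list(covariates)
    cols = [variable, group_col, *covariates]
    d = table[cols].dropna()
    groups = sorted(d[group_col].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    # group indicator: 1 = first level alphabetically ("case" before "control")
    ind = (d[group_col] == groups[0]).astype(float)
    X = pd.DataFrame({"const": 1.0, "group": ind}, index=d.index)
    for c in covariates:
        # centering leaves the group coefficient untouched and keeps the
        # intercept from dominating the collinearity diagnostic
        X[c] = d[c].astype(float) - d[c].astype(float).mean()
    if X.shape[1] > 2:
        ci = condition_index(X.to_numpy())
        if ci > CONDITION_INDEX_LIMIT:
            raise CollinearDesignError(
                f"condition index {ci:.1f} > {CONDITION_INDEX_LIMIT}: refusing covariate set"
            )
    y = d[variable].astype(float)
    if model is None:
        model = choose_model(y.to_numpy())
    if model == "gamma-glm":
        fit = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        df_resid = fit.df_resid
    else:
        fit = sm.OLS(y, X).fit()
        df_resid = fit.df_resid
    coef = fit.params["group"]
    bse = fit.bse["group"]
    if bse == 0 or not np.isfinite(bse):
        t = 0.0 if coef == 0 else float("inf")
    else:
        t = float(coef / bse)
    p = float(2 * sstats.t.sf(abs(t), df_resid)) if np.isfinite(t) else 0.0
    eta = partial_eta_squared(t, df_resid) if np.isfinite(t) else 1.0
    n_case = int((d[group_col] == groups[0]).sum())
    n_control = int((d[group_col] == groups[1]).sum())
    return GroupComparisonResult(
        variable=variable,
        model=model,
        t=t,
        p=p,
        eta_p2=eta,
        df_resid=float(df_resid),
        covariates=tuple(covariates),
        n_case=n_case,
        n_control=n_control,
    )


# ---------------------------------------------------------------------------
# Correlation networks
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Direct transcription of the step-up definition: sort ascending, scale
    p_(i) by m/i, enforce monotonicity by a reverse cumulative minimum, cap
    at 1.  (Implemented in place so the adjusted values follow the printed
    definition bit for bit; ``statsmodels.multipletests`` serves as an
    independent cross-check in the test suite.)
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out

def spearman_fdr(
    table: pd.DataFrame,
    variables: list,
    by_group: bool = False,
    group_col: str = "group",
    alpha: float = ALPHA,
) -> list[CorrelationNetworkResult]:
    """Spearman correlation networks with Benjamini-Hochberg FDR control.

    All unique variable pairs form one FDR family per group (or one family
    overall when ``by_group`` is False).  Constant variables yield NaN
    correlations and are excluded from the family.  ``kept`` flags edges
    with adjusted p below ``alpha``.
    """
    results = []
    frames = (
        [(g, sub) for g, sub in table.groupby(group_col)]
        if by_group
        else [(None, table)]
    )
    for gname, sub in frames:
        rows = []
        for i, vi in enumerate(variables):
            for vj in variables[i + 1 :]:
                pair = sub[[vi, vj]].dropna()
                if len(pair) < 5:
                    rows.append((vi, vj, np.nan, np.nan))
                    continue
                xi, xj = pair[vi].to_numpy(float), pair[vj].to_numpy(float)
                if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                    rows.append((vi, vj, np.nan, np.nan))
                    continue
                r, p = sstats.spearmanr(xi, xj)
                rows.append((vi, vj, float(r), float(p)))
        df = pd.DataFrame(rows, columns=["var_i", "var_j", "r", "p"])
        df["p_fdr"] = np.nan
        valid = df["p"].notna()
        if valid.any():
            df.loc[valid, "p_fdr"] = bh_adjust(df.loc[valid, "p"].to_numpy())
        df["kept"] = df["p_fdr"] < alpha
        results.append(CorrelationNetworkResult(edges=df, group=gname))
    return results
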