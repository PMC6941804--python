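"""Generic statistical engines applied to host traits.

GLMs (Poisson/identity for fecundity, Gaussian/log for diversity indices
and antioxidant capacity), one-way ANOVA with Tukey(-Kramer) honestly
significant differences, Spearman rank correlation, and Wald contrasts
between factor levels of a fitted GLM.

Model fitting is delegated to statsmodels' IRLS machinery; this module
owns the interface, the inference conventions (Wald z for Poisson, t for
Gaussian) and the multiplicity adjustments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import ConvergenceError, ValidationError


@dataclass
class GlmFit:
    """Coefficient table plus the pieces needed for contrasts."""

    params: pd.Series
    bse: pd.Series
    wald: pd.Series          # z (Poisson) or t (Gaussian) statistics
    pvalues: pd.Series
    deviance: float
    df_resid: float
    cov_params: pd.DataFrame
    family: str
    link: str
    fitted: np.ndarray
    loglike: float

    @property
    def use_t(self) -> bool:
        return self.family == "gaussian"


_FAMILIES = {
    ("poisson", "identity"): lambda: sm.families.Poisson(sm.families.links.Identity()),
    ("poisson", "log"): lambda: sm.families.Poisson(sm.families.links.Log()),
    ("gaussian", "identity"): lambda: sm.families.Gaussian(sm.families.links.Identity()),
    ("gaussian", "log"): lambda: sm.families.Gaussian(sm.families.links.Log()),
}


def fit_glm(y, X, family: str = "gaussian", link: str = "identity") -> GlmFit:
    """Fit a GLM by iteratively reweighted least squares.

    ``X`` may be a DataFrame (column names become coefficient names) or
    an array; an intercept column must already be present if wanted.
    Identity-link Poisson fits are started from a feasible point so the
    working means stay positive.
    """
    if (family, link) not in _FAMILIES:
        raise ValidationError(f"unsupported family/link: {family}/{link}")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValidationError("y and X must have equal length")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    if family == "poisson" and np.any(y < 0):
        raise ValidationError("Poisson responses must be >= 0")
    fam = _FAMILIES[(family, link)]()
    import warnings

    with warnings.catch_warnings():
        # identity-link Poisson is the fecundity model of record; the
        # domain caveat is handled by the feasible start + mean check below
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.DomainWarning)
        model = sm.GLM(y, X, family=fam)
    start = None
    if family == "poisson" and link == "identity":
        # feasible start: intercept at the mean, other slopes 0
        start = np.zeros(X.shape[1])
        const_cols = [i for i, c in enumerate(X.columns)
                      if np.allclose(X.iloc[:, i], 1)]
        if const_cols:
            start[const_cols[0]] = max(float(y.mean()), 0.1)
        else:
            start = None
    try:
        res = model.fit(start_params=start, maxiter=100, tol=1e-10)
    except Exception as exc:
        raise ConvergenceError(f"GLM fit failed: {exc}") from exc
    mu = np.asarray(res.fittedvalues)
    if family == "poisson" and np.any(mu <= 0):
        raise ConvergenceError("identity-link Poisson fit left non-positive means")
    use_t = family == "gaussian"
    wald = res.params / res.bse
    if use_t:
        pvals = 2 * stats.t.sf(np.abs(wald), res.df_resid)
    else:
        pvals = 2 * stats.norm.sf(np.abs(wald))
    return GlmFit(
        params=res.params, bse=res.bse, wald=wald,
        pvalues=pd.Series(pvals, index=res.params.index),
        deviance=float(res.deviance), df_resid=float(res.df_resid),
        cov_params=pd.DataFrame(res.cov_params(), index=res.params.index,
                                columns=res.params.index),
        family=family, link=link, fitted=mu, loglike=float(res.llf),
    )


def anova_tukey(values, group_labels, alpha: float = 0.05):
    """One-way ANOVA with Tukey(-Kramer) pairwise comparisons.

    Returns ``(anova_table, pairwise)``: the classical SS/DF/MS/F/p
    decomposition and, per group pair, the mean difference with
    simultaneous ``1 - alpha`` intervals and studentized-range adjusted
    p-values. Unbalanced designs use the Tukey-Kramer standard error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValidationError("ANOVA requires at least two groups")
    data = [values[labels == g] for g in groups]
    sizes = np.array([len(d) for d in data])
    if np.any(sizes < 2):
        bad = groups[int(np.argmin(sizes))]
        raise ValidationError(f"group {bad!r} has fewer than 2 observations")
    k, n_total = len(groups), len(values)
    grand = values.mean()
    means = np.array([d.mean() for d in data])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((d - m) ** 2) for d, m in zip(data, means)))
    df_b, df_w = k - 1, n_total - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(stats.f.sf(f_stat, df_b, df_w))
    table = pd.DataFrame(
        {"SS": [ss_between, ss_within, ss_between + ss_within],
         "DF": [df_b, df_w, df_b + df_w],
         "MS": [ms_b, ms_w, np.nan],
         "F": [f_stat, np.nan, np.nan],
         "p": [p, np.nan, np.nan]},
        index=["between", "within", "total"])

    qcrit = stats.studentized_range.ppf(1 - alpha, k, df_w) if ms_w > 0 else 0.0
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_w / 2 * (1 / sizes[i] + 1 / sizes[j]))
        if se > 0:
            q_obs = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_obs, k, df_w))
        else:
            p_adj = 1.0 if diff == 0 else 0.0
        half = qcrit * se
        rows.append({"group_a": groups[i], "group_b": groups[j],
                     "mean_diff": diff, "ci_low": diff - half,
                     "ci_high": diff + half, "p_adj": p_adj,
                     "significant": p_adj < alpha})
    return table, pd.DataFrame(rows)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), p via the
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("spearman requires two equal vectors, n >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pairwise_glm_contrasts(fit: GlmFit, level_design: pd.DataFrame,
                           adjust: str = "bonferroni") -> pd.DataFrame:
    """Wald contrasts between factor-level means of a fitted GLM.

    ``level_design`` holds one row per factor level giving that level's
    row of the design matrix (on the linear-predictor scale); columns
    must match the fit's coefficients. Returns per pair the estimated
    difference, z (or t), raw and adjusted p.
    """
    if list(level_design.columns) != list(fit.params.index):
        raise ValidationError("level_design columns must match coefficients")
    levels = list(level_design.index)
    cov = fit.cov_params.to_numpy()
    beta = fit.params.to_numpy()
    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = (level_design.loc[a] - level_design.loc[b]).to_numpy(dtype=float)
        est = float(c @ beta)
        var = float(c @ cov @ c)
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else 0.0
        if fit.use_t:
            p = 2 * stats.t.sf(abs(z), fit.df_resid)
        else:
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"level_a": a, "level_b": b, "estimate": est,
                     "se": se, "z": z, "p": float(p)})
    out = pd.DataFrame(rows)
    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return out
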