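"""Rarefaction, alpha-diversity and sample-coverage estimators.

All estimators operate on a single sample's OTU count vector. Shannon
entropy is reported in nats. Chao1 and ACE are the classical abundance-
based richness estimators; Fisher's alpha is the log-series parameter;
sample coverage uses the Zhang-Huang alternating series with the
first-order Good-Turing estimator 1 - f1/n exposed as a reference.

``diversity_table`` evaluates everything per sample and
``diversity_glm`` fits the Gaussian/log-link model linking each index to
exposure concentration and time.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from . import host_stats
from .datatypes import OtuTable, ValidationError

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("observed_richness", "shannon", "chao1", "ace",
                 "fishers_alpha", "zhang_huang_coverage", "depth")


def _counts(vec) -> np.ndarray:
    c = np.asarray(vec)
    if np.any(c < 0):
        raise ValidationError("counts must be >= 0")
    return c[c > 0].astype(np.int64)


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a logged
    warning. Reproducible for a fixed seed.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be > 0")
    totals = table.depths
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, ", ".join(map(str, dropped)))
    if not len(keep):
        raise ValidationError("no sample reaches the rarefaction depth")
    rng = np.random.default_rng(seed)
    sub = table.counts.loc[keep]
    out = np.vstack([
        rng.multivariate_hypergeometric(row, depth)
        for row in sub.to_numpy()
    ])
    counts = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    return OtuTable(counts, table.taxonomy, table.sample_meta.loc[keep])


def rarefy_per_treatment(table: OtuTable, seed: int = 0,
                         group_col: str = "treatment") -> OtuTable:
    """Rarefy each treatment's samples to that treatment's minimum depth.

    The strict per-group reading of equalizing depth "at treatment
    level"; indices are then comparable within but not across groups,
    so :func:`rarefy` to the global minimum remains the default.
    """
    groups = table.sample_meta[group_col]
    parts = []
    for i, g in enumerate(sorted(groups.unique())):
        sub = table.subset_samples(groups.index[groups == g])
        parts.append(rarefy(sub, int(sub.depths.min()), seed=seed + i))
    counts = pd.concat([p.counts for p in parts])
    meta = pd.concat([p.sample_meta for p in parts])
    out = OtuTable(counts.loc[[s for s in table.sample_ids
                               if s in counts.index]],
                   table.taxonomy, meta)
    return out


def shannon(counts) -> float:
    """H = -sum p_i ln p_i over taxa with nonzero counts (nats)."""
    c = _counts(counts)
    if c.size == 0:
        raise ValidationError("empty sample")
    p = c / c.sum()
    return float(-np.sum(p * np.log(p)))


def chao1(counts) -> float:
    """Chao1 richness: classic form when doubletons exist, else the
    bias-corrected form S_obs + f1(f1-1)/(2(f2+1))."""
    c = _counts(counts)
    s_obs = c.size
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator.

    S_ACE = S_abund + S_rare/C + (f1/C) * gamma^2, with the rare group
    defined by counts <= ``rare_threshold``. When every rare taxon is a
    singleton the coverage C is zero and the estimator falls back to
    Chao1 with a warning.
    """
    c = _counts(counts)
    rare = c[c <= rare_threshold]
    s_abund = int(np.sum(c > rare_threshold))
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0:
        warnings.warn("ACE undefined (all rare taxa are singletons); "
                      "falling back to Chao1", RuntimeWarning, stacklevel=2)
        return chao1(counts)
    ks = np.arange(1, rare_threshold + 1)
    fk = np.array([np.sum(rare == k) for k in ks])
    gamma2 = (s_rare / c_ace) * np.sum(ks * (ks - 1) * fk) \
        / (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def fishers_alpha(counts) -> float:
    """Log-series alpha solving S = alpha * ln(1 + N/alpha)."""
    c = _counts(counts)
    s, n = c.size, int(c.sum())
    if s == 0:
        raise ValidationError("empty sample")
    if s == 1:
        return 0.0  # degenerate: a single taxon carries no evenness signal

    def f(a):
        return a * np.log1p(n / a) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValidationError("Fisher's alpha failed to bracket")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=500))


def good_turing_coverage(counts) -> float:
    """First-order coverage estimate C = 1 - f1/n (reference/fallback)."""
    c = _counts(counts)
    n = int(c.sum())
    if n == 0:
        raise ValidationError("empty sample")
    return float(1.0 - np.sum(c == 1) / n)


def zhang_huang_coverage(counts) -> float:
    """Zhang-Huang sample-coverage estimator.

    C = 1 - sum_{v>=1} (-1)^{v+1} f_v / binom(n, v), the alternating
    series whose first term reproduces Good-Turing 1 - f1/n; clamped to
    [0, 1]. Later terms shrink combinatorially, so only frequencies with
    f_v > 0 contribute measurably.
    """
    c = _counts(counts)
    n = int(c.sum())
    if n == 0:
        raise ValidationError("empty sample")
    total = 0.0
    for v in np.unique(c):
        v = int(v)
        f_v = int(np.sum(c == v))
        log_binom = gammaln(n + 1) - gammaln(v + 1) - gammaln(n - v + 1)
        log_term = np.log(f_v) - log_binom
        if log_term < -700:
            continue
        total += (1.0 if v % 2 == 1 else -1.0) * np.exp(log_term)
    return float(np.clip(1.0 - total, 0.0, 1.0))


def diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample index panel (one row per sample)."""
    rows = {}
    for sid, row in table.counts.iterrows():
        vec = row.to_numpy()
        rows[sid] = {
            "observed_richness": int(np.sum(vec > 0)),
            "shannon": shannon(vec),
            "chao1": chao1(vec),
            "ace": ace(vec),
            "fishers_alpha": fishers_alpha(vec),
            "zhang_huang_coverage": zhang_huang_coverage(vec),
            "depth": int(vec.sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def diversity_glm(results: pd.DataFrame, metadata: pd.DataFrame,
                  indices=("fishers_alpha", "chao1", "ace", "shannon"),
                  interaction_alpha: float = 0.05) -> pd.DataFrame:
    """Gaussian/log-link GLM of each index on concentration and time.

    The time x concentration interaction is fitted first and dropped
    when its Wald p exceeds ``interaction_alpha``. Concentration enters
    numerically in mg/L; time is the sampling day. Returns one row per
    (index, factor) with estimate, SE and p.
    """
    meta = metadata.loc[results.index]
    conc = meta["treatment"].to_numpy(dtype=float)
    time = meta["day"].to_numpy(dtype=float)
    rows = []
    for index_name in indices:
        y = results[index_name].to_numpy(dtype=float)
        if np.any(y <= 0):
            y = np.maximum(y, 1e-8)  # log link needs positive responses
        X_full = pd.DataFrame({"intercept": 1.0, "concentration": conc,
                               "time": time, "interaction": conc * time})
        fit = host_stats.fit_glm(y, X_full, family="gaussian", link="log")
        keep_interaction = fit.pvalues["interaction"] <= interaction_alpha
        if not keep_interaction:
            X = X_full.drop(columns=["interaction"])
            fit = host_stats.fit_glm(y, X, family="gaussian", link="log")
        for factor in fit.params.index:
            if factor == "intercept":
                continue
            rows.append({"index": index_name, "factor": factor,
                         "estimate": float(fit.params[factor]),
                         "se": float(fit.bse[factor]),
                         "p": float(fit.pvalues[factor]),
                         "interaction_retained": bool(keep_interaction)})
    return pd.DataFrame(rows)
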