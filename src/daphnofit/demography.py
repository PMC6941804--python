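"""Survival analysis and the Euler-Lotka intrinsic rate of increase.

The demographic core of the pipeline: cohort survivorship via the
Kaplan-Meier product-limit estimator, group comparison by the logrank
test, discrete-age life tables, and the intrinsic rate of increase r
solving

    sum_{x=alpha}^{beta} l(x) m(x) exp(-r x) = 1

with percentile-bootstrap confidence limits obtained by resampling
individuals with replacement.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import brentq

from .datatypes import (
    LifeHistoryRecord,
    LifeTable,
    PopGrowthResult,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _durations_events(records: Sequence[LifeHistoryRecord]):
    durations = np.array([r.last_day for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return durations, events


def kaplan_meier(records: Sequence[LifeHistoryRecord]) -> pd.DataFrame:
    """Product-limit survival curve S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Returns a DataFrame with columns ``time``, ``n_at_risk``,
    ``survival``; censored animals leave the risk set after their last
    observed day.
    """
    if not records:
        raise ValidationError("kaplan_meier requires at least one record")
    durations, events = _durations_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "n_at_risk": table["at_risk"].to_numpy(dtype=int),
        "survival": surv.reindex(table.index).to_numpy(dtype=float),
    })


def logrank_test(records: Sequence[LifeHistoryRecord],
                 group_labels: Sequence) -> tuple[float, int, float]:
    """K-group logrank test of equal survivorship.

    Returns ``(chi2, df, p)`` with ``df = k - 1``.
    """
    labels = np.asarray(group_labels)
    if len(labels) != len(records):
        raise ValidationError("group_labels must match records")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("logrank test requires at least two groups")
    durations, events = _durations_events(records)
    res = multivariate_logrank_test(durations, labels, events)
    chi2 = float(res.test_statistic)
    return chi2, len(groups) - 1, float(res.p_value)


def build_life_table(records: Sequence[LifeHistoryRecord]) -> LifeTable:
    """Tabulate l(x) and m(x) from one treatment's records.

    l(x) is the fraction of the cohort alive at age x, with every animal
    (dying or censored) counted alive through its last observed day.
    m(x) is the total brood released at age x divided by the number of
    mothers alive at age x, so that l(x)m(x) is the standard life-table
    product.
    """
    if not records:
        raise ValidationError("build_life_table requires at least one record")
    horizon = max(r.last_day for r in records)
    ages = np.arange(horizon + 1)
    n = len(records)
    alive = np.zeros(horizon + 1)
    births = np.zeros(horizon + 1)
    for rec in records:
        alive[: rec.last_day + 1] += 1
        for day, brood in rec.clutches:
            births[day] += brood
    lx = alive / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(alive > 0, births / np.maximum(alive, 1), 0.0)
    return LifeTable(ages=ages, lx=lx, mx=mx)


def euler_lotka_residual(r: float, table: LifeTable) -> float:
    """f(r) = sum l(x) m(x) exp(-r x) - 1; strictly decreasing in r."""
    return float(np.sum(table.lx * table.mx * np.exp(-r * table.ages)) - 1.0)


def solve_euler_lotka(table: LifeTable, tol: float = 1e-12) -> float:
    """Unique real root of the discrete Euler-Lotka equation.

    The root is bracketed by geometric expansion from [-2, 2] /day and
    refined by Brent's method; r may be negative when the net
    reproductive rate is below 1.
    """
    weights = table.lx * table.mx
    if np.sum(weights) <= 0:
        raise ValidationError("no reproduction: empty reproductive span")
    ages = table.ages[weights > 0]
    w = weights[weights > 0]
    if ages[0] == 0:
        # reproduction at age 0 makes exp(-r*0) insensitive to r; still
        # solvable as long as some reproduction occurs at a later age or
        # the age-0 term alone does not exceed 1.
        if len(ages) == 1:
            raise ValidationError("all reproduction at age 0: r undefined")

    def f(r):
        return float(np.sum(w * np.exp(-r * ages)) - 1.0)

    lo, hi = -2.0, 2.0
    while f(lo) < 0:  # f decreasing: want f(lo) > 0 > f(hi)
        lo *= 2.0
        if lo < -1e6:
            raise ValidationError("failed to bracket Euler-Lotka root (low)")
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError("failed to bracket Euler-Lotka root (high)")
    r = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    assert abs(f(r)) < 1e-10
    return float(r)


def _cohort_matrices(records: Sequence[LifeHistoryRecord]):
    """Per-individual alive-indicator and birth matrices over 0..horizon."""
    horizon = max(r.last_day for r in records)
    n = len(records)
    alive = np.zeros((n, horizon + 1))
    births = np.zeros((n, horizon + 1))
    for i, rec in enumerate(records):
        alive[i, : rec.last_day + 1] = 1.0
        for day, brood in rec.clutches:
            births[i, day] += brood
    return alive, births


def _solve_from_counts(alive_sum: np.ndarray, birth_sum: np.ndarray,
                       n: int, ages: np.ndarray) -> float | None:
    lxmx = np.where(alive_sum > 0, birth_sum / n, 0.0)
    mask = lxmx > 0
    if not mask.any():
        return None
    w = lxmx[mask]
    a = ages[mask]
    if a[0] == 0 and len(a) == 1:
        return None

    def f(r):
        return float(np.sum(w * np.exp(-r * a)) - 1.0)

    lo, hi = -2.0, 2.0
    while f(lo) < 0:
        lo *= 2.0
        if lo < -1e6:
            return None
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            return None
    return float(brentq(f, lo, hi, xtol=1e-12, maxiter=200))


def bootstrap_population_growth(records: Sequence[LifeHistoryRecord],
                                n_boot: int = 999, conf: float = 0.95,
                                seed: int = 0) -> PopGrowthResult:
    """Bootstrap r by resampling individuals with replacement.

    The point estimate comes from the full cohort; the confidence
    interval is the percentile interval of the ``n_boot`` resampled
    estimates. Resamples whose life table carries no reproduction are
    excluded from the percentiles and counted in ``n_degenerate``.

    Note: l(x)m(x) = births-at-x / initial-cohort-size, so resampled
    life tables reduce to sums over the drawn individuals' birth rows.
    """
    if len(records) < 2:
        raise ValidationError("bootstrap requires at least two individuals")
    table = build_life_table(records)
    r_point = solve_euler_lotka(table)

    alive, births = _cohort_matrices(records)
    n = len(records)
    ages = np.arange(alive.shape[1])
    rng = np.random.default_rng(seed)
    estimates = []
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        r_b = _solve_from_counts(alive[idx].sum(axis=0),
                                 births[idx].sum(axis=0), n, ages)
        if r_b is None:
            n_degenerate += 1
        else:
            estimates.append(r_b)
    if not estimates:
        raise ValidationError("all bootstrap resamples were degenerate")
    if n_degenerate:
        logger.warning("%d of %d bootstrap resamples had no reproduction "
                       "and were excluded", n_degenerate, n_boot)
    lo_q = (1 - conf) / 2
    ci_low, ci_high = np.quantile(estimates, [lo_q, 1 - lo_q])
    return PopGrowthResult(r=r_point, ci_low=float(ci_low),
                           ci_high=float(ci_high), n_boot=n_boot,
                           seed=seed, n_degenerate=n_degenerate)


def compare_by_ci(a: PopGrowthResult, b: PopGrowthResult) -> bool:
    """True iff the two 95% intervals are strictly disjoint.

    Touching endpoints count as overlapping (conservative).
    """
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low
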