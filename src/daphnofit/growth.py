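"""Von Bertalanffy growth-curve fitting.

Fits the saturating growth model

    BL(t) = BL_max * (1 - exp(-K t))

to length-at-age data by nonlinear least squares and reports the full
goodness-of-fit panel (estimates, SEs, 95% CIs, R^2, df, residual SS and
residual standard error Sy.x), plus the disjoint-CI comparison used to
contrast treatments.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .datatypes import ConvergenceError, GrowthFit, ValidationError


def von_bertalanffy(t, bl_max, k):
    """Model curve BL(t) = BL_max (1 - exp(-K t))."""
    return bl_max * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def _initial_guess(t, bl):
    bl_max0 = 1.05 * float(np.max(bl))
    # linearize: log(1 - BL/bl_max0) = -K t
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(np.clip(1.0 - bl / bl_max0, 1e-12, None))
    denom = float(np.sum(t * t))
    k0 = -float(np.sum(t * z)) / denom if denom > 0 else 0.2
    return bl_max0, float(np.clip(k0, 1e-3, 5.0))


def fit_von_bertalanffy(length_at_age: Sequence[tuple[float, float]],
                        conf: float = 0.95) -> GrowthFit:
    """Nonlinear least-squares fit of the von Bertalanffy curve.

    Parameters are constrained positive; standard errors come from the
    Jacobian-based covariance at the optimum and confidence intervals
    use the t distribution on ``n - 2`` residual degrees of freedom.
    Five jittered restarts are attempted before giving up.
    """
    data = np.asarray(list(length_at_age), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValidationError("length_at_age must be (t, BL) pairs")
    t, bl = data[:, 0], data[:, 1]
    n = len(t)
    if n < 3 or len(np.unique(t)) < 2:
        raise ValidationError("need >= 3 points spanning >= 2 distinct ages")
    if np.any(bl <= 0):
        raise ValidationError("body lengths must be > 0")
    df = n - 2
    ss_tot = float(np.sum((bl - bl.mean()) ** 2))
    if ss_tot == 0:
        raise ConvergenceError("constant body length: K is unidentifiable")

    p0 = _initial_guess(t, bl)
    rng = np.random.default_rng(0)
    best = None
    last_err = None
    for attempt in range(6):
        start = p0 if attempt == 0 else (
            p0[0] * rng.uniform(0.8, 1.3), p0[1] * rng.uniform(0.3, 3.0))
        try:
            popt, pcov = curve_fit(
                von_bertalanffy, t, bl, p0=start,
                bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = exc
            continue
        resid = bl - von_bertalanffy(t, *popt)
        ss = float(np.sum(resid ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise ConvergenceError(f"von Bertalanffy fit failed: {last_err}")
    popt, pcov, ss = best
    if not np.all(np.isfinite(pcov)):
        raise ConvergenceError("singular covariance: parameters unidentifiable",
                               best=popt)
    se = np.sqrt(np.diag(pcov))
    tq = stats.t.ppf(0.5 + conf / 2, df)
    r2 = 1.0 - ss / ss_tot
    return GrowthFit(
        bl_max=float(popt[0]), k=float(popt[1]),
        se_bl_max=float(se[0]), se_k=float(se[1]),
        ci_bl_max=(float(popt[0] - tq * se[0]), float(popt[0] + tq * se[0])),
        ci_k=(float(popt[1] - tq * se[1]), float(popt[1] + tq * se[1])),
        r2=float(r2), df=df, ss=ss, sy_x=float(np.sqrt(ss / df)),
        n=n, converged=True,
    )


def compare_growth_fits(a: GrowthFit, b: GrowthFit) -> dict[str, bool]:
    """Disjoint-95%-CI comparison per parameter (ties = overlap)."""

    def disjoint(ci_a, ci_b):
        return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]

    return {"bl_max": disjoint(a.ci_bl_max, b.ci_bl_max),
            "k": disjoint(a.ci_k, b.ci_k)}


def growth_table(fits: dict[str, GrowthFit]):
    """Report frame: one column per treatment, rows mirroring the
    best-fit / SE / CI / goodness-of-fit panel."""
    import pandas as pd

    rows = {}
    for name, f in fits.items():
        rows[name] = {
            "BL_max": f.bl_max, "K": f.k,
            "SE BL_max": f.se_bl_max, "SE K": f.se_k,
            "CI BL_max low": f.ci_bl_max[0], "CI BL_max high": f.ci_bl_max[1],
            "CI K low": f.ci_k[0], "CI K high": f.ci_k[1],
            "R2": f.r2, "df": f.df, "Sum of Squares": f.ss, "Sy.x": f.sy_x,
        }
    return pd.DataFrame(rows)
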