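"""Paralyzable dead-time model: count-rate fitting and count-loss thresholds.

A paralyzable detector observes the count rate

    C(A) = alpha * A * exp(-tau * alpha * A)

where A is the activity at scan time, alpha the linear (low-rate) detector
sensitivity and tau the dead time.  The curve passes through the origin by
construction, peaks at A = 1 / (alpha * tau) and rolls over beyond it.
Inverting the relative count loss 1 - exp(-tau * alpha * A) = p yields the
activity producing a fractional loss p:

    A(p) = -ln(1 - p) / (alpha * tau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CountRateSeries",
    "ParalyzableFit",
    "expected_count_rate",
    "fit_paralyzable",
    "activity_at_count_loss",
    "simulate_count_rate_series",
]


@dataclass(frozen=True)
class CountRateSeries:
    """(activity, count-rate) pairs with the acquisition duration per point."""

    activities_MBq: np.ndarray
    count_rates_cps: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        a = np.asarray(self.activities_MBq, dtype=float)
        c = np.asarray(self.count_rates_cps, dtype=float)
        if a.ndim != 1 or a.shape != c.shape:
            raise ValueError("activities and count rates must be 1D arrays of equal length")
        if a.size < 3:
            raise ValueError("at least three points are required for fitting")
        if (np.diff(a) <= 0).any():
            raise ValueError("activities must be strictly increasing")
        if (a <= 0).any() or (c < 0).any():
            raise ValueError("activities must be positive and count rates nonnegative")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "activities_MBq", a)
        object.__setattr__(self, "count_rates_cps", c)


@dataclass(frozen=True)
class ParalyzableFit:
    """Fitted (alpha, tau) with covariance and residual sum of squares."""

    alpha_cps_per_MBq: float
    tau_s: float
    covariance: np.ndarray
    rss: float

    def predict(self, activities_MBq: np.ndarray) -> np.ndarray:
        return expected_count_rate(np.asarray(activities_MBq, float),
                                   self.alpha_cps_per_MBq, self.tau_s)


def expected_count_rate(A_MBq, alpha: float, tau: float):
    """Paralyzable-model count rate alpha * A * exp(-tau * alpha * A)."""
    A = np.asarray(A_MBq, dtype=float)
    out = alpha * A * np.exp(-tau * alpha * A)
    return float(out) if np.isscalar(A_MBq) else out


def fit_paralyzable(series: CountRateSeries) -> ParalyzableFit:
    """Weighted least-squares fit of the paralyzable model.

    Weights are Poisson-motivated (1 / max(C, 1) on squared residuals).
    alpha is initialized from the slope of the lowest-activity third of the
    series and tau at zero, both bounded below at zero.  If the series is
    essentially linear the fit pins tau to ~0 and a warning is emitted.
    """
    A = series.activities_MBq
    C = series.count_rates_cps
    w = 1.0 / np.sqrt(np.maximum(C, 1.0))

    n_low = max(3, len(A) // 3)
    alpha0 = float(np.mean(C[:n_low] / A[:n_low]))
    if alpha0 <= 0:
        alpha0 = max(float(C.max() / A[np.argmax(C)]), 1e-9)

    def residuals(params: np.ndarray) -> np.ndarray:
        alpha, tau = params
        return w * (alpha * A * np.exp(-tau * alpha * A) - C)

    x0 = np.array([alpha0, 0.0])
    res = least_squares(residuals, x0, bounds=([1e-12, 0.0], [np.inf, np.inf]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
    if not (res.success or res.cost < 1e-20):
        # one jittered restart with a fixed seed
        rng = np.random.default_rng(4242)
        x0 = np.array([alpha0 * (1 + 0.1 * rng.standard_normal()), 1e-7])
        res = least_squares(residuals, np.clip(x0, [1e-12, 0.0], None),
                            bounds=([1e-12, 0.0], [np.inf, np.inf]),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
        if not res.success:
            raise RuntimeError(f"paralyzable fit did not converge: {res.message}")

    alpha, tau = res.x
    if tau * alpha * A.max() < 1e-6:
        warnings.warn("no curvature information in the series; tau is pinned to ~0 "
                      "and count-loss thresholds are unbounded", stacklevel=2)

    rss = float(2.0 * res.cost)
    dof = max(len(A) - 2, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return ParalyzableFit(float(alpha), float(tau), cov, rss)


def activity_at_count_loss(p: float, alpha: float, tau: float) -> float:
    """Activity (MBq) producing a fractional count loss ``p``.

    Closed form from 1 - exp(-tau * alpha * A) = p.  For tau = 0 the loss
    never occurs and the threshold is unbounded (returns ``inf``).
    """
    if not 0 < p < 1:
        raise ValueError("count-loss fraction must be in (0, 1)")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau == 0:
        return math.inf
    return -math.log1p(-p) / (alpha * tau)


def simulate_count_rate_series(
    activities_MBq: np.ndarray,
    alpha: float,
    tau: float,
    duration_s: float = 300.0,
    seed: int | None = 0,
    *,
    poisson: bool = True,
) -> CountRateSeries:
    """Generate a count-rate series from the paralyzable model.

    With ``poisson=True`` the counts per point are Poisson samples of
    ``C(A) * duration``; otherwise the series is noiseless.
    """
    A = np.asarray(activities_MBq, dtype=float)
    expected = expected_count_rate(A, alpha, tau) * duration_s
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return CountRateSeries(A, counts / duration_s, duration_s)
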