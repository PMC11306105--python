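"""Logistic growth-curve fitting and closed-form lag/doubling statistics.

The population model is the three-parameter logistic

    N(t) = K / [1 + ((K - N0)/N0) * exp(-r t)]

with carrying capacity ``K``, initial size ``N0`` (both in OD600 units) and
intrinsic rate ``r`` (per hour).  Two derived statistics are used throughout:

* **lag time** — the time at which N(t) reaches a fixed detection threshold
  (default OD600 = 0.01 on the background-corrected scale), obtained by
  inverting the logistic in closed form:

      t = (-1/r) [ ln((K - N_t)/(K - N0)) - ln(N_t/N0) ]

* **doubling time** — the time at which N(t) = 2 N0, the same inversion with
  N_t = 2 N0, which reduces to ln(2)/r in the N0 << K limit.

Both are exact inverses of the fitted curve, so ``predict`` evaluated at the
returned time reproduces the target value to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DataError, ParameterError, UndefinedStatisticError
from .io import GrowthCurve

DEFAULT_LAG_THRESHOLD = 0.01
DEFAULT_DYNAMIC_RANGE_FLOOR = 0.02

__all__ = [
    "LogisticFit",
    "LagStatistic",
    "logistic",
    "predict",
    "fit_logistic",
    "lag_time",
    "doubling_time",
    "summarize_fits",
    "DEFAULT_LAG_THRESHOLD",
    "DEFAULT_DYNAMIC_RANGE_FLOOR",
]


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters and diagnostics for one well."""

    K: float
    N0: float
    r: float
    sse: float
    converged: bool
    well_id: str = ""
    condition: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.converged:
            if not (0.0 < self.N0 < self.K):
                raise ParameterError(
                    f"converged fit requires 0 < N0 < K, got N0={self.N0}, K={self.K}"
                )
            if not self.r > 0:
                raise ParameterError(f"converged fit requires r > 0, got {self.r}")
        if self.sse < 0 or not np.isfinite(self.sse):
            raise ParameterError(f"sse must be finite and >= 0, got {self.sse}")


@dataclass(frozen=True)
class LagStatistic:
    """Lag and doubling times extracted from one fit."""

    lag_time: float
    doubling_time: float
    threshold: float = field(default=DEFAULT_LAG_THRESHOLD)


def logistic(t, K: float, N0: float, r: float):
    """Evaluate N(t) for the three-parameter logistic model.

    Computed as K * expit(r t - ln((K - N0)/N0)), which is algebraically
    identical to the textbook form but free of overflow for extreme
    parameters.
    """
    t = np.asarray(t, dtype=float)
    log_b = math.log(K - N0) - math.log(N0)
    return K * expit(r * t - log_b)


def predict(fit: LogisticFit, t):
    """Predict OD600 at time ``t`` (hours) from a converged fit."""
    if not fit.converged:
        raise ParameterError("cannot predict from a non-converged fit")
    return logistic(t, fit.K, fit.N0, fit.r)


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Interpolated time of the first upward crossing of ``level``."""
    above = y >= level
    if above[0]:
        return float(t[0])
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))

def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Heuristic (K, N0, r) start values from quantile crossings.

    K starts at the observed maximum.  The rate comes from the time taken to
    rise from 0.2 K to 0.8 K (for a logistic that interval spans ln(16)/r).
    N0 follows from the half-maximum crossing time t50 via
    N0 = K / (1 + e^{r t50}).  All guesses are clipped to plausible
    plate-reader ranges so the optimizer starts inside a sane basin even for
    noisy or degenerate wells.
    """
    k0 = float(np.max(y))
    t20 = _first_crossing(t, y, 0.2 * k0)
    t80 = _first_crossing(t, y, 0.8 * k0)
    if t20 is not None and t80 is not None and t80 > t20:
        r0 = math.log(16.0) / (t80 - t20)
    else:
        r0 = 0.5
    r0 = float(np.clip(r0, 0.01, 20.0))
    t50 = _first_crossing(t, y, 0.5 * k0)
    if t50 is not None and r0 * t50 < 500.0:
        n0 = k0 / (1.0 + math.exp(r0 * t50))
    else:
        n0 = k0 / 1e6
    n0 = float(np.clip(n0, 1e-9, 0.5 * k0))
    return k0, n0, r0


def fit_logistic(
    curve: GrowthCurve,
    dynamic_range_floor: float = DEFAULT_DYNAMIC_RANGE_FLOOR,
    max_nfev: int = 10_000,
) -> LogisticFit:
    """Least-squares fit of the logistic model to one corrected curve.

    Parameters are estimated on the log scale (log K, log N0, log r) so the
    positivity constraints hold by construction and the optimizer never sits
    on a boundary.  Wells whose observed dynamic range (max - min OD600) is
    below ``dynamic_range_floor`` are declared non-growing and returned with
    ``converged=False``; no lag or doubling statistics should be derived from
    them.  The same applies when the optimizer fails or the estimates violate
    0 < N0 < K.
    """
    if len(curve) < 4:
        raise DataError(f"well {curve.well_id}: need >=4 points to fit, got {len(curve)}")
    t = curve.time
    y = curve.od600

    def failed() -> LogisticFit:
        return LogisticFit(
            K=float("nan"), N0=float("nan"), r=float("nan"),
            sse=float(np.sum((y - np.mean(y)) ** 2)),
            converged=False,
            well_id=curve.well_id, condition=curve.condition,
            replicate_index=curve.replicate_index,
        )

    if curve.non_growing or float(np.max(y) - np.min(y)) < dynamic_range_floor:
        return failed()

    k0, n00, r0 = _initial_guess(t, y)
    theta0 = np.log([k0, n00, r0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        K, N0, r = np.exp(np.clip(theta, -60.0, 60.0))
        if not N0 < K:  # outside the model's domain; push back smoothly
            N0 = 0.999999 * K
        return logistic(t, K, N0, r) - y

    try:
        result = least_squares(
            residuals, theta0, method="lm", max_nfev=max_nfev,
            ftol=1e-12, xtol=1e-12, gtol=1e-12,
        )
    except (ValueError, FloatingPointError):
        return failed()

    K, N0, r = (float(v) for v in np.exp(result.x))
    sse = float(np.sum(result.fun**2))
    ok = (
        result.success
        and np.isfinite([K, N0, r]).all()
        and 0.0 < N0 < K
        and r > 0
        and (K - N0) >= dynamic_range_floor
    )
    if not ok:
        return failed()
    return LogisticFit(
        K=K, N0=N0, r=r, sse=sse, converged=True,
        well_id=curve.well_id, condition=curve.condition,
        replicate_index=curve.replicate_index,
    )


def lag_time(fit: LogisticFit, threshold: float = DEFAULT_LAG_THRESHOLD) -> float:
    """Time at which the fitted curve reaches ``threshold`` OD600.

    Closed-form inversion of the logistic.  A fit whose N0 already exceeds
    the threshold yields a negative lag, which is reported as-is so that
    differences between conditions stay well defined.

    Raises
    ------
    UndefinedStatisticError
        If ``threshold >= K``: the population never reaches the threshold.
    """
    if not fit.converged:
        raise ParameterError("lag_time requires a converged fit")
    if not threshold > 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    if threshold >= fit.K:
        raise UndefinedStatisticError(
            f"threshold {threshold} >= carrying capacity {fit.K}: lag undefined"
        )
    K, N0, r = fit.K, fit.N0, fit.r
    return (-1.0 / r) * (
        math.log((K - threshold) / (K - N0)) - math.log(threshold / N0)
    )


def doubling_time(fit: LogisticFit) -> float:
    """Time at which the fitted curve reaches 2*N0.

    Same closed-form inversion with N_t = 2 N0; approaches ln(2)/r when
    N0 << K.

    Raises
    ------
    UndefinedStatisticError
        If ``2*N0 >= K``: the population never doubles.
    """
    if not fit.converged:
        raise ParameterError("doubling_time requires a converged fit")
    K, N0, r = fit.K, fit.N0, fit.r
    if 2.0 * N0 >= K:
        raise UndefinedStatisticError(
            f"2*N0 = {2 * N0} >= carrying capacity {K}: doubling undefined"
        )
    return (-1.0 / r) * (math.log((K - 2.0 * N0) / (K - N0)) - math.log(2.0))


def summarize_fits(fits, threshold: float = DEFAULT_LAG_THRESHOLD):
    """Tidy per-well table of fit parameters and derived statistics.

    Non-converged (non-growing) wells appear with NaN statistics so they are
    visible in output but excluded from any downstream lag comparison.
    """
    import pandas as pd

    rows = []
    for fit in fits:
        row = {
            "well": fit.well_id,
            "condition": fit.condition,
            "replicate": fit.replicate_index,
            "K": fit.K,
            "N0": fit.N0,
            "r": fit.r,
            "sse": fit.sse,
            "converged": fit.converged,
            "lag_h": float("nan"),
            "doubling_h": float("nan"),
        }
        if fit.converged:
            try:
                row["lag_h"] = lag_time(fit, threshold)
            except UndefinedStatisticError:
                pass
            try:
                row["doubling_h"] = doubling_time(fit)
            except UndefinedStatisticError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
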