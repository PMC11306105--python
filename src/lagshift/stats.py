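"""Delta-lag statistics: condition summaries, uncertainty propagation and
many-to-one significance testing.

The effect of a supplement on the lag phase is expressed as

    delta_lag = mean_lag(control) - mean_lag(treatment)

so a positive value means the supplement *shortened* the lag.  The standard
deviation of the estimated difference between means is propagated as

    sd_diff = sqrt(sd1^2/n1 + sd2^2/n2)

Significance of each treatment against the shared control comes from a
one-way ANOVA followed by Dunnett's many-to-one comparison (two-sided, with
the pooled error variance across all groups in the call), delegated to
``scipy.stats.dunnett``.  Adjusted p-values are mapped to the conventional
categories ``***`` (<=0.001), ``**`` (<=0.01), ``*`` (<=0.05), ``NS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

__all__ = [
    "ConditionSummary",
    "DeltaLagResult",
    "summarize_condition",
    "delta_lag",
    "dunnett_many_to_one",
    "significance_category",
    "compare_conditions",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate-level summary of one condition's lag (or doubling) times."""

    condition: str
    n: int
    mean_lag: float
    sd_lag: float
    mean_doubling: float = float("nan")
    sd_doubling: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError(f"condition {self.condition!r}: need n >= 2, got {self.n}")
        if self.sd_lag < 0:
            raise DataError("standard deviation must be non-negative")


@dataclass(frozen=True)
class DeltaLagResult:
    """Difference in mean lag between a control and one treatment."""

    treatment: str
    control: str
    delta_lag: float
    sd_diff: float
    p_adjusted: float = float("nan")
    significance: str = ""

    def __post_init__(self) -> None:
        if self.sd_diff < 0:
            raise DataError("sd_diff must be non-negative")
        if not math.isnan(self.p_adjusted) and not 0.0 <= self.p_adjusted <= 1.0:
            raise DataError(f"p_adjusted out of [0, 1]: {self.p_adjusted}")

    def formatted(self) -> str:
        """Render as ``'1.2 (±0.1)'`` — delta with its propagated sd."""
        return f"{self.delta_lag:.1f} (±{self.sd_diff:.1f})"


def summarize_condition(
    lags: Sequence[float],
    condition: str,
    doublings: Sequence[float] | None = None,
) -> ConditionSummary:
    """Sample mean and sample sd (n-1 denominator) of a condition's lags."""
    arr = np.asarray(lags, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DataError(
            f"condition {condition!r}: need >=2 finite lag values, got {arr.size}"
        )
    mean_d, sd_d = float("nan"), float("nan")
    if doublings is not None:
        d = np.asarray(doublings, dtype=float)
        d = d[np.isfinite(d)]
        if d.size >= 2:
            mean_d, sd_d = float(d.mean()), float(d.std(ddof=1))
    return ConditionSummary(
        condition=condition,
        n=int(arr.size),
        mean_lag=float(arr.mean()),
        sd_lag=float(arr.std(ddof=1)),
        mean_doubling=mean_d,
        sd_doubling=sd_d,
    )


def delta_lag(control: ConditionSummary, treatment: ConditionSummary) -> DeltaLagResult:
    """Control-minus-treatment difference of mean lags with propagated sd.

    ``sd_diff = sqrt(sd_t^2/n_t + sd_c^2/n_c)`` — the standard deviation of
    the estimated difference between the two means.  Negative deltas
    (lag-prolonging supplements, e.g. methionine) are reported as-is.
    """
    diff = control.mean_lag - treatment.mean_lag
    sd = math.sqrt(
        treatment.sd_lag**2 / treatment.n + control.sd_lag**2 / control.n
    )
    return DeltaLagResult(
        treatment=treatment.condition,
        control=control.condition,
        delta_lag=diff,
        sd_diff=sd,
    )


def significance_category(p: float) -> str:
    """Map an adjusted p-value to ***, **, * or NS."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p-value out of [0, 1]: {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def dunnett_many_to_one(
    lag_values: Mapping[str, Sequence[float]],
    control: str,
    seed: int = 0,
) -> dict[str, float]:
    """Two-sided Dunnett comparisons of every treatment against the control.

    All groups in ``lag_values`` share the pooled ANOVA error variance; the
    family-wise adjustment covers the K-1 treatments in this call.  The
    multivariate-t probability underlying the adjusted p-values is evaluated
    by quasi-Monte Carlo integration; ``seed`` fixes that stream so results
    are reproducible.

    Returns a mapping treatment -> adjusted p-value (control excluded).
    """
    if control not in lag_values:
        raise ParameterError(f"control condition {control!r} not present")
    groups: dict[str, np.ndarray] = {}
    for name, values in lag_values.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise DataError(f"condition {name!r}: need >=2 finite values")
        groups[name] = arr
    treatments = [name for name in groups if name != control]
    if not treatments:
        return {}
    pooled_ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    if pooled_ss == 0.0:
        # degenerate: no within-group variance; equal means are certain nulls
        return {
            name: 1.0 if groups[name].mean() == groups[control].mean() else 0.0
            for name in treatments
        }
    result = sps.dunnett(
        *(groups[name] for name in treatments),
        control=groups[control],
        alternative="two-sided",
        rng=np.random.default_rng(seed),
    )
    return {
        name: float(min(max(p, 0.0), 1.0))
        for name, p in zip(treatments, result.pvalue)
    }


def compare_conditions(
    lag_values: Mapping[str, Sequence[float]],
    control: str,
    doubling_values: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full delta-lag table: effect sizes, propagated sds and adjusted p.

    One row per treatment, columns
    ``treatment, control, n_treat, n_ctrl, delta_lag_h, sd_diff_h,
    p_adjusted, significance, formatted`` (plus doubling columns when
    ``doubling_values`` is given).
    """
    control_summary = summarize_condition(lag_values[control], control)
    pvals = dunnett_many_to_one(lag_values, control, seed=seed)
    dbl_pvals: dict[str, float] = {}
    if doubling_values is not None:
        dbl_pvals = dunnett_many_to_one(doubling_values, control, seed=seed)
    rows = []
    for name in lag_values:
        if name == control:
            continue
        treat_summary = summarize_condition(lag_values[name], name)
        res = delta_lag(control_summary, treat_summary)
        p = pvals[name]
        row = {
            "treatment": name,
            "control": control,
            "n_treat": treat_summary.n,
            "n_ctrl": control_summary.n,
            "delta_lag_h": res.delta_lag,
            "sd_diff_h": res.sd_diff,
            "p_adjusted": p,
            "significance": significance_category(p),
            "formatted": res.formatted(),
        }
        if doubling_values is not None and name in doubling_values:
            dc = summarize_condition(doubling_values[control], control)
            dt = summarize_condition(doubling_values[name], name)
            ddiff = delta_lag(dc, dt)
            row["delta_doubling_h"] = ddiff.delta_lag
            row["sd_diff_doubling_h"] = ddiff.sd_diff
            row["p_adjusted_doubling"] = dbl_pvals.get(name, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
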