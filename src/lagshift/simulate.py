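"""Synthetic plate-reader experiments and feature tables with known truth.

The plate generator emulates the study conditions of a 96-well growth
experiment: a flat background phase, logistic growth, additive Gaussian
measurement noise on the plate-reader (raw) scale, readings every 20 min over
30 h, and a multiplicative instrument calibration factor.  For each well

    raw(t) = [ N(t - shift; K, N0, r) + background + eps ] / calibration_factor

with eps ~ Normal(0, noise_sd).  Lag-shortening effects are injected through
the initial population size N0 — a larger effective inoculum reaches the
detection threshold earlier while leaving the doubling time essentially
unchanged, which keeps the generative model inside the fitted model family
and gives exact closed-form ground truth.  An optional per-condition time
shift is available as a model-misspecification stressor.

Randomness: a single integer seed is split into independent per-well streams
with ``numpy.random.SeedSequence.spawn`` (wells in layout order), so the same
seed reproduces the same plate bit-for-bit regardless of how many wells are
consumed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .expression import FeatureTable
from .io import PlateLayout
from .logistic import LogisticFit, doubling_time, lag_time, logistic

__all__ = [
    "ConditionSpec",
    "SyntheticPlateConfig",
    "GroundTruth",
    "SimulatedPlate",
    "simulate_plate",
    "standard_experiment",
    "lag_effect_via_n0",
    "simulate_feature_table",
    "plate_frame_to_wide",
]


@dataclass(frozen=True)
class ConditionSpec:
    """True logistic parameters and replicate count for one condition."""

    label: str
    K: float
    N0: float
    r: float
    n_replicates: int = 4
    time_shift: float = 0.0  # hours; misspecification stressor, 0 = in-model

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.N0 > 0 and self.r > 0):
            raise ParameterError(f"condition {self.label!r}: K, N0, r must be positive")
        if not self.N0 < self.K:
            raise ParameterError(f"condition {self.label!r}: need N0 < K")
        if self.n_replicates < 2:
            raise ParameterError(f"condition {self.label!r}: need >=2 replicates")


@dataclass(frozen=True)
class SyntheticPlateConfig:
    """Study-condition defaults for a simulated plate.

    Defaults mirror the growth protocol the generator emulates: four
    replicate wells per condition, a 20-min read cycle over 30 h, additive
    noise sd 0.003 on the raw absorbance scale, and the 3.8603 plate-to-
    cuvette calibration factor.
    """

    conditions: tuple[ConditionSpec, ...]
    control: str = ""
    noise_sd: float = 0.003
    background_level: float = 0.04
    calibration_factor: float = 3.8603
    sampling_interval: float = 1.0 / 3.0  # hours
    duration: float = 30.0  # hours
    lag_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ParameterError("need at least one condition")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ParameterError("condition labels must be unique")
        control = self.control or labels[0]
        if control not in labels:
            raise ParameterError(f"control {control!r} not among conditions")
        object.__setattr__(self, "control", control)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.noise_sd < 0 or self.background_level < 0:
            raise ParameterError("noise_sd and background_level must be >= 0")
        if not (self.calibration_factor > 0 and self.sampling_interval > 0):
            raise ParameterError("calibration_factor and sampling_interval must be positive")
        if self.duration < 4 * self.sampling_interval:
            raise ParameterError("duration too short for a fittable curve")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form statistics of the noiseless generating curves.

    ``lag`` and ``doubling`` are keyed by condition label; ``delta_lag`` is
    control-minus-treatment (positive = shorter lag than control) and
    excludes the control itself.  Time shifts are added to the in-model lag.
    """

    control: str
    threshold: float
    lag: dict = field(default_factory=dict)
    doubling: dict = field(default_factory=dict)
    delta_lag: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulatedPlate:
    """Raw plate table (long format), its layout and the generating truth."""

    frame: pd.DataFrame
    layout: PlateLayout
    truth: GroundTruth
    config: SyntheticPlateConfig


def _true_fit(spec: ConditionSpec) -> LogisticFit:
    return LogisticFit(K=spec.K, N0=spec.N0, r=spec.r, sse=0.0, converged=True)


def _ground_truth(config: SyntheticPlateConfig) -> GroundTruth:
    lags, doublings = {}, {}
    for spec in config.conditions:
        lags[spec.label] = lag_time(_true_fit(spec), config.lag_threshold) + spec.time_shift
        doublings[spec.label] = doubling_time(_true_fit(spec))
    control_lag = lags[config.control]
    deltas = {
        label: control_lag - lag
        for label, lag in lags.items()
        if label != config.control
    }
    return GroundTruth(
        control=config.control,
        threshold=config.lag_threshold,
        lag=lags,
        doubling=doublings,
        delta_lag=deltas,
    )


def simulate_plate(config: SyntheticPlateConfig) -> SimulatedPlate:
    """Simulate one plate; returns raw data, layout and closed-form truth.

    Wells are laid out one plate row per condition (A1..An for the first
    condition, B1..Bn for the second, ...).  With ``noise_sd=0``,
    ``background_level=0`` and ``calibration_factor=1`` the raw values equal
    the logistic exactly.
    """
    n_points = int(math.floor(config.duration / config.sampling_interval)) + 1
    t = np.arange(n_points) * config.sampling_interval

    layout_entries = {}
    well_specs: list[tuple[str, ConditionSpec]] = []
    for i, spec in enumerate(config.conditions):
        row = chr(ord("A") + i)
        for j in range(spec.n_replicates):
            well = f"{row}{j + 1}"
            layout_entries[well] = (spec.label, None, None)
            well_specs.append((well, spec))

    streams = np.random.SeedSequence(config.seed).spawn(len(well_specs))
    frames = []
    for (well, spec), stream in zip(well_specs, streams):
        rng = np.random.default_rng(stream)
        clean = logistic(t - spec.time_shift, spec.K, spec.N0, spec.r)
        noise = rng.normal(0.0, config.noise_sd, size=t.shape) if config.noise_sd else 0.0
        raw = (clean + config.background_level + noise) / config.calibration_factor
        frames.append(pd.DataFrame({"well": well, "time_h": t, "absorbance": raw}))

    return SimulatedPlate(
        frame=pd.concat(frames, ignore_index=True),
        layout=PlateLayout(layout_entries),
        truth=_ground_truth(config),
        config=config,
    )


def plate_frame_to_wide(frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long raw plate table to the wide dialect (time_h + one column per well)."""
    wide = frame.pivot(index="time_h", columns="well", values="absorbance")
    wide = wide.reset_index()
    wide.columns.name = None
    return wide


def lag_effect_via_n0(
    base_N0: float,
    target_delta_lag: float,
    r: float,
    K: float,
    threshold: float = 0.01,
) -> float:
    """N0 that shifts the closed-form lag by ``target_delta_lag`` hours.

    Solves lag(K, N0', r) = lag(K, base_N0, r) - target for N0' by inverting
    the logistic at the threshold:  N0' = K / (1 + ((K - c)/c) e^{r t'}).
    Positive targets shorten the lag (larger N0'); the effect leaves the
    doubling time essentially unchanged while N0' << K.

    Raises
    ------
    ParameterError
        If the target is infeasible (the required N0' reaches the threshold,
        i.e. the shortened lag would be non-positive).
    """
    if not (0 < base_N0 < threshold < K):
        raise ParameterError("need 0 < base_N0 < threshold < K")
    base_lag = lag_time(LogisticFit(K=K, N0=base_N0, r=r, sse=0.0, converged=True), threshold)
    t_target = base_lag - target_delta_lag
    n0_new = K / (1.0 + ((K - threshold) / threshold) * math.exp(r * t_target))
    if not n0_new < threshold:
        raise ParameterError(
            f"target delta lag {target_delta_lag} h infeasible: adjusted N0 "
            f"{n0_new:.3g} reaches the threshold {threshold}"
        )
    return n0_new


def standard_experiment(
    delta_lags: dict[str, float],
    n_replicates: int = 4,
    noise_sd: float = 0.003,
    seed: int = 0,
    K: float = 0.5,
    r: float = 0.8,
    control_N0: float = 1e-7,
    threshold: float = 0.01,
) -> SyntheticPlateConfig:
    """Config for a control-plus-supplements plate with injected lag effects.

    ``delta_lags`` maps each treatment label to its true lag shortening in
    hours (vs the control); the corresponding N0 values come from
    :func:`lag_effect_via_n0` so the closed-form ground truth is exact.  The
    control's effective N0 default (1e-7 OD600, control lag ~14.4 h at the
    default K and r) keeps the 2-8 h background window genuinely growth-free
    for every condition, including shortenings up to ~2.5 h — the stable
    non-growth phase is a stated property of the protocol this generator
    emulates.  (A nominal inoculum OD can be far above the *effective*
    logistic N0 when cells resume growth only after a true delay.)
    """
    conditions = [ConditionSpec("control", K, control_N0, r, n_replicates)]
    for label, delta in delta_lags.items():
        n0 = lag_effect_via_n0(control_N0, delta, r, K, threshold)
        conditions.append(ConditionSpec(label, K, n0, r, n_replicates))
    return SyntheticPlateConfig(
        conditions=tuple(conditions),
        control="control",
        noise_sd=noise_sd,
        lag_threshold=threshold,
        seed=seed,
    )


def simulate_feature_table(
    n_genes: int,
    n_samples: int,
    rrna_fraction: float = 0.05,
    de_fraction: float = 0.1,
    seed: int = 0,
    n_groups: int = 1,
    de_abs_log2fc: tuple[float, float] = (0.7, 2.5),
    de_padj_max: float = 0.04,
) -> FeatureTable:
    """Simulate a count table with negative-binomial-like counts and DE truth.

    Gene mean abundances are lognormal; rRNA-flagged genes sit at strongly
    elevated abundance.  A ``de_fraction`` of the non-rRNA genes receives
    significant DE statistics (|log2fc| drawn within ``de_abs_log2fc``, padj
    below ``de_padj_max``); the rest receive statistics failing at least one
    threshold.  Samples are split into ``n_groups`` contiguous groups (time
    points) for the abundance-floor rule.

    The returned table carries truth columns: ``is_rrna``, ``de_stats_true``
    (the DE thresholds pass) and ``is_de_truth`` (DE thresholds pass AND
    >=50 mean TPM in at least one group, computed here with independent
    arithmetic on the rRNA-removed table).  Identical seeds give identical
    tables.
    """
    if not 0.0 <= rrna_fraction <= 1.0 or not 0.0 <= de_fraction <= 1.0:
        raise ParameterError("fractions must lie in [0, 1]")
    if n_genes < 1 or n_samples < 1 or n_groups < 1 or n_groups > n_samples:
        raise ParameterError("invalid table dimensions")
    rng = np.random.default_rng(seed)

    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    lengths = rng.integers(200, 5000, size=n_genes)
    base_mean = rng.lognormal(mean=3.0, sigma=1.5, size=n_genes)

    n_rrna = int(round(rrna_fraction * n_genes))
    is_rrna = np.zeros(n_genes, dtype=bool)
    rrna_idx = rng.choice(n_genes, size=n_rrna, replace=False)
    is_rrna[rrna_idx] = True
    base_mean[is_rrna] *= 200.0  # rRNA dominates libraries before depletion

    # negative-binomial counts with mild per-sample depth variation
    depth = rng.lognormal(mean=0.0, sigma=0.15, size=n_samples)
    dispersion = 10.0
    counts = np.empty((n_genes, n_samples), dtype=float)
    for j in range(n_samples):
        mu = base_mean * depth[j]
        p = dispersion / (dispersion + mu)
        counts[:, j] = rng.negative_binomial(dispersion, p)

    # DE statistics: a designated subset passes both thresholds with margin,
    # everything else fails at least one.
    non_rrna_idx = np.flatnonzero(~is_rrna)
    n_de = int(round(de_fraction * non_rrna_idx.size))
    de_idx = rng.choice(non_rrna_idx, size=n_de, replace=False)
    de_stats_true = np.zeros(n_genes, dtype=bool)
    de_stats_true[de_idx] = True

    log2fc = np.where(
        rng.random(n_genes) < 0.5,
        rng.uniform(-0.5, 0.5, size=n_genes),
        rng.uniform(-0.55, 0.55, size=n_genes),
    )
    padj = rng.uniform(0.06, 1.0, size=n_genes)
    sign = np.where(rng.random(n_de) < 0.5, -1.0, 1.0)
    log2fc[de_idx] = sign * rng.uniform(*de_abs_log2fc, size=n_de)
    padj[de_idx] = 10.0 ** rng.uniform(-6.0, math.log10(de_padj_max), size=n_de)

    samples = [f"s{j + 1}" for j in range(n_samples)]
    groups = [list(chunk) for chunk in np.array_split(np.array(samples), n_groups)]

    # truth abundance on the rRNA-removed table, independent arithmetic
    sub = counts[~is_rrna]
    rates = sub / lengths[~is_rrna, None]
    tpm_sub = 1e6 * rates / rates.sum(axis=0, keepdims=True)
    sample_pos = {s: j for j, s in enumerate(samples)}
    floor_pass_sub = np.zeros(sub.shape[0], dtype=bool)
    for group in groups:
        cols = [sample_pos[s] for s in group]
        floor_pass_sub |= tpm_sub[:, cols].mean(axis=1) >= 50.0
    floor_pass = np.zeros(n_genes, dtype=bool)
    floor_pass[~is_rrna] = floor_pass_sub

    df = pd.DataFrame({"gene_id": gene_ids, "length": lengths})
    for j, s in enumerate(samples):
        df[s] = counts[:, j]
    df["log2fc"] = log2fc
    df["padj"] = padj
    df["is_rrna"] = is_rrna
    df["de_stats_true"] = de_stats_true
    df["is_de_truth"] = de_stats_true & floor_pass
    df.attrs["sample_groups"] = groups
    return FeatureTable(df=df, samples=tuple(samples))
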