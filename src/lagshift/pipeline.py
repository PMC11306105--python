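"""End-to-end plate analysis: raw table -> fits -> delta-lag statistics."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import (
    DEFAULT_BACKGROUND_WINDOW,
    DEFAULT_CALIBRATION_FACTOR,
    PlateLayout,
    calibrate_absorbance,
    read_plate_table,
    subtract_background,
    trim_to_growth_span,
)
from .logistic import (
    DEFAULT_LAG_THRESHOLD,
    fit_logistic,
    summarize_fits,
)
from .stats import compare_conditions

__all__ = ["fit_plate", "delta_lag_table", "analyze_plate"]


def fit_plate(
    source,
    layout: PlateLayout,
    dialect: str = "long",
    calibration_factor: float = DEFAULT_CALIBRATION_FACTOR,
    background_window: tuple[float, float] = DEFAULT_BACKGROUND_WINDOW,
    threshold: float = DEFAULT_LAG_THRESHOLD,
) -> pd.DataFrame:
    """Read, calibrate, background-correct, trim and fit every well.

    ``source`` is a CSV path or an already-loaded long-format DataFrame with
    columns ``well,time_h,absorbance``.  Returns the per-well fit table from
    :func:`lagshift.logistic.summarize_fits`.
    """
    if isinstance(source, (str, Path)):
        series = read_plate_table(source, dialect=dialect, layout=layout)
    else:
        import tempfile

        # route DataFrames through the same reader for identical validation
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as handle:
            source.to_csv(handle, index=False)
            path = handle.name
        series = read_plate_table(path, dialect=dialect, layout=layout)
        Path(path).unlink()

    fits = []
    for raw in series:
        calibrated = calibrate_absorbance(raw, factor=calibration_factor)
        curve = subtract_background(calibrated, window=background_window)
        curve = trim_to_growth_span(curve)
        fits.append(fit_logistic(curve))
    return summarize_fits(fits, threshold=threshold)


def delta_lag_table(
    fit_frame: pd.DataFrame,
    control: str,
    seed: int = 0,
    include_doubling: bool = True,
) -> pd.DataFrame:
    """Delta-lag statistics per treatment from a per-well fit table.

    Only converged wells contribute; non-growing wells are excluded from the
    replicate sets, matching how undetectable lag entries are reported.
    """
    good = fit_frame.loc[fit_frame["converged"] & fit_frame["lag_h"].notna()]
    lag_values = {
        cond: sub["lag_h"].tolist() for cond, sub in good.groupby("condition", sort=False)
    }
    doubling_values = None
    if include_doubling:
        with_dbl = good.loc[good["doubling_h"].notna()]
        doubling_values = {
            cond: sub["doubling_h"].tolist()
            for cond, sub in with_dbl.groupby("condition", sort=False)
        }
    return compare_conditions(lag_values, control, doubling_values, seed=seed)


def analyze_plate(
    source,
    layout: PlateLayout,
    control: str,
    dialect: str = "long",
    calibration_factor: float = DEFAULT_CALIBRATION_FACTOR,
    background_window: tuple[float, float] = DEFAULT_BACKGROUND_WINDOW,
    threshold: float = DEFAULT_LAG_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: returns (per-well fit table, delta-lag table)."""
    fits = fit_plate(
        source,
        layout,
        dialect=dialect,
        calibration_factor=calibration_factor,
        background_window=background_window,
        threshold=threshold,
    )
    deltas = delta_lag_table(fits, control=control, seed=seed)
    return fits, deltas
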