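"""Plate-reader ingest: parsing, absorbance calibration and background handling.

A 96-well plate reader reports raw absorbance per well over time.  Before any
growth-model fitting, three conventions are applied:

1. raw absorbance is converted to cuvette-equivalent OD600 by a multiplicative
   instrument calibration factor (default 3.8603, determined by comparing the
   plate reader against a 1 cm cuvette spectrophotometer);
2. the per-well background — the mean absorbance over the stable non-growth
   window, by default 2–8 h — is subtracted from every reading of that well;
3. each corrected series is trimmed to the span between its global minimum
   and global maximum, the portion the logistic model is fitted to.

Times are held in hours throughout the package; readers convert on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, PlateFormatError, PlateLayoutError

DEFAULT_CALIBRATION_FACTOR = 3.8603
DEFAULT_BACKGROUND_WINDOW = (2.0, 8.0)

__all__ = [
    "RawPlateSeries",
    "GrowthCurve",
    "PlateLayout",
    "read_plate_table",
    "calibrate_absorbance",
    "subtract_background",
    "trim_to_growth_span",
    "curves_to_frame",
    "DEFAULT_CALIBRATION_FACTOR",
    "DEFAULT_BACKGROUND_WINDOW",
]


@dataclass(frozen=True)
class RawPlateSeries:
    """One well's raw absorbance time series.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A1"``.
    time : ndarray
        Sampling times in hours, strictly increasing, at least 4 points.
    absorbance : ndarray
        Raw plate-reader absorbance, same length as ``time``, all finite.
    condition : str
        Experimental condition label from the plate layout.
    replicate_index : int
        1-based replicate number within the condition.
    """

    well_id: str
    time: np.ndarray
    absorbance: np.ndarray
    condition: str
    replicate_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise DataError("time and absorbance must be 1-D arrays of equal length")
        if t.size < 4:
            raise DataError(f"well {self.well_id}: need >=4 time points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise PlateFormatError(f"well {self.well_id}: time must be strictly increasing")
        if t[0] < 0:
            raise DataError(f"well {self.well_id}: negative time")
        if not np.all(np.isfinite(a)):
            raise DataError(f"well {self.well_id}: non-finite absorbance")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class GrowthCurve:
    """A background-corrected OD600 series for one well.

    ``od600`` may contain small negative values: background subtraction is not
    clipped, because clipping would bias the fitted initial population size.
    ``non_growing`` is set by :func:`trim_to_growth_span` when the series
    maximum precedes its minimum (the well never grew).
    """

    well_id: str
    time: np.ndarray
    od600: np.ndarray
    condition: str
    replicate_index: int
    background_value: float
    non_growing: bool = field(default=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.od600, dtype=float)
        if y.shape != t.shape:
            raise DataError("time and od600 must have equal length")
        if not np.isfinite(self.background_value):
            raise DataError("background_value must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od600", y)

    def __len__(self) -> int:
        return self.time.size


class PlateLayout:
    """Map from well id to (condition, supplement, molar concentration).

    The layout is the experimenter's condition map for a plate.  Conditions
    with several wells are biological replicates; replicate indices are
    assigned deterministically by well id order at read time.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str | None, float | None]]):
        self._entries = dict(entries)
        if not self._entries:
            raise ParameterError("layout must contain at least one well")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        """Read a layout CSV with columns well,condition,supplement,concentration_molar."""
        df = pd.read_csv(path)
        required = {"well", "condition"}
        if not required.issubset(df.columns):
            raise PlateFormatError(f"layout file must have columns {sorted(required)}")
        if df["well"].duplicated().any():
            dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
            raise PlateFormatError(f"well {dup!r} appears more than once in layout")
        entries = {}
        for row in df.itertuples(index=False):
            supplement = getattr(row, "supplement", None)
            conc = getattr(row, "concentration_molar", None)
            conc = float(conc) if conc is not None and pd.notna(conc) else None
            entries[str(row.well)] = (str(row.condition), supplement, conc)
        return cls(entries)

    def condition_of(self, well_id: str) -> str:
        try:
            return self._entries[well_id][0]
        except KeyError:
            raise PlateLayoutError(f"well {well_id!r} not present in layout") from None

    def wells(self) -> list[str]:
        return sorted(self._entries)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _, _ in self._entries.values():
            seen.setdefault(cond, None)
        return list(seen)

    def __contains__(self, well_id: str) -> bool:
        return well_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)


def _frame_to_series(df: pd.DataFrame, layout: PlateLayout) -> list[RawPlateSeries]:
    if df.duplicated(subset=["well", "time_h"]).any():
        bad = df.loc[df.duplicated(subset=["well", "time_h"]), ["well", "time_h"]].iloc[0]
        raise PlateFormatError(
            f"duplicated (well, time) row: well={bad['well']!r} time={bad['time_h']}"
        )
    # deterministic replicate numbering: wells sorted within each condition
    wells = sorted(df["well"].unique())
    rep_counter: dict[str, int] = {}
    out = []
    for well in wells:
        condition = layout.condition_of(well)
        rep_counter[condition] = rep_counter.get(condition, 0) + 1
        sub = df.loc[df["well"] == well].sort_values("time_h")
        out.append(
            RawPlateSeries(
                well_id=well,
                time=sub["time_h"].to_numpy(float),
                absorbance=sub["absorbance"].to_numpy(float),
                condition=condition,
                replicate_index=rep_counter[condition],
            )
        )
    return out


def read_plate_table(
    path: str | Path,
    dialect: str = "long",
    layout: PlateLayout | None = None,
    time_unit: str = "h",
) -> list[RawPlateSeries]:
    """Read a plate-reader CSV export into one series per well.

    Two dialects are supported.  ``"long"`` expects columns
    ``well,time_h,absorbance``; ``"wide"`` expects a first column ``time_h``
    followed by one column per well.  Both produce identical output for the
    same underlying data.  ``time_unit`` may be ``"h"``, ``"min"`` or ``"s"``;
    values are converted to hours.

    Raises
    ------
    PlateLayoutError
        If a well in the file is missing from ``layout``.
    PlateFormatError
        If the file violates the declared dialect or contains duplicated
        (well, time) rows or non-monotone times.
    """
    if layout is None:
        raise ParameterError("a PlateLayout is required")
    scale = {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}.get(time_unit)
    if scale is None:
        raise ParameterError(f"unknown time unit {time_unit!r}")

    df = pd.read_csv(path)
    if dialect == "long":
        required = {"well", "time_h", "absorbance"}
        if not required.issubset(df.columns):
            raise PlateFormatError(f"long dialect requires columns {sorted(required)}")
        df = df[["well", "time_h", "absorbance"]].copy()
        df["well"] = df["well"].astype(str)
    elif dialect == "wide":
        if df.columns[0] != "time_h":
            raise PlateFormatError("wide dialect requires first column 'time_h'")
        df = df.melt(id_vars="time_h", var_name="well", value_name="absorbance")
        df["well"] = df["well"].astype(str)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    df["time_h"] = df["time_h"].astype(float) * scale
    return _frame_to_series(df, layout)


def calibrate_absorbance(
    series: RawPlateSeries, factor: float = DEFAULT_CALIBRATION_FACTOR
) -> RawPlateSeries:
    """Convert plate-reader absorbance to cuvette-equivalent OD600.

    Multiplies every reading by ``factor`` (instrument-specific; the default
    3.8603 corrects a 150 µl well under hexadecane to a 1 cm light path).
    """
    if not factor > 0:
        raise ParameterError(f"calibration factor must be positive, got {factor}")
    return replace(series, absorbance=series.absorbance * float(factor))


def subtract_background(
    series: RawPlateSeries,
    window: tuple[float, float] = DEFAULT_BACKGROUND_WINDOW,
) -> GrowthCurve:
    """Subtract this well's own non-growth background from every reading.

    The background is the mean absorbance over ``window`` (hours, inclusive),
    the phase where OD is stable before growth starts.  Each well uses its own
    background; negative corrected values are retained.
    """
    t_start, t_end = window
    if not t_end > t_start:
        raise ParameterError(f"invalid background window {window}")
    mask = (series.time >= t_start) & (series.time <= t_end)
    if mask.sum() < 2:
        raise ParameterError(
            f"background window {window} covers {int(mask.sum())} point(s) in "
            f"well {series.well_id}; need >=2"
        )
    background = float(series.absorbance[mask].mean())
    return GrowthCurve(
        well_id=series.well_id,
        time=series.time,
        od600=series.absorbance - background,
        condition=series.condition,
        replicate_index=series.replicate_index,
        background_value=background,
    )


def trim_to_growth_span(curve: GrowthCurve) -> GrowthCurve:
    """Restrict a curve to the span from its lowest to its highest OD600.

    The logistic model describes the rise from minimum to maximum; leading
    dips (e.g. condensation settling) and any post-peak decline are removed.
    If the global maximum precedes the global minimum the well never grew:
    the untrimmed curve is returned with ``non_growing=True``.
    """
    if len(curve) == 0:
        raise DataError("cannot trim an empty curve")
    i_min = int(np.argmin(curve.od600))
    i_max = int(np.argmax(curve.od600))
    if i_max < i_min:
        return replace(curve, non_growing=True)
    return replace(
        curve,
        time=curve.time[i_min : i_max + 1],
        od600=curve.od600[i_min : i_max + 1],
    )


def curves_to_frame(curves: Iterable[GrowthCurve]) -> pd.DataFrame:
    """Tidy long-format DataFrame of corrected curves (one row per reading)."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "well": c.well_id,
                    "condition": c.condition,
                    "replicate": c.replicate_index,
                    "time_h": c.time,
                    "od600": c.od600,
                    "background": c.background_value,
                    "non_growing": c.non_growing,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["well", "condition", "replicate", "time_h", "od600", "background", "non_growing"]
        )
    return pd.concat(rows, ignore_index=True)
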