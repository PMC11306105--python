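import numpy as np
import pytest

from lagshift.io import GrowthCurve, PlateLayout, RawPlateSeries


@pytest.fixture
def simple_layout():
    return PlateLayout(
        {
            "A1": ("control", None, None),
            "A2": ("control", None, None),
            "B1": ("dmsp", "DMSP", 2e-6),
        }
    )


@pytest.fixture
def raw_series():
    return RawPlateSeries(
        well_id="A1",
        time=np.array([2.0, 4.0, 6.0, 10.0, 14.0]),
        absorbance=np.array([0.05, 0.05, 0.05, 0.15, 0.45]),
        condition="control",
        replicate_index=1,
    )


def make_curve(time, od600, well="A1", condition="control", replicate=1, background=0.0):
    return GrowthCurve(
        well_id=well,
        time=np.asarray(time, dtype=float),
        od600=np.asarray(od600, dtype=float),
        condition=condition,
        replicate_index=replicate,
        background_value=background,
    )
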