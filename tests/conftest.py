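"""Shared fixtures: in-memory rasters and a small default scenario."""

import numpy as np
import pytest

from senoscope.image_io import CellMask, image_from_array
from senoscope.synthetic import ScenarioSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_mask():
    """8x8 mask with a 4x4 True block in the upper-left corner."""
    region = np.zeros((8, 8), dtype=bool)
    region[:4, :4] = True
    return CellMask(region=region)


@pytest.fixture
def unit_image():
    """8x8 plane of ones with 1 µm isotropic pixels."""
    return image_from_array(np.ones((8, 8)), pixel_size_x=1.0, pixel_size_y=1.0)


@pytest.fixture
def small_spec():
    """Two donors x two inducers at the bottom of the study's cell range."""
    return ScenarioSpec(
        seed=11,
        donors={"YD": 0.0, "OD": 0.3},
        inducers={"C10": 0.0, "Doxo": 0.35},
        s_percent_boost={"C10": 0.0, "Doxo": 55.0},
        v_rel_percent={"C10": 100.0, "Doxo": 88.0},
        flow_mfi_fold={"C10": 1.0, "Doxo": 2.5},
        n_cells_per_condition=95,
        events_per_cell=120,
    )
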