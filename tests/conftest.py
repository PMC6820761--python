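"""Shared fixtures: spectral axis, band table, and simulated cubes.

The small cube (32 x 32) backs most unit tests; the desk-scale cube
(128 x 128, the default study configuration) is built once per session and
backs the noise-model and calibration checks that need realistic statistics.
"""

from collections import namedtuple

import numpy as np
import pytest

from ftirsim import (
    SimulationConfig,
    build_clean_cube,
    build_mask,
    blur_cube,
    load_band_table,
    make_axis,
    synth_core_maps,
)
from ftirsim.config import GridConfig, NoiseConfig
from ftirsim.pipeline import simulate_clean

SimSet = namedtuple("SimSet", "config maps preblur clean mask")


@pytest.fixture(scope="session")
def axis():
    return make_axis()


@pytest.fixture(scope="session")
def band_table():
    return load_band_table()


@pytest.fixture(scope="session")
def small_sim():
    """A 32 x 32 px simulated core, through assembly + blur + mask."""
    config = SimulationConfig(
        grid=GridConfig(rows=32, cols=32, core_radius_px=14.0,
                        smoothness_px=4.0, lipid_smoothness_px=2.0),
        noise=NoiseConfig(scans=(4, 16)),
        seed=7,
    )
    return SimSet(config, *simulate_clean(config))


@pytest.fixture(scope="session")
def desk_sim():
    """The desk-scale default study configuration (128 x 128 px)."""
    config = SimulationConfig(seed=1)
    return SimSet(config, *simulate_clean(config))
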