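"""Shared fixtures.

The two expensive fixtures (an overfit run on 8 fixed scenes and a 50-scene
training run) are session-scoped so the whole suite pays for each training
loop once.  All randomness is seeded; reruns are bit-identical.
"""

from __future__ import annotations

import numpy as np
import pytest

from woundseg.area import fit_calibration
from woundseg.segnet import NetworkConfig, build_network
from woundseg.synthetic import (
    SCALED_CAMERA,
    CalibrationSeriesSpec,
    generate_scenes,
    render_calibration_series,
)
from woundseg.training import TrainConfig, train

# conditions for CPU-sized runs: the scaled camera keeps the default camera's
# field of view; close-up heights give wounds a realistic share of the frame
OVERFIT_SCENES = dict(
    seed=7, camera=SCALED_CAMERA, area_range_cm2=(15.0, 35.0),
    height_range_mm=(120.0, 220.0),
)
PIPELINE_SCENES = dict(
    camera=SCALED_CAMERA, area_range_cm2=(10.0, 35.0), height_range_mm=(120.0, 300.0),
)


def small_config(input_side: int = 64, **kwargs) -> NetworkConfig:
    defaults = dict(
        variant=813,
        input_side=input_side,
        stage_channels=(8, 16, 32, 64, 128),
        ca_reduction=4,
        seed=1,
    )
    defaults.update(kwargs)
    return NetworkConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def calibration_curve_small():
    """Degree-4 inverse-basis fit on the scaled camera's prior-graphic series."""
    records = render_calibration_series(CalibrationSeriesSpec(camera=SCALED_CAMERA))
    return fit_calibration(records)


@pytest.fixture(scope="session")
def overfit_run():
    """Variant-813 network trained 300 steps on 8 fixed synthetic scenes."""
    scenes = generate_scenes(8, **OVERFIT_SCENES)
    net = build_network(small_config(input_side=64))
    result = train(
        scenes,
        net,
        TrainConfig(epochs=300, max_steps=300, batch_size=8, val_fraction=0.0, seed=3),
    )
    return {"network": net, "result": result, "scenes": scenes}


@pytest.fixture(scope="session")
def pipeline_run():
    """50 training scenes, 200 optimizer steps, held-out test scenes."""
    scenes = generate_scenes(50, seed=11, **PIPELINE_SCENES)
    net = build_network(small_config(input_side=160))
    result = train(
        scenes,
        net,
        TrainConfig(epochs=100, max_steps=200, batch_size=8, val_fraction=0.2, seed=3),
    )
    test_scenes = generate_scenes(10, seed=99, **PIPELINE_SCENES)
    return {"network": net, "result": result, "test_scenes": test_scenes}
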