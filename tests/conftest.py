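import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "stable",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("stable")

from map3d import OpticalConfig, TargetSpot, synthesize_plan
from map3d.optsim import VolumeGrid


@pytest.fixture
def cfg():
    """Small DMD with a half-unit shear per µm of depth (tanθ = 0.5)."""
    return OpticalConfig(
        dmd_cols=512, dmd_rows=512, um_per_px=1.0, theta=math.atan(0.5)
    )


@pytest.fixture
def single_target_plan(cfg):
    target = TargetSpot(5.0, -3.0, 20.0, radius_px=5)
    return synthesize_plan([target], cfg)


@pytest.fixture
def coarse_grid():
    return VolumeGrid(nx=32, ny=32, nz=17, dx=2.0, dy=2.0, dz=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
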