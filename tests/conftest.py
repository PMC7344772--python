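"""Shared fixtures: reduced-size platform configurations.

The full-resolution platform is used only by the acceptance tests; unit
and property tests run on either a scaled-down platform (same physics,
smaller footprint) or the default geometry at reduced vertical/margin
resolution, so the whole suite stays fast.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import telisim as ts
from telisim.cli_io import RunConfig, SolverSettings
from telisim.core_model import GridResolution, PlatformGeometry

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tiny_geometry(**overrides) -> PlatformGeometry:
    """A scaled-down platform: same layer structure, smaller footprint."""
    defaults = dict(
        channel_length=800.0, channel_width=600.0, channel_height=50.0,
        rz_diameter=150.0, rz_height=5.0,
        junction_diameter=150.0, junction_separation=250.0,
        track_width=60.0, frame_margin=300.0,
        substrate_slab_thickness=200.0,
    )
    defaults.update(overrides)
    return PlatformGeometry(**defaults)


def tiny_resolution(**overrides) -> GridResolution:
    defaults = dict(dxy=18.75, n_z_rz=2, n_z_liquid=4, n_z_slab=2, n_margin=2)
    defaults.update(overrides)
    return GridResolution(**defaults)


@pytest.fixture(scope="session")
def tiny_grid():
    return ts.build_grid(ts.build_geometry(tiny_geometry()), tiny_resolution())


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    """Default platform geometry at reduced vertical/margin resolution
    and 20 ms sampling — the reduced-grid forward model used for the
    inference recovery studies."""
    return RunConfig(
        resolution=GridResolution(dxy=62.5, n_z_rz=2, n_z_liquid=4,
                                  n_z_slab=2, n_margin=2),
        solver=SolverSettings(dt=0.02, t_end=30.0),
    )


@pytest.fixture(scope="session")
def fast_fm(fast_config) -> ts.ForwardModel:
    fm = fast_config.build_forward_model()
    fm.transport_kernel()
    fm.thermal_kernel()
    return fm


@pytest.fixture(scope="session")
def tiny_fm(tiny_grid) -> ts.ForwardModel:
    """Forward model on the scaled-down platform, 10 s horizon."""
    return ts.ForwardModel(grid=tiny_grid, dt=0.02, t_end=10.0)
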