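"""Shared fixtures: small synthetic volumes and fast experiment configs.

Everything is generated programmatically; heavyweight end-to-end results
are session-scoped so acceptance checks reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from dsabox.drr import VoxelVolume
from dsabox.evaluation import ExperimentConfig
from dsabox.geometry import make_view_geometry
from dsabox.phantoms import build_head_phantom

MU_SPHERE = 0.02  # 1/mm target attenuation of the test sphere
SPHERE_RADIUS = 30.0


def make_sphere_volume(radius: float = SPHERE_RADIUS, spacing: float = 1.0,
                       n: int = 96, mu: float = MU_SPHERE) -> VoxelVolume:
    """Homogeneous sphere with exactly known attenuation ``mu`` inside,
    air outside (HU chosen so hu_to_attenuation gives ``mu``).  The
    boundary is antialiased so line integrals track the analytic chord."""
    from dsabox.phantoms import _paint_sphere

    hu = (mu / 0.0205 - 1.0) * 1000.0
    origin = -(np.full(3, n) - 1) / 2 * spacing
    vol = VoxelVolume(origin=origin, spacing=np.full(3, spacing),
                      values=np.full((n, n, n), -1000.0, dtype=np.float32))
    _paint_sphere(vol, np.zeros(3), radius, hu)
    return vol


@pytest.fixture(scope="session")
def sphere_volume() -> VoxelVolume:
    return make_sphere_volume()


@pytest.fixture(scope="session")
def frontal_geometry():
    return make_view_geometry("frontal", 1000.0, 1500.0, (256, 256), 1.0)


@pytest.fixture(scope="session")
def geometry_pair():
    return [make_view_geometry(v, 1000.0, 1500.0, (128, 128), 2.0)
            for v in ("frontal", "sagittal")]


@pytest.fixture(scope="session")
def coarse_head():
    """Head phantom at 2.5 mm spacing — fast enough for registration tests."""
    return build_head_phantom(spacing_mm=2.5)


def fast_config() -> ExperimentConfig:
    """Downscaled stated world for speed-sensitive probes (capture-range,
    error-propagation); accuracy bounds are checked at the default scale."""
    return ExperimentConfig(
        cubic_edge_mm=100.0,
        cubic_ct_spacing_mm=1.5,
        cubic_detector=(128, 128),
        cubic_pixel_mm=1.5,
        head_ct_spacing_mm=2.5,
        head_detector=(96, 96),
        head_pixel_mm=3.0,
        maxfev_per_level=500,
    )


@pytest.fixture()
def fast_experiment_config() -> ExperimentConfig:
    return fast_config()
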