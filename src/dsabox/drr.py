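"""Digitally reconstructed radiographs (DRRs) from a CT volume.

A DRR pixel holds the line integral of linear attenuation along the ray
from the X-ray source through that pixel center, with the CT volume held
at a rigid pose about the isocenter ("the volume moves, the rays stay").
Intensities are raw integrals (dimensionless, mu * mm); an exponential
display transform is available for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._raycast import integrate_rays
from .geometry import (IDENTITY_POSE, GeometryError, ProjectionGeometry,
                       RigidPose)

#: water attenuation coefficient, 1/mm, at ~70 keV effective energy
MU_WATER_DEFAULT = 0.0205


@dataclass
class VoxelVolume:
    """A regular axis-aligned 3D grid of HU values in the patient (LPS)
    frame.  ``origin`` is the world position of the *center* of voxel
    (0, 0, 0); ``values`` is indexed [ix, iy, iz]."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_lo(self) -> np.ndarray:
        """Lower corner of the physical volume (edge of voxel (0,0,0))."""
        return self.origin - 0.5 * self.spacing

    @property
    def extent_hi(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 0.5) * self.spacing

    @property
    def center(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) / 2 * self.spacing

    def voxel_centers_axes(self):
        return tuple(self.origin[i] + np.arange(self.dims[i]) * self.spacing[i]
                     for i in range(3))


@dataclass
class PlanarImage:
    """A planar image on a detector: native X-ray, DSA, or DRR.

    ``values`` is indexed [iu, iv], matching the geometry's detector axes.
    """

    values: np.ndarray
    geometry: ProjectionGeometry
    kind: str = "drr"  # {native_xray, dsa, drr}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.geometry.detector_size):
            raise ValueError(
                f"image shape {self.values.shape} does not match detector "
                f"size {self.geometry.detector_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("planar image contains non-finite values")

    @property
    def pixel_spacing(self) -> Tuple[float, float]:
        return (self.geometry.pixel_spacing_u, self.geometry.pixel_spacing_v)


def hu_to_attenuation(hu, mu_water: float = MU_WATER_DEFAULT):
    """Linear attenuation (1/mm) from Hounsfield units:
    mu = mu_water * (1 + HU/1000), clamped at zero (air and below -> 0)."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0), 0.0)


# Cache of zero-padded attenuation grids keyed by the identity of the HU
# array, so repeated renders during optimization skip the conversion.
_MU_CACHE: dict = {}


def _padded_attenuation(volume: VoxelVolume, mu_water: float) -> np.ndarray:
    key = (id(volume.values), volume.values.shape, float(mu_water))
    hit = _MU_CACHE.get(key)
    if hit is not None and hit[0] is volume.values:
        return hit[1]
    mu = hu_to_attenuation(volume.values, mu_water).astype(np.float32)
    padded = np.zeros(tuple(n + 2 for n in mu.shape), dtype=np.float32)
    padded[1:-1, 1:-1, 1:-1] = mu
    _MU_CACHE.clear()  # keep at most one volume resident
    _MU_CACHE[key] = (volume.values, padded)
    return padded


def _ray_box_intersection(src, dirs, lo, hi):
    """Slab intersection of rays with an AABB; returns (t0, t1) arrays."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
    tl = (lo[None, :] - src[None, :]) * inv
    th = (hi[None, :] - src[None, :]) * inv
    # for zero direction components the slab constraint is src in [lo, hi]
    zero = np.abs(dirs) < 1e-12
    inside = (src[None, :] >= lo[None, :]) & (src[None, :] <= hi[None, :])
    tl = np.where(zero, np.where(inside, -np.inf, np.inf), tl)
    th = np.where(zero, np.where(inside, np.inf, -np.inf), th)
    tmin = np.nanmax(np.minimum(tl, th), axis=1)
    tmax = np.nanmin(np.maximum(tl, th), axis=1)
    tmin = np.maximum(tmin, 0.0)
    return tmin, tmax


def render_drr(volume: VoxelVolume,
               geometry: ProjectionGeometry,
               pose: RigidPose = IDENTITY_POSE,
               step_mm: Optional[float] = None,
               mu_water: float = MU_WATER_DEFAULT) -> PlanarImage:
    """Render a DRR of ``volume`` posed by ``pose`` onto ``geometry``.

    Fixed-step ray marching with trilinear interpolation; attenuation is
    zero outside the volume.  Default step is half the minimum voxel
    spacing.
    """
    if step_mm is None:
        step_mm = 0.5 * float(np.min(volume.spacing))
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")

    mu_padded = _padded_attenuation(volume, mu_water)

    # transform rays into the (unposed) volume frame
    rinv = pose.rotation_matrix().T
    t = pose.translation
    src_v = rinv @ (geometry.source_position - t)
    pix_world = geometry.pixel_grid_world().reshape(-1, 3)
    pix_v = (pix_world - t) @ rinv.T
    dirs = pix_v - src_v
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    t0, t1 = _ray_box_intersection(src_v, dirs, volume.extent_lo, volume.extent_hi)
    origin_pad = volume.origin - volume.spacing
    vals = integrate_rays(mu_padded, origin_pad.astype(np.float64),
                          volume.spacing.astype(np.float64),
                          src_v.astype(np.float64),
                          np.ascontiguousarray(dirs, dtype=np.float64),
                          t0.astype(np.float64), t1.astype(np.float64),
                          float(step_mm))
    nu, nv = geometry.detector_size
    return PlanarImage(values=vals.reshape(nu, nv), geometry=geometry, kind="drr")


def display_transform(image: PlanarImage) -> np.ndarray:
    """Radiograph-like display: exp(-integral).  Visualization only."""
    return np.exp(-image.values)
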