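"""Synthetic test phantoms and acquisition configurations.

Two phantoms cover the accuracy experiments from trivial to head-like:

* a homogeneous soft-tissue cube with a 2 mm metal ball at its exact
  center, and
* a head-like phantom — an ellipsoidal bone shell around soft tissue with
  a cubic air cavity holding three non-collinear metal markers.

Eleven named acquisition configurations vary couch shift, detector roll /
pitch, phantom yaw and field of view; simulated native X-rays and DSA
images are DRRs (plus seeded Gaussian noise), so the native and DSA image
of a view share the identical geometry — they are intrinsically
registered, as real subtraction angiography is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .drr import MU_WATER_DEFAULT, PlanarImage, VoxelVolume, render_drr
from .geometry import (IDENTITY_POSE, ProjectionGeometry, RigidPose,
                       make_view_geometry)

HU_AIR = -1000.0
HU_SOFT_TISSUE = 30.0
HU_WATER = 0.0
HU_BONE = 1200.0
HU_METAL = 3000.0
#: threshold separating metal targets from everything else
METAL_THRESHOLD_HU = 1500.0

#: head-phantom marker centers (mm, LPS, inside the air cavity) and size:
#: fixed, non-collinear, well separated in both canonical projections.
HEAD_MARKER_CENTERS = np.array([
    [-18.0, -12.0, -15.0],
    [22.0, 6.0, 2.0],
    [-2.0, 14.0, 18.0],
])
HEAD_MARKER_DIAMETER = 3.0


@dataclass
class PhantomSpec:
    kind: str  # {cubic, head}
    edge_mm: Optional[float] = None
    axes_mm: Optional[Tuple[float, float, float]] = None
    marker_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    marker_diameter_mm: float = 2.0
    materials_hu: Dict[str, float] = field(default_factory=lambda: {
        "air": HU_AIR, "soft_tissue": HU_SOFT_TISSUE,
        "bone": HU_BONE, "metal": HU_METAL})


@dataclass(frozen=True)
class ConfigurationCase:
    """One acquisition configuration of the head-phantom robustness sweep."""
    name: str
    couch_shift_mm: float = 0.0  # lateral (x) shift of the phantom
    roll_deg: float = 0.0        # imaging directions rotated about longitudinal (z) axis
    pitch_deg: float = 0.0       # imaging directions rotated about lateral (x) axis
    yaw_deg: float = 0.0         # phantom rotated about vertical couch (y) axis
    fov_fraction: float = 1.0    # 1.0 = full detector, <1 = central crop

    def __post_init__(self):
        if not (0.0 < self.fov_fraction <= 1.0):
            raise ValueError("fov_fraction must be in (0, 1]")


#: The 11 evaluated configurations, in report order.  "about 30 deg" yaw is
#: fixed at exactly 30.  Frame_Standard vs NoFrame_Standard differ only in
#: immobilization hardware, which has no geometric effect here; both are
#: kept as distinct named cases.
CONFIGURATIONS: Dict[str, ConfigurationCase] = {c.name: c for c in [
    ConfigurationCase("Frame_Standard"),
    ConfigurationCase("NoFrame_Standard"),
    ConfigurationCase("NoFrame_SmallFOV", fov_fraction=0.5),
    ConfigurationCase("NoFrame_Couchshift -10 cm", couch_shift_mm=-100.0),
    ConfigurationCase("NoFrame_Couchshift -5 cm", couch_shift_mm=-50.0),
    ConfigurationCase("NoFrame_Couchshift 0 cm"),
    ConfigurationCase("NoFrame_Couchshift 5 cm", couch_shift_mm=50.0),
    ConfigurationCase("NoFrame_Couchshift 10 cm", couch_shift_mm=100.0),
    ConfigurationCase("NoFrame_Roll45", roll_deg=45.0),
    ConfigurationCase("NoFrame_Pitch30", pitch_deg=30.0),
    ConfigurationCase("NoFrame_Yaw30", yaw_deg=30.0),
]}


def list_configurations() -> List[str]:
    return list(CONFIGURATIONS)


# ---------------------------------------------------------------------------
# Volume painting helpers
# ---------------------------------------------------------------------------


def _centered_volume(extent_mm: Sequence[float], spacing_mm: float,
                     fill_hu: float = HU_AIR) -> VoxelVolume:
    dims = tuple(int(np.ceil(e / spacing_mm)) for e in extent_mm)
    spacing = np.full(3, float(spacing_mm))
    origin = -(np.array(dims) - 1) / 2 * spacing
    return VoxelVolume(origin=origin, spacing=spacing,
                       values=np.full(dims, fill_hu, dtype=np.float32))


def _paint_sphere(volume: VoxelVolume, center: Sequence[float], radius: float,
                  hu: float, supersample: int = 3) -> None:
    """Paint a sphere with partial-volume antialiasing: each boundary voxel
    gets a HU mix proportional to its covered fraction."""
    center = np.asarray(center, dtype=float)
    lo_idx = np.maximum(
        np.floor((center - radius - volume.origin) / volume.spacing - 1), 0
    ).astype(int)
    hi_idx = np.minimum(
        np.ceil((center + radius - volume.origin) / volume.spacing + 1),
        np.array(volume.dims) - 1).astype(int)
    if np.any(lo_idx > hi_idx):
        return
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5  # subvoxel offsets in voxel units
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    axes = [volume.origin[i] + np.arange(lo_idx[i], hi_idx[i] + 1) * volume.spacing[i]
            for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1)  # (a,b,c,3)
    frac = np.zeros(centers.shape[:3])
    for off in sub:
        pts = centers + off * volume.spacing
        frac += np.sum((pts - center) ** 2, axis=-1) <= radius ** 2
    frac /= len(sub)
    region = volume.values[lo_idx[0]:hi_idx[0] + 1,
                           lo_idx[1]:hi_idx[1] + 1,
                           lo_idx[2]:hi_idx[2] + 1]
    volume.values[lo_idx[0]:hi_idx[0] + 1,
                  lo_idx[1]:hi_idx[1] + 1,
                  lo_idx[2]:hi_idx[2] + 1] = region * (1 - frac) + hu * frac


# ---------------------------------------------------------------------------
# Phantom builders
# ---------------------------------------------------------------------------


def build_cubic_phantom(edge_mm: float = 120.0,
                        ball_diameter_mm: float = 2.0,
                        spacing_mm: float = 1.0,
                        margin_mm: float = 5.0
                        ) -> Tuple[VoxelVolume, np.ndarray]:
    """Homogeneous water-equivalent cube in air with a metal ball at the
    exact volume center (the isocenter).  Returns (volume, ball center)."""
    if ball_diameter_mm >= edge_mm:
        raise ValueError("ball must fit inside the cube")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    vol = _centered_volume([edge_mm + 2 * margin_mm] * 3, spacing_mm)
    axes = vol.voxel_centers_axes()
    inside = [(np.abs(a) <= edge_mm / 2) for a in axes]
    cube = inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    vol.values[cube] = HU_WATER
    _paint_sphere(vol, (0.0, 0.0, 0.0), ball_diameter_mm / 2, HU_METAL)
    return vol, np.zeros(3)


def build_head_phantom(spacing_mm: float = 1.25,
                       outer_axes_mm: Tuple[float, float, float] = (72.0, 88.0, 92.0),
                       shell_thickness_mm: float = 6.0,
                       cavity_edge_mm: float = 60.0,
                       marker_centers: Optional[np.ndarray] = None,
                       marker_diameter_mm: float = HEAD_MARKER_DIAMETER,
                       ) -> Tuple[VoxelVolume, np.ndarray]:
    """Head-like phantom: ellipsoidal bone shell (semi-axes
    ``outer_axes_mm``) around soft tissue, a cubic air cavity at the center
    holding three metal markers.  Returns (volume, marker centers (3, 3))."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if marker_centers is None:
        marker_centers = HEAD_MARKER_CENTERS
    marker_centers = np.asarray(marker_centers, dtype=float)
    a = np.asarray(outer_axes_mm, dtype=float)
    vol = _centered_volume(2 * a + 10.0, spacing_mm)
    axes = vol.voxel_centers_axes()
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    outer = (gx / a[0]) ** 2 + (gy / a[1]) ** 2 + (gz / a[2]) ** 2 <= 1.0
    ai = a - shell_thickness_mm
    inner = (gx / ai[0]) ** 2 + (gy / ai[1]) ** 2 + (gz / ai[2]) ** 2 <= 1.0
    vol.values[outer] = HU_BONE
    vol.values[inner] = HU_SOFT_TISSUE
    h = cavity_edge_mm / 2
    cavity = (np.abs(gx) <= h) & (np.abs(gy) <= h) & (np.abs(gz) <= h)
    vol.values[cavity] = HU_AIR
    for c in marker_centers:
        if np.any(np.abs(c) + marker_diameter_mm / 2 > h):
            raise ValueError(f"marker {c} does not fit inside the cavity")
        _paint_sphere(vol, c, marker_diameter_mm / 2, HU_METAL)
    return vol, marker_centers


def target_only_volume(volume: VoxelVolume,
                       threshold_hu: float = METAL_THRESHOLD_HU) -> VoxelVolume:
    """The metal/target component of a phantom on an air background — the
    stand-in for the contrast-filled vasculature a DSA would show.

    Thresholding blended HU misses sub-voxel markers on coarse grids;
    prefer :func:`make_target_volume` when the marker geometry is known.
    """
    vals = np.where(volume.values >= threshold_hu, volume.values, HU_AIR)
    return VoxelVolume(origin=volume.origin.copy(), spacing=volume.spacing.copy(),
                       values=vals.astype(np.float32))


def make_target_volume(volume_like: VoxelVolume,
                       marker_centers: np.ndarray,
                       marker_diameter_mm: float) -> VoxelVolume:
    """Metal markers painted (antialiased) on an air background, on the
    same grid as ``volume_like`` — the exact target component of the
    phantom, independent of CT resolution."""
    vol = VoxelVolume(origin=volume_like.origin.copy(),
                      spacing=volume_like.spacing.copy(),
                      values=np.full(volume_like.dims, HU_AIR, dtype=np.float32))
    for c in np.atleast_2d(marker_centers):
        _paint_sphere(vol, c, marker_diameter_mm / 2, HU_METAL)
    return vol


# ---------------------------------------------------------------------------
# Acquisition configurations
# ---------------------------------------------------------------------------


@dataclass
class ConfiguredAcquisition:
    """Geometry pair + phantom pose + per-view FOV masks for one case."""
    case: ConfigurationCase
    geometries: List[ProjectionGeometry]
    phantom_pose: RigidPose
    fov_masks: List[Optional[np.ndarray]]


def make_configuration(case: ConfigurationCase | str,
                       sad: float = 1000.0,
                       sid: float = 1500.0,
                       detector_size: Tuple[int, int] = (256, 256),
                       pixel_spacing: float = 1.0) -> ConfiguredAcquisition:
    """Realize a named configuration: rotate the two imaging directions by
    roll/pitch, pose the phantom (lateral couch shift + yaw), crop the FOV.

    For couch-shift cases each detector is re-centred in-plane on the
    projected phantom center (as a technologist keeps the skull in view);
    for the sagittal view the lateral shift is along the beam, so only its
    zoom factor changes.
    """
    if isinstance(case, str):
        try:
            case = CONFIGURATIONS[case]
        except KeyError:
            raise KeyError(
                f"unknown configuration {case!r}; valid names: "
                f"{', '.join(CONFIGURATIONS)}") from None

    pose = RigidPose(tx=case.couch_shift_mm, ry=case.yaw_deg)
    shift = np.array([case.couch_shift_mm, 0.0, 0.0])
    geometries = []
    masks: List[Optional[np.ndarray]] = []
    for view in ("frontal", "sagittal"):
        base = make_view_geometry(view, sad=sad, sid=sid,
                                  detector_size=detector_size,
                                  pixel_spacing=pixel_spacing,
                                  roll_deg=case.roll_deg,
                                  pitch_deg=case.pitch_deg)
        mag = sid / sad
        in_plane = (mag * np.dot(shift, base.detector_axis_u),
                    mag * np.dot(shift, base.detector_axis_v))
        geom = make_view_geometry(view, sad=sad, sid=sid,
                                  detector_size=detector_size,
                                  pixel_spacing=pixel_spacing,
                                  roll_deg=case.roll_deg,
                                  pitch_deg=case.pitch_deg,
                                  detector_offset=in_plane)
        geometries.append(geom)
        if case.fov_fraction < 1.0:
            nu, nv = detector_size
            mask = np.zeros((nu, nv), dtype=bool)
            hu_, hv_ = int(round(nu * case.fov_fraction / 2)), int(round(nv * case.fov_fraction / 2))
            cu, cv = nu // 2, nv // 2
            mask[cu - hu_:cu + hu_, cv - hv_:cv + hv_] = True
            masks.append(mask)
        else:
            masks.append(None)
    return ConfiguredAcquisition(case=case, geometries=geometries,
                                 phantom_pose=pose, fov_masks=masks)


# ---------------------------------------------------------------------------
# Simulated acquisitions
# ---------------------------------------------------------------------------


def simulate_native_xray(volume: VoxelVolume,
                         geometry: ProjectionGeometry,
                         noise_sd: Optional[float] = None,
                         seed: int = 0,
                         pose: RigidPose = IDENTITY_POSE,
                         step_mm: Optional[float] = None,
                         fov_mask: Optional[np.ndarray] = None) -> PlanarImage:
    """A simulated native radiograph: DRR of the full phantom plus seeded
    additive Gaussian noise.  ``noise_sd=None`` uses 1% of the image max;
    pass 0 for a noise-free image."""
    img = render_drr(volume, geometry, pose=pose, step_mm=step_mm)
    vals = img.values.copy()
    if noise_sd is None:
        noise_sd = 0.01 * float(vals.max()) if vals.max() > 0 else 0.0
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    if fov_mask is not None:
        vals = np.where(fov_mask, vals, 0.0)
    return PlanarImage(values=vals, geometry=geometry, kind="native_xray")


def simulate_dsa(volume: VoxelVolume,
                 geometry: ProjectionGeometry,
                 target_only: bool = True,
                 seed: int = 0,
                 pose: RigidPose = IDENTITY_POSE,
                 step_mm: Optional[float] = None,
                 noise_sd: float = 0.0,
                 fov_mask: Optional[np.ndarray] = None,
                 target: Optional[VoxelVolume] = None) -> PlanarImage:
    """A simulated DSA image, sharing the native image's geometry (the two
    are intrinsically registered).

    ``target_only=True`` renders only the target component (markers stand
    in for contrast-filled vessels): either an explicit ``target`` volume
    (see :func:`make_target_volume`) or, by default, the metal voxels
    thresholded out of ``volume``.  ``target_only=False`` reproduces the
    solid-phantom workaround where a copy of the native X-ray is imported
    in place of a DSA: the result is pixel-identical to
    ``simulate_native_xray`` with the same seed.
    """
    if not target_only:
        native = simulate_native_xray(volume, geometry, noise_sd=None if noise_sd == 0
                                      else noise_sd, seed=seed, pose=pose,
                                      step_mm=step_mm, fov_mask=fov_mask)
        return PlanarImage(values=native.values.copy(), geometry=geometry, kind="dsa")
    if target is None:
        target = target_only_volume(volume)
    img = render_drr(target, geometry, pose=pose, step_mm=step_mm)
    vals = img.values.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    if fov_mask is not None:
        vals = np.where(fov_mask, vals, 0.0)
    return PlanarImage(values=vals, geometry=geometry, kind="dsa")
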