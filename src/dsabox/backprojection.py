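"""Backprojection of planar target contours into a volumetric "box"
structure.

Each closed 2D contour, swept back along the divergent rays toward its
source, defines a generalized cone in 3D; the box structure is the
intersection of the frontal and sagittal cones, evaluated on the CT grid.
No smoothing is applied to the box.  Polygon membership uses the even-odd
rule with the boundary counted as inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .drr import VoxelVolume
from .geometry import ProjectionGeometry, RigidPose, project_points


class DisjointConesError(ValueError):
    """The two back-projected cones do not intersect on the CT grid —
    likely a registration or contouring error."""


# ---------------------------------------------------------------------------
# 2D contours
# ---------------------------------------------------------------------------


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour2D:
    """A closed target polygon on one planar view, vertices in detector
    millimetres (relative to the detector origin, so FOV crops do not
    shift coordinates)."""
    view_label: str
    vertices: np.ndarray
    name: str = "target"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (u, v) mm")
        # drop an explicit closing vertex
        if len(self.vertices) > 1 and np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ValueError("a closed contour needs at least 3 vertices")
        if abs(_polygon_area(self.vertices)) < 1e-12:
            raise ValueError("contour has zero area")

    @property
    def area(self) -> float:
        return abs(_polygon_area(self.vertices))


def points_in_polygon(points: np.ndarray, vertices: np.ndarray,
                      eps: float = 1e-9) -> np.ndarray:
    """Even-odd membership of 2D points in a closed polygon; points on the
    boundary (within ``eps``) count as inside.  Vectorized over points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    verts = np.asarray(vertices, dtype=float)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    boundary = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # even-odd ray crossing (horizontal ray toward +u)
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < xint)
        # boundary proximity
        ex, ey = x2 - x1, y2 - y1
        ln2 = ex * ex + ey * ey
        if ln2 == 0:
            d2 = (px - x1) ** 2 + (py - y1) ** 2
        else:
            t = np.clip(((px - x1) * ex + (py - y1) * ey) / ln2, 0.0, 1.0)
            d2 = (px - (x1 + t * ex)) ** 2 + (py - (y1 + t * ey)) ** 2
        boundary |= d2 <= eps * eps
    return inside | boundary


def point_in_cone(contour: Contour2D, geometry: ProjectionGeometry,
                  pose: RigidPose, p: np.ndarray) -> bool:
    """True iff the patient-frame point projects inside the closed contour
    (the point lies inside the back-projected generalized cone)."""
    uv = project_points(geometry, pose, np.asarray(p, dtype=float), strict=False)
    uv = np.atleast_2d(uv)
    if not np.all(np.isfinite(uv)):
        warnings.warn("point is not projectable onto this view; treating as "
                      "outside the cone")
        return False
    return bool(points_in_polygon(uv, contour.vertices)[0])


# ---------------------------------------------------------------------------
# 3D structures
# ---------------------------------------------------------------------------


@dataclass
class Structure3D:
    """A volumetric structure as a binary mask on a regular grid in the CT
    patient frame, with per-slice boundary polygons on demand."""
    mask: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    name: str = "structure"
    frame: str = "LPS"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def member_coordinates(self) -> np.ndarray:
        """World coordinates (mm) of member voxel centers, (n, 3)."""
        idx = np.argwhere(self.mask)
        return self.origin + idx * self.spacing

    def slice_contours(self) -> Dict[int, List[np.ndarray]]:
        return extract_slice_contours(self)


GridLike = Union[VoxelVolume, Tuple[np.ndarray, np.ndarray, Tuple[int, int, int]]]


def _grid_params(grid: GridLike) -> Tuple[np.ndarray, np.ndarray, Tuple[int, int, int]]:
    if isinstance(grid, VoxelVolume):
        return grid.origin, grid.spacing, grid.dims
    origin, spacing, dims = grid
    return (np.asarray(origin, dtype=float), np.asarray(spacing, dtype=float),
            tuple(int(d) for d in dims))


def backproject_contours(front: Contour2D,
                         sag: Contour2D,
                         geometries: Sequence[ProjectionGeometry],
                         pose: RigidPose,
                         ct_grid: GridLike,
                         supersample: int = 1,
                         name: Optional[str] = None,
                         chunk: int = 400_000) -> Structure3D:
    """Intersect the two back-projected cones on the CT grid.

    A voxel center belongs to the box iff its projection (through the
    registered pose) lies inside the drawn contour on *both* views.  With
    ``supersample`` > 1 the membership is evaluated on a grid refined by
    that factor (sub-voxel COM accuracy at modest cost).
    """
    origin, spacing, dims = _grid_params(ct_grid)
    if supersample > 1:
        s = int(supersample)
        new_spacing = spacing / s
        origin = origin - 0.5 * spacing + 0.5 * new_spacing
        spacing = new_spacing
        dims = tuple(d * s for d in dims)

    contours = (front, sag)
    n_total = int(np.prod(dims))
    mask_flat = np.zeros(n_total, dtype=bool)
    ax = [origin[i] + np.arange(dims[i]) * spacing[i] for i in range(3)]

    for start in range(0, n_total, chunk):
        stop = min(start + chunk, n_total)
        idx = np.unravel_index(np.arange(start, stop), dims)
        pts = np.stack([ax[0][idx[0]], ax[1][idx[1]], ax[2][idx[2]]], axis=1)
        member = np.ones(stop - start, dtype=bool)
        for contour, geom in zip(contours, geometries):
            if not member.any():
                break
            uv = project_points(geom, pose, pts[member], strict=False)
            ok = np.all(np.isfinite(uv), axis=1)
            inpoly = np.zeros(len(uv), dtype=bool)
            inpoly[ok] = points_in_polygon(uv[ok], contour.vertices)
            member[member.copy()] = inpoly
        mask_flat[start:stop] = member

    mask = mask_flat.reshape(dims)
    if not mask.any():
        raise DisjointConesError(
            "back-projected cones have an empty intersection on the CT grid; "
            "check the registration and the drawn contours")
    return Structure3D(mask=mask, origin=origin, spacing=spacing,
                       name=name or front.name)


# ---------------------------------------------------------------------------
# Per-slice contour extraction
# ---------------------------------------------------------------------------


def extract_slice_contours(structure: Structure3D) -> Dict[int, List[np.ndarray]]:
    """Closed boundary polygons of the mask per axial (z) slice.

    Returns ``{z_index: [poly, ...]}`` with each polygon an (n, 2) array of
    (x, y) millimetres.  Subpixel iso-contours at level 0.5; single-voxel
    features yield small closed loops around the voxel.
    """
    if not structure.mask.any():
        raise ValueError("empty structure")
    out: Dict[int, List[np.ndarray]] = {}
    for k in range(structure.mask.shape[2]):
        sl = structure.mask[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        polys = []
        for c in skmeasure.find_contours(padded, 0.5):
            ij = c - 1.0  # undo padding
            xy = structure.origin[None, :2] + ij * structure.spacing[None, :2]
            if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
                xy = xy[:-1]
            polys.append(xy)
        if polys:
            out[k] = polys
    return out


def rasterize_slice_contours(contours: Dict[int, List[np.ndarray]],
                             origin: np.ndarray, spacing: np.ndarray,
                             dims: Tuple[int, int, int]) -> np.ndarray:
    """Rasterize per-slice polygons back to a binary mask (round-trip
    companion of :func:`extract_slice_contours`)."""
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    mask = np.zeros(dims, dtype=bool)
    for k, polys in contours.items():
        for poly in polys:
            ij = (np.asarray(poly) - origin[None, :2]) / spacing[None, :2]
            rr, cc = skdraw.polygon(ij[:, 0], ij[:, 1], shape=dims[:2])
            mask[rr, cc, k] = True
    return mask
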