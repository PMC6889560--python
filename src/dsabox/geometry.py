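"""Divergent-beam C-arm projection geometry and rigid 6-DOF poses.

Conventions
-----------
* Patient frame: DICOM LPS (x = left, y = posterior, z = superior), in
  millimetres, with the imaging isocenter at the origin.
* Poses rotate about the isocenter.  Euler angles are degrees about the
  *fixed* patient axes applied in the order x -> y -> z, i.e. the rotation
  matrix is ``R = Rz @ Ry @ Rx``.
* Canonical "frontal" view: beam propagates along +y (source anterior of
  the patient), detector axes u = +x, v = -z.
* Canonical "sagittal" view: beam propagates along +x, u = -y, v = -z
  (axes chosen so u x v points along the beam).
* Detector coordinates (u, v) are millimetres relative to the center of
  pixel (0, 0) (``detector_origin``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Invalid projection geometry or pose parameters."""


class NonProjectableError(ValueError):
    """A point cannot be projected onto the detector (behind the source or
    its ray is parallel to the detector plane)."""


_ORTHO_TOL = 1e-8


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length axis vector")
    return v / n


# ---------------------------------------------------------------------------
# Rigid pose
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidPose:
    """A 6-DOF rigid transform: rotation about the isocenter followed by a
    translation, ``p' = R p + t``.

    Angles are degrees about fixed axes applied x -> y -> z
    (``R = Rz @ Ry @ Rx``); translations are millimetres.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    # -- basic algebra ------------------------------------------------------

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            "xyz", [self.rx, self.ry, self.rz], degrees=True
        ).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the pose to one point (3,) or an array of points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation_matrix().T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return the pose acting as *self after other*:
        ``(self @ other)(p) = self(other(p))``."""
        ra, rb = self.rotation_matrix(), other.rotation_matrix()
        r = ra @ rb
        t = ra @ other.translation + self.translation
        return RigidPose.from_matrix(r, t)

    def inverse(self) -> "RigidPose":
        r = self.rotation_matrix().T
        t = -r @ self.translation
        return RigidPose.from_matrix(r, t)

    @staticmethod
    def from_matrix(r: np.ndarray, t: np.ndarray) -> "RigidPose":
        rx, ry, rz = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
        return RigidPose(float(t[0]), float(t[1]), float(t[2]),
                         float(rx), float(ry), float(rz))

    # -- vector round trip (used by the optimizer) --------------------------

    def as_vector(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @staticmethod
    def from_vector(v: Sequence[float]) -> "RigidPose":
        return RigidPose(*(float(x) for x in v))


IDENTITY_POSE = RigidPose()


def apply_pose(pose: RigidPose, p: np.ndarray) -> np.ndarray:
    return pose.apply(p)


def compose(pose_a: RigidPose, pose_b: RigidPose) -> RigidPose:
    """Composition ``(pose_a o pose_b)(p) = pose_a(pose_b(p))``."""
    return pose_a.compose(pose_b)


def invert(pose: RigidPose) -> RigidPose:
    return pose.inverse()


# ---------------------------------------------------------------------------
# Projection geometry
# ---------------------------------------------------------------------------


@dataclass
class ProjectionGeometry:
    """One divergent-beam view: point source, planar detector, SAD/SID.

    ``detector_origin`` is the world position of the *center* of detector
    pixel (0, 0); pixel (iu, iv) sits at
    ``detector_origin + iu*su*u_axis + iv*sv*v_axis``.
    """

    view_label: str
    source_position: np.ndarray
    detector_origin: np.ndarray
    detector_axis_u: np.ndarray
    detector_axis_v: np.ndarray
    pixel_spacing_u: float
    pixel_spacing_v: float
    detector_size: Tuple[int, int]
    sad: float
    sid: float

    def __post_init__(self):
        self.source_position = np.asarray(self.source_position, dtype=float)
        self.detector_origin = np.asarray(self.detector_origin, dtype=float)
        self.detector_axis_u = np.asarray(self.detector_axis_u, dtype=float)
        self.detector_axis_v = np.asarray(self.detector_axis_v, dtype=float)
        self.detector_size = (int(self.detector_size[0]), int(self.detector_size[1]))
        if not (self.sid > self.sad > 0):
            raise GeometryError(f"require sid > sad > 0, got sad={self.sad}, sid={self.sid}")
        if self.pixel_spacing_u <= 0 or self.pixel_spacing_v <= 0:
            raise GeometryError("pixel spacing must be positive")
        u, v = self.detector_axis_u, self.detector_axis_v
        if (abs(np.linalg.norm(u) - 1) > 1e-6 or abs(np.linalg.norm(v) - 1) > 1e-6
                or abs(np.dot(u, v)) > 1e-6):
            raise GeometryError("detector axes must be orthonormal")

    # -- derived quantities -------------------------------------------------

    @property
    def detector_normal(self) -> np.ndarray:
        """Unit normal of the detector plane, oriented along the beam
        (u x v points from the source toward the detector)."""
        return _unit(np.cross(self.detector_axis_u, self.detector_axis_v))

    @property
    def beam_direction(self) -> np.ndarray:
        return self.detector_normal

    @property
    def detector_center(self) -> np.ndarray:
        nu, nv = self.detector_size
        return (self.detector_origin
                + (nu - 1) / 2 * self.pixel_spacing_u * self.detector_axis_u
                + (nv - 1) / 2 * self.pixel_spacing_v * self.detector_axis_v)

    @property
    def principal_point(self) -> np.ndarray:
        """(u, v) mm of the foot of the perpendicular from the source."""
        d = self.source_position - self.detector_origin
        return np.array([np.dot(d, self.detector_axis_u),
                         np.dot(d, self.detector_axis_v)])

    # -- coordinate helpers -------------------------------------------------

    def pixel_to_mm(self, pixel: Sequence[float]) -> np.ndarray:
        return np.array([pixel[0] * self.pixel_spacing_u,
                         pixel[1] * self.pixel_spacing_v])

    def mm_to_pixel(self, uv: Sequence[float]) -> np.ndarray:
        return np.array([uv[0] / self.pixel_spacing_u,
                         uv[1] / self.pixel_spacing_v])

    def detector_point(self, uv: Sequence[float]) -> np.ndarray:
        """World position of detector-plane point (u, v) mm."""
        return (self.detector_origin
                + uv[0] * self.detector_axis_u
                + uv[1] * self.detector_axis_v)

    def pixel_grid_world(self) -> np.ndarray:
        """World positions of all pixel centers, shape (nu, nv, 3)."""
        nu, nv = self.detector_size
        iu = np.arange(nu) * self.pixel_spacing_u
        iv = np.arange(nv) * self.pixel_spacing_v
        return (self.detector_origin[None, None, :]
                + iu[:, None, None] * self.detector_axis_u[None, None, :]
                + iv[None, :, None] * self.detector_axis_v[None, None, :])


_CANONICAL = {
    # view: (beam direction, u axis, v axis) in LPS
    "frontal": (np.array([0.0, 1.0, 0.0]),
                np.array([1.0, 0.0, 0.0]),
                np.array([0.0, 0.0, -1.0])),
    "sagittal": (np.array([1.0, 0.0, 0.0]),
                 np.array([0.0, -1.0, 0.0]),
                 np.array([0.0, 0.0, -1.0])),
}


def make_view_geometry(view_label: str,
                       sad: float = 1000.0,
                       sid: float = 1500.0,
                       detector_size: Tuple[int, int] = (256, 256),
                       pixel_spacing: float | Tuple[float, float] = 1.0,
                       roll_deg: float = 0.0,
                       pitch_deg: float = 0.0,
                       detector_offset: Tuple[float, float] = (0.0, 0.0),
                       ) -> ProjectionGeometry:
    """Build a frontal or sagittal view geometry, optionally rotated rigidly
    about the isocenter (roll about the longitudinal/z axis first, then
    pitch about the lateral/x axis) and/or with the detector shifted
    in-plane by ``detector_offset`` (mm along u, v).

    With zero offset the detector is centered on the principal ray, which
    passes through the isocenter.
    """
    if sad <= 0 or sid <= 0:
        raise GeometryError("sad and sid must be positive")
    if sid <= sad:
        raise GeometryError("sid must exceed sad")
    try:
        beam, u_axis, v_axis = _CANONICAL[view_label]
    except KeyError:
        raise GeometryError(f"unknown view label {view_label!r}; "
                            "expected 'frontal' or 'sagittal'") from None
    if np.isscalar(pixel_spacing):
        su = sv = float(pixel_spacing)
    else:
        su, sv = (float(s) for s in pixel_spacing)
    if su <= 0 or sv <= 0:
        raise GeometryError("pixel spacing must be positive")

    rot = Rotation.from_euler("zx", [roll_deg, pitch_deg], degrees=True).as_matrix()
    beam, u_axis, v_axis = rot @ beam, rot @ u_axis, rot @ v_axis

    source = -sad * beam
    center = source + sid * beam + detector_offset[0] * u_axis + detector_offset[1] * v_axis
    nu, nv = detector_size
    origin = center - (nu - 1) / 2 * su * u_axis - (nv - 1) / 2 * sv * v_axis
    return ProjectionGeometry(view_label=view_label,
                              source_position=source,
                              detector_origin=origin,
                              detector_axis_u=u_axis,
                              detector_axis_v=v_axis,
                              pixel_spacing_u=su,
                              pixel_spacing_v=sv,
                              detector_size=(nu, nv),
                              sad=sad, sid=sid)


# ---------------------------------------------------------------------------
# Projection and ray operations
# ---------------------------------------------------------------------------


def project_points(geometry: ProjectionGeometry,
                   pose: RigidPose,
                   points: np.ndarray,
                   strict: bool = True) -> np.ndarray:
    """Project an array of patient-frame points (..., 3) through the posed
    volume frame onto the detector; returns (u, v) mm, shape (..., 2).

    With ``strict=False`` non-projectable points yield NaN instead of
    raising.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    q = pose.apply(pts)
    s = geometry.source_position
    n = geometry.detector_normal
    d = q - s
    denom = d @ n
    numer = np.dot(geometry.detector_origin - s, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = numer / denom
    bad = ~np.isfinite(lam) | (denom <= 1e-12) | (lam <= 0)
    if strict and bad.any():
        raise NonProjectableError(
            "point behind the source or ray parallel to the detector plane")
    x = s + lam[..., None] * d
    rel = x - geometry.detector_origin
    uv = np.stack([rel @ geometry.detector_axis_u,
                   rel @ geometry.detector_axis_v], axis=-1)
    uv[bad] = np.nan
    if np.asarray(points).ndim == 1:
        return uv[0]
    return uv


def project_point(geometry: ProjectionGeometry,
                  pose: RigidPose,
                  p: np.ndarray) -> np.ndarray:
    """Project a single patient-frame point; returns (u, v) mm."""
    return project_points(geometry, pose, np.asarray(p, dtype=float))


def pixel_ray(geometry: ProjectionGeometry,
              pixel: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Ray from the source through the center of detector pixel (iu, iv):
    returns (origin, unit direction)."""
    iu, iv = pixel
    nu, nv = geometry.detector_size
    if not (0 <= iu < nu and 0 <= iv < nv):
        raise GeometryError(f"pixel {pixel} outside detector {geometry.detector_size}")
    target = geometry.detector_point(geometry.pixel_to_mm(pixel))
    direction = _unit(target - geometry.source_position)
    return geometry.source_position.copy(), direction


def magnification(geometry: ProjectionGeometry, object_depth: float) -> float:
    """Divergent-beam zoom factor for an object at ``object_depth`` mm from
    the source along the principal ray: SID / depth.  At the isocenter
    (depth = SAD) this is the nominal magnification SID/SAD."""
    if not (0 < object_depth <= geometry.sid):
        raise GeometryError(
            f"object depth must lie in (0, sid={geometry.sid}], got {object_depth}")
    return geometry.sid / object_depth


def geometry_to_dict(geom: ProjectionGeometry) -> dict:
    """JSON-serializable representation (units mm; LPS frame)."""
    return {
        "view_label": geom.view_label,
        "source_position": list(geom.source_position),
        "detector_origin": list(geom.detector_origin),
        "detector_axis_u": list(geom.detector_axis_u),
        "detector_axis_v": list(geom.detector_axis_v),
        "pixel_spacing_u": geom.pixel_spacing_u,
        "pixel_spacing_v": geom.pixel_spacing_v,
        "detector_size": list(geom.detector_size),
        "sad": geom.sad,
        "sid": geom.sid,
        "frame": "LPS",
        "units": "mm",
    }


def geometry_from_dict(d: dict) -> ProjectionGeometry:
    return ProjectionGeometry(
        view_label=d["view_label"],
        source_position=np.array(d["source_position"], dtype=float),
        detector_origin=np.array(d["detector_origin"], dtype=float),
        detector_axis_u=np.array(d["detector_axis_u"], dtype=float),
        detector_axis_v=np.array(d["detector_axis_v"], dtype=float),
        pixel_spacing_u=float(d["pixel_spacing_u"]),
        pixel_spacing_v=float(d["pixel_spacing_v"]),
        detector_size=tuple(d["detector_size"]),
        sad=float(d["sad"]),
        sid=float(d["sid"]),
    )
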