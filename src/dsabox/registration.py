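"""2D-3D rigid registration of planar X-rays against dynamically rendered
DRRs, plus the match-initialization (zoom factor) and visual-verification
steps around it.

The auto-matcher maximizes the summed per-view similarity between each
acquired image and the DRR rendered at a candidate 6-DOF pose, using
derivative-free Powell search on a multi-resolution detector pyramid
(default factors 4, 2, 1).  The default metric is normalized
cross-correlation; gradient-NCC and mutual information are available for
less idealized image pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, optimize

from .drr import PlanarImage, VoxelVolume, render_drr
from .geometry import (IDENTITY_POSE, ProjectionGeometry, RigidPose,
                       magnification)

ArrayLike = Union[np.ndarray, PlanarImage]


def _values(img: ArrayLike) -> np.ndarray:
    return img.values if isinstance(img, PlanarImage) else np.asarray(img, dtype=float)


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def _gradient_magnitude(a: np.ndarray) -> np.ndarray:
    gx, gy = np.gradient(a)
    return np.hypot(gx, gy)


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def similarity(a: ArrayLike, b: ArrayLike, metric: str = "ncc",
               mask: Optional[np.ndarray] = None) -> float:
    """Image similarity; higher is better for every metric.  NCC and
    gradient-NCC lie in [-1, 1] and are symmetric in (a, b)."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError(f"image dimensions differ: {av.shape} vs {bv.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != av.shape:
            raise ValueError("mask shape does not match images")
        if not mask.any():
            raise ValueError("empty similarity mask")
    if metric == "ncc":
        pass
    elif metric == "gradient_ncc":
        av, bv = _gradient_magnitude(av), _gradient_magnitude(bv)
    elif metric == "mi":
        if mask is not None:
            return _mutual_information(av[mask], bv[mask])
        return _mutual_information(av, bv)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if mask is not None:
        av, bv = av[mask], bv[mask]
    return _ncc(av, bv)


# ---------------------------------------------------------------------------
# Zoom-factor estimation (match initialization, part 2)
# ---------------------------------------------------------------------------


def _rescale_about_center(img: np.ndarray, s: float) -> np.ndarray:
    """Sample ``img`` at coordinates scaled by ``s`` about the image center:
    output(x) = img(c + s*(x - c)).  s > 1 shrinks the depicted object."""
    c = (np.array(img.shape) - 1) / 2
    return ndimage.affine_transform(img, np.diag([s, s]), offset=c - s * c,
                                    order=1, mode="constant", cval=0.0)


def estimate_zoom(xray: ArrayLike, drr: ArrayLike,
                  search: Tuple[float, float, int] = (0.7, 1.4, 15),
                  metric: str = "ncc") -> float:
    """Estimate the zoom factor between an X-ray and a DRR: the scale ``s``
    (object size in xray / object size in drr) whose compensation maximizes
    their similarity.  Coarse grid search over ``search=(lo, hi, n)``
    followed by golden-section refinement."""
    lo, hi, n = search
    if lo <= 0:
        raise ValueError("zoom search lower bound must be positive")
    if hi <= lo or n < 2:
        raise ValueError("empty zoom search range")
    xv, dv = _values(xray), _values(drr)
    if xv.shape != dv.shape:
        raise ValueError("images must share dimensions")

    # exclude borders dragged in/out by the rescale from the comparison
    border = max(2, int(0.12 * min(xv.shape)))
    sl = (slice(border, -border), slice(border, -border))

    def score(s: float) -> float:
        return similarity(_rescale_about_center(xv, s)[sl], dv[sl], metric=metric)

    grid = np.linspace(lo, hi, int(n))
    vals = [score(s) for s in grid]
    k = int(np.argmax(vals))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda s: -score(s), bounds=(blo, bhi),
                                   method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x)


# ---------------------------------------------------------------------------
# Match initialization (workflow step 1)
# ---------------------------------------------------------------------------


@dataclass
class InitMatch2D:
    """Per-view manual 2D-2D match: in-plane shift of the X-ray relative to
    the DRR (mm), in-plane rotation about the beam axis (deg), and the zoom
    factor (X-ray magnification / DRR magnification)."""
    du: float = 0.0
    dv: float = 0.0
    rotation_deg: float = 0.0
    zoom: float = 1.0

    def __post_init__(self):
        if self.zoom <= 0:
            raise ValueError("zoom must be positive")


def _intensity_centroid(img: np.ndarray, geometry: ProjectionGeometry) -> np.ndarray:
    w = np.clip(img, 0, None)
    tot = w.sum()
    if tot == 0:
        return np.array(geometry.principal_point)
    iu = np.arange(img.shape[0]) * geometry.pixel_spacing_u
    iv = np.arange(img.shape[1]) * geometry.pixel_spacing_v
    return np.array([(w.sum(axis=1) * iu).sum() / tot,
                     (w.sum(axis=0) * iv).sum() / tot])


def initialize_match(xray_pair: Sequence[ArrayLike],
                     ct: Optional[VoxelVolume],
                     geometry_pair: Sequence[ProjectionGeometry],
                     manual: Union[str, Sequence[InitMatch2D]] = "auto",
                     pose0: RigidPose = IDENTITY_POSE,
                     step_mm: Optional[float] = None) -> RigidPose:
    """Convert per-view 2D-2D match parameters into an initial 6-DOF pose.

    In-plane shifts map to patient-frame translations scaled by
    1/magnification; a zoom mismatch maps to a translation along the view's
    principal ray (depth sad/zoom); per-view in-plane rotations combine as
    rotation vectors about the beam axes.  The over-determined translation
    system from the two views is solved by least squares.

    ``manual="auto"`` estimates per-view shifts by aligning the intensity
    centroid of each X-ray with that of the DRR rendered at ``pose0``
    (zoom and rotations left at identity).
    """
    if len(xray_pair) != 2 or len(geometry_pair) != 2:
        raise ValueError("exactly two views required")
    beams = [g.beam_direction for g in geometry_pair]
    if abs(np.dot(beams[0], beams[1])) > 0.95:
        raise ValueError("view principal rays are near-parallel; "
                         "cannot triangulate an initialization")

    if manual == "auto":
        if ct is None:
            raise ValueError("auto initialization needs the CT volume")
        inits = []
        for img, geom in zip(xray_pair, geometry_pair):
            drr = render_drr(ct, geom, pose=pose0, step_mm=step_mm)
            c_x = _intensity_centroid(_values(img), geom)
            c_d = _intensity_centroid(drr.values, geom)
            inits.append(InitMatch2D(du=c_x[0] - c_d[0], dv=c_x[1] - c_d[1]))
    else:
        inits = list(manual)
        if len(inits) != 2:
            raise ValueError("need one InitMatch2D per view")

    # Each nonzero per-view adjustment contributes one linear constraint on
    # the 3D translation; adjustments left at their neutral value (zero
    # shift, unit zoom) mean "nothing observed in that direction" and are
    # dropped, so they cannot dilute the other view's measurement.
    rows, rhs = [], []
    rotvec = np.zeros(3)
    for init, geom in zip(inits, geometry_pair):
        m = magnification(geom, geom.sad)
        d = geom.beam_direction
        for axis, val in ((geom.detector_axis_u, init.du / m),
                          (geom.detector_axis_v, init.dv / m),
                          (d, geom.sad * (1.0 / init.zoom - 1.0))):
            if abs(val) > 1e-12:
                rows.append(axis)
                rhs.append(val)
        rotvec += np.deg2rad(init.rotation_deg) * d
    if rows:
        t_delta, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    else:
        t_delta = np.zeros(3)

    from scipy.spatial.transform import Rotation
    delta = RigidPose.from_matrix(Rotation.from_rotvec(rotvec).as_matrix(), t_delta)
    return delta.compose(pose0)


# ---------------------------------------------------------------------------
# Auto matching (workflow step 2)
# ---------------------------------------------------------------------------


@dataclass
class MatchOptions:
    """Knobs of the 2D-3D auto-matcher.

    The documented capture range is about +/-10 mm / +/-10 deg around the
    initial pose; beyond that the similarity landscape is not trusted and
    convergence is not guaranteed.
    """
    metric: str = "ncc"
    pyramid: Tuple[int, ...] = (4, 2, 1)
    step_mm: Optional[float] = None     # ray-march step at pyramid level 1
    xtol: float = 0.01                  # mm / deg
    maxfev_per_level: int = 400
    masks: Optional[Sequence[Optional[np.ndarray]]] = None
    optimize_rotation: bool = True
    n_restarts: int = 0                 # seeded extra Powell starts per level
    restart_seed: int = 0
    restart_scale: Tuple[float, float] = (1.0, 1.0)  # mm, deg


@dataclass
class MatchResult:
    pose: RigidPose
    similarity_per_view: List[float]
    similarity: float
    converged: bool
    iterations: int


def _block_reduce(img: np.ndarray, f: int) -> np.ndarray:
    nu, nv = (img.shape[0] // f) * f, (img.shape[1] // f) * f
    return img[:nu, :nv].reshape(nu // f, f, nv // f, f).mean(axis=(1, 3))


def _coarsen_geometry(geom: ProjectionGeometry, f: int,
                      new_size: Tuple[int, int]) -> ProjectionGeometry:
    """Geometry of the block-averaged detector: pixel (0,0) of the coarse
    grid is the centroid of the first f x f fine block."""
    shift = ((f - 1) / 2 * geom.pixel_spacing_u * geom.detector_axis_u
             + (f - 1) / 2 * geom.pixel_spacing_v * geom.detector_axis_v)
    return ProjectionGeometry(
        view_label=geom.view_label,
        source_position=geom.source_position.copy(),
        detector_origin=geom.detector_origin + shift,
        detector_axis_u=geom.detector_axis_u.copy(),
        detector_axis_v=geom.detector_axis_v.copy(),
        pixel_spacing_u=geom.pixel_spacing_u * f,
        pixel_spacing_v=geom.pixel_spacing_v * f,
        detector_size=new_size,
        sad=geom.sad, sid=geom.sid)


def auto_match(ct: VoxelVolume,
               xray_pair: Sequence[ArrayLike],
               geometry_pair: Sequence[ProjectionGeometry],
               init: RigidPose,
               opts: Optional[MatchOptions] = None) -> MatchResult:
    """Estimate the rigid pose of the CT that renders DRRs best matching
    the two planar images, starting from ``init``.

    Powell search over (tx, ty, tz, rx, ry, rz) on each pyramid level from
    coarse to fine; the returned pose never scores below the initial pose
    at the finest level (ties and regressions fall back to ``init``).
    """
    opts = opts or MatchOptions()
    masks = list(opts.masks) if opts.masks is not None else [None, None]
    base_step = opts.step_mm if opts.step_mm is not None else float(np.min(ct.spacing))

    xrays = [_values(im) for im in xray_pair]
    levels = []
    for f in opts.pyramid:
        imgs_f, geoms_f, masks_f = [], [], []
        for img, geom, mask in zip(xrays, geometry_pair, masks):
            if f > 1:
                imf = _block_reduce(img, f)
                geoms_f.append(_coarsen_geometry(geom, f, imf.shape))
                imgs_f.append(imf)
                masks_f.append(None if mask is None
                               else _block_reduce(mask.astype(float), f) > 0.5)
            else:
                imgs_f.append(img)
                geoms_f.append(geom)
                masks_f.append(mask)
        levels.append((f, imgs_f, geoms_f, masks_f))

    nfev_total = 0
    success = True
    x = init.as_vector()
    free = slice(0, 6) if opts.optimize_rotation else slice(0, 3)
    rng = np.random.default_rng(opts.restart_seed)

    for f, imgs_f, geoms_f, masks_f in levels:
        step = base_step * max(1, f // 2)

        def neg_sim(xv: np.ndarray, _fixed=x.copy()) -> float:
            p = _fixed.copy()
            p[free] = xv
            pose = RigidPose.from_vector(p)
            s = 0.0
            for img, geom, mask in zip(imgs_f, geoms_f, masks_f):
                drr = render_drr(ct, geom, pose=pose, step_mm=step)
                s += similarity(img, drr.values, metric=opts.metric, mask=mask)
            return -s / len(imgs_f)

        starts = [x[free].copy()]
        for _ in range(opts.n_restarts):
            pert = np.zeros(6)
            pert[:3] = rng.uniform(-opts.restart_scale[0], opts.restart_scale[0], 3)
            pert[3:] = rng.uniform(-opts.restart_scale[1], opts.restart_scale[1], 3)
            starts.append((x + pert)[free])
        best = None
        for x0 in starts:
            res = optimize.minimize(neg_sim, x0, method="Powell",
                                    options={"xtol": opts.xtol, "ftol": 1e-6,
                                             "maxfev": opts.maxfev_per_level,
                                             "disp": False})
            nfev_total += res.nfev
            if best is None or res.fun < best.fun:
                best = res
        success = success and bool(best.success)
        x[free] = best.x

    pose = RigidPose.from_vector(x)

    # per-view similarity at full resolution; monotone-refinement guard
    def combined(p: RigidPose) -> Tuple[List[float], float]:
        per = []
        for img, geom, mask in zip(xrays, geometry_pair, masks):
            drr = render_drr(ct, geom, pose=p, step_mm=base_step)
            per.append(similarity(img, drr.values, metric=opts.metric, mask=mask))
        return per, float(np.mean(per))

    per_final, sim_final = combined(pose)
    per_init, sim_init = combined(init)
    if sim_final < sim_init:
        # the initial pose was already (at least) as good; keep it.  Only a
        # substantial regression marks a failed optimization.
        regressed = sim_init - sim_final > 1e-6
        if regressed:
            warnings.warn("auto_match did not improve on the initial pose; "
                          "returning the initial pose")
        return MatchResult(pose=init, similarity_per_view=per_init,
                           similarity=sim_init,
                           converged=success and not regressed,
                           iterations=nfev_total)
    return MatchResult(pose=pose, similarity_per_view=per_final,
                       similarity=sim_final, converged=success,
                       iterations=nfev_total)


# ---------------------------------------------------------------------------
# Visual match verification (workflow step 3)
# ---------------------------------------------------------------------------


@dataclass
class VerificationViews:
    """Composites for visually checking an X-ray against the DRR at the
    registered pose, plus the residual similarity score for scripted QA."""
    xray: np.ndarray
    drr: np.ndarray
    residual_score: float

    def blend(self, alpha: float) -> np.ndarray:
        """alpha=0 -> pure X-ray; alpha=1 -> pure DRR."""
        return (1 - alpha) * self.xray + alpha * self.drr

    def split(self, u0: int) -> np.ndarray:
        """X-ray for columns iu < u0, DRR from u0 on (u0=0 -> all DRR)."""
        out = self.drr.copy()
        out[:u0, :] = self.xray[:u0, :]
        return out

    def checker(self, k: int) -> np.ndarray:
        """k x k checkerboard; k=1 is a single DRR tile."""
        nu, nv = self.xray.shape
        iu = (np.arange(nu) * k // nu)[:, None]
        iv = (np.arange(nv) * k // nv)[None, :]
        take_xray = (iu + iv) % 2 == 1
        return np.where(take_xray, self.xray, self.drr)


def verification_views(xray: ArrayLike, drr_at_pose: ArrayLike,
                       metric: str = "ncc",
                       mask: Optional[np.ndarray] = None) -> VerificationViews:
    xv, dv = _values(xray), _values(drr_at_pose)
    if xv.shape != dv.shape:
        raise ValueError("image dimensions differ")
    return VerificationViews(xray=xv, drr=dv,
                             residual_score=similarity(xv, dv, metric=metric,
                                                       mask=mask))
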