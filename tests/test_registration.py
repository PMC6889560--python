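"""Similarity metrics, zoom estimation, initialization and the 2D-3D
auto-matcher (fast, coarse setups; accuracy bounds at full scale live in
the acceptance suite)."""

import numpy as np
import pytest

from dsabox.drr import render_drr
from dsabox.geometry import RigidPose, make_view_geometry
from dsabox.phantoms import simulate_native_xray
from dsabox.registration import (InitMatch2D, MatchOptions, auto_match,
                                 estimate_zoom, initialize_match, similarity,
                                 verification_views)

from conftest import make_sphere_volume


@pytest.fixture(scope="module")
def head_setup(coarse_head):
    """Coarse head phantom with 96^2 detectors and noiseless X-rays at the
    identity pose."""
    vol, _ = coarse_head
    geoms = [make_view_geometry(v, 1000, 1500, (96, 96), 3.0)
             for v in ("frontal", "sagittal")]
    xrays = [simulate_native_xray(vol, g, noise_sd=0.0, step_mm=1.25)
             for g in geoms]
    return vol, geoms, xrays


FAST_OPTS = dict(pyramid=(2, 1), step_mm=2.5, maxfev_per_level=500)


class TestSimilarity:
    def test_ncc_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(64, 64))
        assert similarity(a, a) == pytest.approx(1.0)
        assert similarity(a, -a) == pytest.approx(-1.0)
        b = rng.normal(size=(64, 64))
        assert similarity(a, b) == pytest.approx(similarity(b, a))

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(256, 256))
        b = rng.normal(size=(256, 256))
        assert abs(similarity(a, b)) < 0.05

    def test_gradient_ncc_and_mi_prefer_identical(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(64, 64)).cumsum(axis=0)
        b = rng.normal(size=(64, 64)).cumsum(axis=0)
        for metric in ("gradient_ncc", "mi"):
            assert (similarity(a, a, metric=metric)
                    > similarity(a, b, metric=metric))

    def test_dimension_mismatch_and_empty_mask(self):
        a = np.zeros((8, 8))
        with pytest.raises(ValueError):
            similarity(a, np.zeros((9, 9)))
        with pytest.raises(ValueError):
            similarity(a, a, mask=np.zeros((8, 8), dtype=bool))

    def test_mask_restricts_support(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(32, 32))
        b = a.copy()
        b[16:, :] = rng.normal(size=(16, 32))  # corrupt the lower half
        mask = np.zeros((32, 32), dtype=bool)
        mask[:16, :] = True
        assert similarity(a, b, mask=mask) == pytest.approx(1.0)
        assert similarity(a, b) < 0.9


@pytest.fixture(scope="module")
def sphere_drr():
    vol = make_sphere_volume(radius=25.0, n=64)
    g = make_view_geometry("frontal", 1000, 1500, (128, 128), 1.0)
    return render_drr(vol, g, step_mm=1.0)


class TestEstimateZoom:
    def test_identical_images_give_unity(self, sphere_drr):
        z = estimate_zoom(sphere_drr, sphere_drr)
        assert z == pytest.approx(1.0, abs=0.005)

    @pytest.mark.parametrize("true_zoom", [0.8, 0.9, 1.1, 1.25])
    def test_recovers_known_magnification_ratio(self, true_zoom):
        # the "x-ray" is rendered with SID scaled so its magnification is
        # true_zoom times the reference DRR's
        vol = make_sphere_volume(radius=25.0, n=64)
        g_ref = make_view_geometry("frontal", 1000, 1500, (128, 128), 1.0)
        g_zoom = make_view_geometry("frontal", 1000, 1500 * true_zoom,
                                    (128, 128), 1.0)
        drr = render_drr(vol, g_ref, step_mm=1.0)
        xray = render_drr(vol, g_zoom, step_mm=1.0)
        z = estimate_zoom(xray, drr)
        assert z == pytest.approx(true_zoom, rel=0.005)

    def test_invariant_to_intensity_scaling(self, sphere_drr):
        scaled = sphere_drr.values * 7.3
        z = estimate_zoom(scaled, sphere_drr)
        assert z == pytest.approx(1.0, abs=0.005)

    def test_bad_search_range(self, sphere_drr):
        with pytest.raises(ValueError):
            estimate_zoom(sphere_drr, sphere_drr, search=(-1.0, 2.0, 5))
        with pytest.raises(ValueError):
            estimate_zoom(sphere_drr, sphere_drr, search=(1.0, 1.0, 1))


class TestInitializeMatch:
    def test_zero_shifts_give_identity(self, head_setup):
        vol, geoms, xrays = head_setup
        pose = initialize_match(xrays, vol, geoms,
                                manual=[InitMatch2D(), InitMatch2D()])
        assert np.allclose(pose.as_vector(), 0.0, atol=1e-9)

    def test_in_plane_shift_scales_by_magnification(self, head_setup):
        vol, geoms, xrays = head_setup
        pose = initialize_match(xrays, vol, geoms,
                                manual=[InitMatch2D(du=15.0), InitMatch2D()])
        # frontal u axis is +x, magnification 1.5 -> 10 mm patient shift
        assert pose.tx == pytest.approx(10.0, abs=1e-6)
        assert abs(pose.ty) < 1e-6 and abs(pose.tz) < 1e-6

    def test_zoom_maps_to_depth_translation(self, head_setup):
        vol, geoms, xrays = head_setup
        pose = initialize_match(xrays, vol, geoms,
                                manual=[InitMatch2D(zoom=1.2), InitMatch2D()])
        # frontal beam is +y: depth = sad/zoom -> move along -y
        assert pose.ty == pytest.approx(1000 * (1 / 1.2 - 1), rel=1e-6)

    def test_auto_centroid_initialization(self, head_setup):
        vol, _, _ = head_setup
        # wide detectors so the shifted phantom is never clipped (centroid
        # alignment assumes the whole object is in view)
        geoms = [make_view_geometry(v, 1000, 1500, (128, 128), 3.0)
                 for v in ("frontal", "sagittal")]
        truth = RigidPose(tx=12.0, ty=-9.0, tz=14.0)
        xrays = [simulate_native_xray(vol, g, noise_sd=0.0, pose=truth,
                                      step_mm=1.25) for g in geoms]
        pose = initialize_match(xrays, vol, geoms, manual="auto")
        assert np.linalg.norm(pose.translation - truth.translation) < 3.0

    def test_parallel_views_rejected(self, head_setup):
        vol, geoms, xrays = head_setup
        with pytest.raises(ValueError):
            initialize_match([xrays[0], xrays[0]], vol, [geoms[0], geoms[0]])


class TestAutoMatch:
    def test_truth_is_a_fixed_point(self, head_setup):
        vol, geoms, xrays = head_setup
        res = auto_match(vol, xrays, geoms, RigidPose(),
                         MatchOptions(**FAST_OPTS))
        assert res.converged
        assert np.all(np.abs(res.pose.as_vector()) < 0.05)
        assert res.similarity > 0.999

    def test_recovers_perturbed_pose(self, head_setup):
        vol, geoms, xrays = head_setup
        init = RigidPose(2.0, -2.0, 2.0, 2.0, -2.0, 2.0)
        res = auto_match(vol, xrays, geoms, init, MatchOptions(**FAST_OPTS))
        v = res.pose.as_vector()
        assert np.all(np.abs(v[:3]) < 0.2) and np.all(np.abs(v[3:]) < 0.2)

    def test_capture_range_exceeded_is_flagged(self, head_setup):
        vol, geoms, xrays = head_setup
        res_id = auto_match(vol, xrays, geoms, RigidPose(),
                            MatchOptions(**FAST_OPTS))
        far = RigidPose(tx=30.0, ty=-30.0, tz=25.0)
        res = auto_match(vol, xrays, geoms, far,
                         MatchOptions(pyramid=(2, 1), step_mm=2.5,
                                      maxfev_per_level=150))
        assert (not res.converged) or res.similarity < res_id.similarity

    def test_monotone_refinement(self, head_setup):
        vol, geoms, xrays = head_setup
        init = RigidPose(3.0, 1.0, -2.0, 1.0, 2.0, -1.0)
        res = auto_match(vol, xrays, geoms, init, MatchOptions(**FAST_OPTS))
        init_sim = np.mean([similarity(x.values,
                                       render_drr(vol, g, pose=init,
                                                  step_mm=2.5).values)
                            for x, g in zip(xrays, geoms)])
        assert res.similarity >= init_sim - 1e-12

    def test_view_order_symmetry(self, head_setup):
        vol, geoms, xrays = head_setup
        init = RigidPose(1.5, -1.0, 0.5, 1.0, -0.5, 0.5)
        res_ab = auto_match(vol, xrays, geoms, init, MatchOptions(**FAST_OPTS))
        res_ba = auto_match(vol, xrays[::-1], geoms[::-1], init,
                            MatchOptions(**FAST_OPTS))
        assert np.allclose(res_ab.pose.as_vector(), res_ba.pose.as_vector(),
                           atol=0.05)


class TestVerificationViews:
    @pytest.fixture()
    def views(self):
        rng = np.random.default_rng(4)
        xray, drr = rng.normal(size=(32, 32)), rng.normal(size=(32, 32))
        return xray, drr, verification_views(xray, drr)

    def test_blend_endpoints(self, views):
        xray, drr, v = views
        assert np.array_equal(v.blend(0.0), xray)
        assert np.array_equal(v.blend(1.0), drr)

    def test_split_and_checker_identities(self, views):
        xray, drr, v = views
        assert np.array_equal(v.split(0), drr)
        assert np.array_equal(v.checker(1), drr)
        assert np.array_equal(v.split(32), xray)

    def test_residual_score_is_similarity(self, views):
        xray, drr, v = views
        assert v.residual_score == pytest.approx(similarity(xray, drr))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            verification_views(np.zeros((8, 8)), np.zeros((9, 9)))
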