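"""Geometry: resampling, smoothing, curvature/torsion estimators, surfaces."""

import numpy as np
import pytest

from armkin import (
    BackboneCurve,
    MovementSequence,
    SplineConfig,
    bend_point,
    build_surfaces,
    circumcircle_curvature,
    curvature_profile,
    elongation_ratio,
    frenet_reconstruct,
    resample_uniform,
    smooth_spline,
    torsion_profile,
    triangle_normal_torsion,
)
from armkin.exceptions import (
    DegenerateCurveError,
    DegenerateTriangleError,
    NoBendError,
)

from conftest import random_rigid_transform


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


class TestResample:
    def test_unit_segment_equal_spacing(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        out = resample_uniform(pts, 5)
        assert np.allclose(out.points[:, 0], [0, 0.25, 0.5, 0.75, 1.0])
        assert np.allclose(out.points[:, 1:], 0.0)

    def test_idempotent_on_uniform_input(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t, 2 * t, -t])  # straight, uniform
        out = resample_uniform(pts, 50)
        assert np.abs(out.points - pts).max() < 1e-9

    def test_semicircle_chord_uniformity(self):
        # oracle: a radius-1 semicircle has analytic arclength pi
        th = np.linspace(0, np.pi, 1000)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        out = resample_uniform(pts, 100)
        chords = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        assert np.abs(chords / chords.mean() - 1).max() < 1e-3
        assert abs(chords.sum() - np.pi) < 1e-3

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        out = resample_uniform(pts, 33)
        assert np.array_equal(out.points[0], pts[0])
        assert np.array_equal(out.points[-1], pts[-1])

    def test_degenerate_input(self):
        with pytest.raises(DegenerateCurveError):
            resample_uniform(np.zeros((5, 3)), 10)


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------


class TestSmoothSpline:
    def test_p1_interpolates(self, rng):
        pts = np.cumsum(rng.normal(size=(30, 3)) + [1, 0, 0], axis=0)
        curve = resample_uniform(pts, 30)
        out = smooth_spline(curve, SplineConfig(p=1.0))
        assert np.abs(out.points - curve.points).max() < 1e-9

    def test_p0_least_squares_line(self, rng):
        pts = np.cumsum(np.abs(rng.normal(size=(40, 3))) + 0.1, axis=0)
        curve = resample_uniform(pts, 40)
        out = smooth_spline(curve, SplineConfig(p=0.0))
        # oracle: coordinate-wise degree-1 polynomial fit at the same sites
        x = curve.arclengths / curve.length
        for c in range(3):
            coef = np.polynomial.polynomial.polyfit(x, curve.points[:, c], 1)
            expect = np.polynomial.polynomial.polyval(x, coef)
            assert np.abs(out.points[:, c] - expect).max() < 1e-8

    def test_noisy_circle_denoised(self):
        rng = np.random.default_rng(7)
        th = np.linspace(0, 1.5 * np.pi, 100)
        clean = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        noisy = clean + rng.normal(0, 0.01, clean.shape)
        out = smooth_spline(BackboneCurve(noisy), SplineConfig(p=0.99))
        sse_noisy = np.sum((noisy - clean) ** 2)
        sse_smooth = np.sum((out.points - clean) ** 2)
        assert sse_smooth < sse_noisy


# ---------------------------------------------------------------------------
# pointwise estimators
# ---------------------------------------------------------------------------


class TestPointEstimators:
    @pytest.mark.parametrize(
        "A,B,C,expect",
        [
            ((0, 0, 0), (1, 0, 0), (2, 0, 0), 0.0),  # collinear
            ((1, 0, 0), (0, 1, 0), (-1, 0, 0), 1.0),  # unit circle
            # oracle: circumcenter (1, 0, 0), radius 1
            ((0, 0, 0), (1, 1, 0), (2, 0, 0), 1.0),
        ],
    )
    def test_circumcircle(self, A, B, C, expect):
        assert circumcircle_curvature(A, B, C) == pytest.approx(expect, abs=1e-12)

    def test_circumcircle_coincident_points(self):
        with pytest.raises(DegenerateTriangleError):
            circumcircle_curvature((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_torsion_coplanar_zero(self):
        pts = [(0, 0, 0), (1, 1, 0), (2, 0, 0), (3, 1, 0), (4, 0, 0)]
        assert triangle_normal_torsion(*pts) == 0.0

    def test_torsion_perpendicular_planes(self):
        # ABC lies in z=0 (normal along z); CDE lies in y=0 (normal along y);
        # d(B, D) = 2 by construction, so tau = arccos(0)/2 = pi/4
        A, B, C = (0, 0, 0), (1, 1, 0), (2, 0, 0)
        D, E = (1 + np.sqrt(2), 0, 1), (3, 0, 0)
        assert triangle_normal_torsion(A, B, C, D, E) == pytest.approx(np.pi / 4, rel=1e-12)

    def test_torsion_degenerate_triangle_warns_zero(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 1), (4, 0, 2)]
        assert triangle_normal_torsion(*pts) == 0.0


# ---------------------------------------------------------------------------
# profiles: closed forms
# ---------------------------------------------------------------------------


class TestProfiles:
    def test_straight_line_zero(self, fx):
        assert curvature_profile(fx["line"]).max() == 0.0
        assert torsion_profile(fx["line"]).max() == 0.0

    def test_circle_curvature(self, fx):
        k = curvature_profile(fx["circle_r2"])
        assert k.size == 100
        assert np.abs(k[1:-1] - 0.5).max() < 0.005  # within 1% of 1/r

    def test_helix_closed_forms(self, fx):
        # helix a=1, b=0.5: kappa = a/(a^2+b^2) = 0.8, tau = b/(a^2+b^2) = 0.4
        k = curvature_profile(fx["helix"])
        t = torsion_profile(fx["helix"])
        assert np.abs(k[1:-1] / 0.8 - 1).max() < 0.01
        assert np.abs(t[2:-2] / 0.4 - 1).max() < 0.01

    def test_planar_s_curve_torsion_zero(self, fx):
        assert torsion_profile(fx["s_curve"]).max() < 1e-6

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_covariance(self, fx, c):
        base_k = curvature_profile(fx["helix"])
        base_t = torsion_profile(fx["helix"])
        scaled = BackboneCurve(fx["helix"].points * c)
        assert np.allclose(curvature_profile(scaled), base_k / c, rtol=1e-9, atol=1e-12)
        assert np.allclose(torsion_profile(scaled), base_t / c, rtol=1e-7, atol=1e-12)

    def test_profile_length_matches_n(self, rng):
        pts = np.cumsum(np.abs(rng.normal(size=(37, 3))) + 0.05, axis=0)
        curve = resample_uniform(pts, 23)
        assert curvature_profile(curve).size == 23
        assert torsion_profile(curve).size == 23


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


class TestBuildSurfaces:
    def test_identical_planar_frames_torsion_zero(self, fx):
        seq = MovementSequence(
            curves=[fx["s_curve"]] * 5, times=np.linspace(0, 1, 5)
        )
        _, tors = build_surfaces(seq)
        assert tors.values.max() < 1e-6

    def test_output_shape_n_by_n(self, fx):
        curv, tors = build_surfaces(fx["helix_sequence"])
        assert curv.values.shape == (100, 100)
        assert tors.values.shape == (100, 100)

    def test_rigid_motion_invariance(self, fx, rng):
        seq = fx["helix_sequence"]
        curv0, tors0 = build_surfaces(seq)
        worst = 0.0
        for _ in range(10):
            R, v = random_rigid_transform(rng)
            moved = MovementSequence(
                [BackboneCurve(c.points @ R.T + v) for c in seq.curves], seq.times
            )
            curv, tors = build_surfaces(moved)
            worst = max(
                worst,
                np.abs(curv.values - curv0.values).max(),
                np.abs(tors.values - tors0.values).max(),
            )
        assert worst < 1e-9

    def test_tip_exclusion_flat_fill(self, fx):
        curv, _ = build_surfaces(fx["helix_sequence"], tip_exclude_fraction=0.2)
        n_excl = round(0.2 * 100)
        distal = curv.values[:, -n_excl:]
        assert np.all(distal == curv.values[:, [-n_excl - 1]])

    def test_helix_surface_value(self, fx):
        # constant-geometry frames: kappa surface flat at the closed form
        seq = MovementSequence(curves=[fx["helix"]] * 5, times=np.linspace(0, 1, 5))
        curv, _ = build_surfaces(seq, tip_exclude_fraction=0.0)
        L = fx["helix"].length  # arm length normalized to 1 scales kappa by L
        assert np.abs(curv.values[:, 2:-2] / (0.8 * L) - 1).max() < 0.01


# ---------------------------------------------------------------------------
# bend descriptors
# ---------------------------------------------------------------------------


def _bump_curve(center, n=100, width=0.006, amp=8.0):
    s = np.linspace(0, 1, n)
    kappa = amp * np.exp(-((s - center) ** 2) / (2 * width))
    return frenet_reconstruct(kappa, np.zeros(n), length=1.0)


class TestBendPoint:
    def test_planted_bump_location(self):
        curve = _bump_curve(0.4)
        assert abs(bend_point(curve) - 0.4) <= 1.0 / 99 + 1e-12

    def test_straight_line_no_bend(self, fx):
        with pytest.raises(NoBendError):
            bend_point(fx["line"])

    def test_circle_tie_break_deterministic(self, fx):
        # constant-curvature profile: any index is acceptable, but repeated
        # calls must agree (the op resolves ties to the first maximum)
        assert bend_point(fx["circle_r1"]) == bend_point(fx["circle_r1"])

    def test_elongation_ratio_planted(self):
        seq = MovementSequence(
            curves=[_bump_curve(0.5)] * 3, times=np.linspace(0, 1, 3)
        )
        r = elongation_ratio(seq)
        assert np.abs(r - 0.5).max() < 0.02
        assert np.all((r > 0) & (r < 1))

    def test_elongation_ratio_travelling_bend_monotone(self):
        centers = np.linspace(0.3, 0.7, 8)
        seq = MovementSequence(
            curves=[_bump_curve(c) for c in centers], times=np.linspace(0, 1, 8)
        )
        r = elongation_ratio(seq)
        assert np.all(np.diff(r) >= 0)
        assert np.all((r > 0) & (r < 1))
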