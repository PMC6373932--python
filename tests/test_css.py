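import math

import numpy as np
import pytest

from leaftooth import (
    CSSParams,
    classify_curve,
    detect_corners,
    extract_contour,
    find_candidates,
    remove_round_corners,
    smooth_curve,
)
from leaftooth.css import CornerSet, corner_angles, remove_false_corners
from leaftooth.features import segment
from leaftooth.preprocess import Contour
from leaftooth.synthetic import SyntheticLeafSpec, generate_leaf

from conftest import disk_mask, ellipse_mask


def contour_from_xy(x, y, closed=True):
    pts = np.stack([np.asarray(y), np.asarray(x)], axis=1)
    return Contour(points=pts, closed=closed)


def circle_contour(r, n=None):
    n = n or int(2 * math.pi * r)
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return contour_from_xy(r * np.cos(t) + r + 5, r * np.sin(t) + r + 5)


class TestClassifyCurve:
    def test_traced_boundary_closed(self):
        contour = extract_contour(disk_mask(8))
        assert classify_curve(contour.points, 3.0) == "closed"

    def test_straight_segment_open(self):
        pts = np.stack([np.zeros(50, int), np.arange(50)], axis=1)
        assert classify_curve(pts, 3.0) == "open"

    def test_gap_boundary_inclusive(self):
        pts = np.array([[0, 0], [0, 1], [0, 2], [0, 3]])
        assert classify_curve(pts, 3.0) == "closed"


class TestSmoothCurve:
    def test_circle_radius_preserved(self):
        contour = circle_contour(50)
        curve = smooth_curve(contour, 4.0)
        cx, cy = curve.x.mean(), curve.y.mean()
        radii = np.hypot(curve.x - cx, curve.y - cy)
        assert abs(radii.mean() - 50) / 50 < 0.02

    def test_closed_square_stays_closed(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True
        curve = smooth_curve(extract_contour(m), 3.0)
        gap = math.hypot(curve.x[0] - curve.x[-1], curve.y[0] - curve.y[-1])
        assert gap < 2.0


class TestCurvature:
    @pytest.mark.parametrize("r", [20, 50, 100])
    def test_circle_analytic(self, r):
        curve = smooth_curve(circle_contour(r), 4.0)
        kappa = np.abs(curve.kappa)
        assert np.abs(kappa - 1.0 / r).max() / (1.0 / r) < 0.05

    def test_ellipse_analytic(self):
        a, b = 60.0, 30.0
        n = 600
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        contour = contour_from_xy(a * np.cos(t) + 70, b * np.sin(t) + 40)
        # parameter spacing is non-uniform; delta in samples ~ 0.5 px here
        curve = smooth_curve(contour, 4.0)
        expected = (a * b) / (
            (a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2) ** 1.5
        )
        rel = np.abs(np.abs(curve.kappa) - expected) / expected
        assert np.median(rel) < 0.05

    def test_convex_margin_positive_sign(self):
        curve = smooth_curve(extract_contour(disk_mask(20)), 4.0)
        assert np.median(curve.kappa) > 0

    def test_straight_line_zero(self):
        pts = np.stack([np.full(80, 5), np.arange(80)], axis=1)
        curve = smooth_curve(Contour(points=pts, closed=False), 4.0)
        assert np.abs(curve.kappa[10:-10]).max() < 1e-6


class TestCandidatesAndFilters:
    def test_sine_modulated_circle_candidate_count(self):
        k = 6
        n = 720
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        r = 100 + 12 * np.sin(k * t)
        contour = contour_from_xy(r * np.cos(t) + 120, r * np.sin(t) + 120)
        curve = smooth_curve(contour, 4.0)
        cands = find_candidates(curve)
        # k maxima of each curvature sign
        assert len(cands) == 2 * k

    def test_round_corner_filter_removes_circle_noise(self):
        curve = smooth_curve(circle_contour(60), 4.0)
        cands = find_candidates(curve)
        kept = remove_round_corners(cands, curve, 1.5)
        assert len(kept) == 0

    def test_angle_boundary_strict_removal_only(self):
        # synthetic corner set with angles straddling T_angle
        pts = np.stack([np.zeros(100, int), np.arange(100)], axis=1)
        curve = smooth_curve(Contour(points=pts, closed=False), 2.0)
        cs = CornerSet(
            indices=np.array([50]), curvatures=np.array([1.0]),
            angles=np.array([np.nan]),
        )
        kept = remove_false_corners(cs, curve, t_angle=179.9)
        # straight line: angle ~180 -> removed for any t_angle < 180
        assert len(kept) == 0


class TestDetectCorners:
    def test_circle_yields_no_corners(self):
        contour = extract_contour(disk_mask(40))
        assert len(detect_corners(contour, CSSParams())) == 0

    def test_ellipse_mask_yields_no_corners(self):
        contour = extract_contour(ellipse_mask(60, 40))
        assert len(detect_corners(contour, CSSParams())) <= 2

    def test_eight_tooth_leaf_sixteen_corners(self):
        spec = SyntheticLeafSpec(
            n_teeth=8, flank_style="st", sinus_style="angular",
            tooth_amplitude=56.0, seed=3,
        )
        img, _ = generate_leaf(spec)
        contour = extract_contour(segment(img))
        corners = detect_corners(contour, CSSParams())
        assert len(corners) == 16

    def test_corner_count_non_increasing_in_delta(self, simple_leaf):
        _, img, _ = simple_leaf
        contour = extract_contour(segment(img))
        counts = [
            len(detect_corners(contour, CSSParams(delta=d)))
            for d in (2, 4, 5, 6, 7)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_rotation_preserves_corner_count(self, simple_leaf):
        _, img, _ = simple_leaf
        n0 = len(detect_corners(extract_contour(segment(img)), CSSParams()))
        n90 = len(detect_corners(
            extract_contour(segment(np.rot90(img).copy())), CSSParams()))
        assert n0 == n90

    def test_returned_corners_satisfy_filter_inequalities(self, simple_leaf):
        _, img, _ = simple_leaf
        contour = extract_contour(segment(img))
        params = CSSParams()
        corners = detect_corners(contour, params)
        assert np.all(np.diff(corners.indices) > 0)
        assert np.all(corners.angles <= params.t_angle)
        assert np.all(corners.curvatures > 0)

    def test_open_curve_endpoints_marked(self):
        t = np.linspace(0, math.pi, 200)
        x = 100 * np.cos(t) + 110
        y = 60 * np.sin(t) + 70
        contour = Contour(
            points=np.stack([np.round(y), np.round(x)], axis=1).astype(int),
            closed=False,
        )
        corners = detect_corners(contour, CSSParams(endpoint=True))
        assert 0 in corners.indices and (len(contour) - 1) in corners.indices
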