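import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leaftooth import (
    ConvexityTestParams,
    CSSParams,
    detect_corners,
    extract_contour,
    extract_tooth_points,
    find_sinus,
    is_convex,
    split_corners,
)
from leaftooth.features import segment
from leaftooth.preprocess import Contour
from leaftooth.synthetic import SyntheticLeafSpec, generate_leaf

from conftest import disk_mask, ellipse_mask


def wedge_mask(angle_deg: float, size: int = 81):
    """Foreground wedge with its vertex at the centre, opening right."""
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    ang = np.degrees(np.arctan2(yy - c, xx - c))
    m = np.abs(ang) <= angle_deg / 2.0
    m[c, c] = True
    return m, (c, c)


def brute_force_sinus(contour, apex_a, apex_b):
    """Independent max-distance scan with the interior-side convention."""
    pts = contour.points
    n = len(pts)
    seg = [(apex_a + t) % n for t in range(1, (apex_b - apex_a) % n)]
    p1 = pts[apex_a].astype(float)
    p2 = pts[apex_b].astype(float)
    dx, dy = p2[1] - p1[1], p2[0] - p1[0]
    norm = np.hypot(dx, dy)
    best, best_d = None, 0.0
    for i in seg:
        q = pts[i].astype(float)
        cross = dx * (q[0] - p1[0]) - dy * (q[1] - p1[1])
        d = cross / norm
        if d > best_d:
            best, best_d = i, d
    return best


class TestIsConvex:
    def test_wedge_apex_convex(self):
        m, vertex = wedge_mask(60)
        contour = Contour(points=np.array([vertex]), closed=True)
        assert is_convex(0, contour, m, ConvexityTestParams(disk_radius=10))

    def test_reflex_notch_not_convex(self):
        m, vertex = wedge_mask(300)
        contour = Contour(points=np.array([vertex]), closed=True)
        assert not is_convex(0, contour, m, ConvexityTestParams(disk_radius=10))

    def test_straight_edge_not_convex(self):
        # point on a half-plane boundary: foreground fraction ~ 1/2,
        # the strict "less than" rule decides non-convex
        m = np.zeros((41, 41), dtype=bool)
        m[20:, :] = True
        contour = Contour(points=np.array([[20, 20]]), closed=True)
        assert not is_convex(0, contour, m, ConvexityTestParams(disk_radius=8))


class TestSplitCorners:
    def test_square_corners_all_convex(self):
        m = np.zeros((40, 40), dtype=bool)
        m[8:32, 8:32] = True
        contour = extract_contour(m)
        corners = detect_corners(contour, CSSParams(delta=2.0))
        apices = split_corners(corners, contour, m)
        assert len(apices) == 4

    def test_star_leaf_returns_tip_corners(self, simple_leaf):
        spec, img, gt = simple_leaf
        mask = segment(img)
        contour = extract_contour(mask)
        corners = detect_corners(contour, CSSParams())
        apices = split_corners(corners, contour, mask)
        assert len(apices) == spec.n_teeth

    def test_circle_has_no_apices(self):
        m = disk_mask(40)
        contour = extract_contour(m)
        corners = detect_corners(contour, CSSParams())
        assert split_corners(corners, contour, m) == []


class TestFindSinus:
    def test_v_notch_bottom_found(self):
        # two tips with a V-notch between them
        m = np.zeros((60, 80), dtype=bool)
        yy, xx = np.mgrid[:60, :80]
        m[(yy >= 20) & (yy <= 50)] = True
        # V-notch cut into the top edge: widest at y=20, vertex at (40, 40)
        m &= ~((yy >= 20) & (yy < 40) & (np.abs(xx - 40) < (40 - yy)))
        contour = extract_contour(m)
        # the notch shoulders on the top edge act as pseudo-apices
        rows = contour.points[:, 0]
        cols = contour.points[:, 1]
        a = int(np.flatnonzero((rows == 20) & (cols == 20))[0])
        b = int(np.flatnonzero((rows == 20) & (cols == 60))[0])
        # the notch lies on one traversal direction between the shoulders
        s = find_sinus(a, b, contour)
        if s is None:
            s = find_sinus(b, a, contour)
        assert s is not None
        assert abs(int(rows[s]) - 40) <= 2 and abs(int(cols[s]) - 40) <= 2

    def test_matches_brute_force_on_leaf(self, simple_leaf):
        _, img, _ = simple_leaf
        mask = segment(img)
        contour = extract_contour(mask)
        corners = detect_corners(contour, CSSParams())
        apices = split_corners(corners, contour, mask)
        for k in range(len(apices)):
            a, b = apices[k], apices[(k + 1) % len(apices)]
            assert find_sinus(a, b, contour) == brute_force_sinus(contour, a, b)

    def test_bulging_segment_has_no_sinus(self):
        # on a convex disk every between-point lies on the exterior side
        contour = extract_contour(disk_mask(20))
        n = len(contour.points)
        assert find_sinus(0, n // 3, contour) is None


class TestExtractToothPoints:
    def test_tooth_counts_match_generator(self, simple_leaf):
        spec, img, _ = simple_leaf
        mask = segment(img)
        contour = extract_contour(mask)
        corners = detect_corners(contour, CSSParams())
        tps = extract_tooth_points(contour, corners, mask)
        assert tps.n_teeth == spec.n_teeth
        assert len(tps.sinuses) == spec.n_teeth

    def test_ellipse_is_toothless(self):
        m = ellipse_mask(80, 50)
        contour = extract_contour(m)
        corners = detect_corners(contour, CSSParams())
        tps = extract_tooth_points(contour, corners, m)
        assert tps.toothless and tps.n_teeth == 0

    @settings(max_examples=6, deadline=None, derandomize=True)
    @given(
        n_teeth=st.sampled_from([8, 10, 14, 20]),
        sinus=st.sampled_from(["angular"]),
        jitter=st.sampled_from([0.0, 0.3]),
        seed=st.integers(0, 500),
    )
    def test_interleaving_invariant(self, n_teeth, sinus, jitter, seed):
        """Apices and sinuses strictly alternate along the contour."""
        spec = SyntheticLeafSpec(
            n_teeth=n_teeth, sinus_style=sinus, spacing_jitter=jitter,
            tooth_amplitude=min(56.0, 640.0 / n_teeth), seed=seed,
        )
        img, _ = generate_leaf(spec)
        mask = segment(img)
        contour = extract_contour(mask)
        corners = detect_corners(contour, CSSParams())
        tps = extract_tooth_points(contour, corners, mask)
        n = len(contour.points)
        for k, s in enumerate(tps.sinuses):
            if s is None:
                continue
            a = tps.apices[k]
            b = tps.apices[(k + 1) % tps.n_teeth]
            assert 0 < (s - a) % n < (b - a) % n
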