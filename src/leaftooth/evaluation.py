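"""End-to-end validation experiments for the tooth-feature pipeline.

Each function runs one self-contained experiment against synthetic
ground truth or an independent oracle and returns plain numbers, so the
same routines back both the pytest acceptance tests and the
command-line results script.
"""

from __future__ import annotations

import math

import numpy as np

from .config import PipelineConfig
from .css import CSSParams, detect_corners, smooth_curve
from .features import classify_sinus_shape, extract_features, segment
from .preprocess import Contour, close_mask, extract_contour, otsu_threshold
from .synthetic import generate_suite
from .tooth_points import find_sinus

#: Published mean sinus curvatures (1/px) with their class labels.
SINUS_REFERENCE = (
    (0.087059, "angular"),
    (0.078781, "angular"),
    (0.065193, "angular"),
    (0.061088, "angular"),
    (0.043190, "rounded"),
    (0.025086, "rounded"),
    (0.016129, "rounded"),
    (0.009013, "rounded"),
)

DELTA_SWEEP = (2, 4, 5, 6, 7)


def sinus_reference_accuracy(threshold: float = 0.05) -> tuple:
    """How many of the published mean curvatures classify correctly."""
    correct = sum(
        classify_sinus_shape(value, threshold) == label
        for value, label in SINUS_REFERENCE
    )
    return int(correct), len(SINUS_REFERENCE)


def delta_monotonicity(n_leaves: int = 20, seed: int = 0) -> tuple:
    """Leaves whose corner count is non-increasing over the delta sweep.

    Mirrors the original scale-sweep experiment on serrate leaves:
    the suite is restricted to angular-sinus (toothed) templates.
    """
    good = 0
    for _, img, _ in generate_suite(n_leaves, seed, sinus_style="angular"):
        contour = extract_contour(segment(img))
        counts = [
            len(detect_corners(contour, CSSParams(delta=d)))
            for d in DELTA_SWEEP
        ]
        good += all(a >= b for a, b in zip(counts, counts[1:]))
    return good, n_leaves


def ground_truth_recovery(n_leaves: int = 50, seed: int = 0) -> dict:
    """Per-character accuracy of the full pipeline on a synthetic suite."""
    stats = {
        "n": n_leaves, "count_exact": 0, "count_within_1": 0,
        "spacing": 0, "sinus": 0, "orders": 0,
        "flank_cv_st_cc": 0, "flank_cv_st_cc_n": 0,
        "flank_fl_rt": 0, "flank_fl_rt_n": 0,
    }
    for _, img, gt in generate_suite(n_leaves, seed):
        rec = extract_features(img, PipelineConfig())
        diff = abs(rec.n_teeth - gt.n_teeth)
        stats["count_exact"] += diff == 0
        stats["count_within_1"] += diff <= 1
        stats["spacing"] += rec.spacing == gt.spacing
        stats["sinus"] += rec.sinus_shape == gt.sinus_shape
        stats["orders"] += rec.n_orders == gt.n_orders
        key = "flank_fl_rt" if gt.tooth_shape in ("fl", "rt") else "flank_cv_st_cc"
        stats[key + "_n"] += 1
        stats[key] += rec.tooth_shape == gt.tooth_shape
    return stats


# ---------------------------------------------------------------------------
# oracle equivalence

def _brute_otsu(gray: np.ndarray) -> int:
    flat = gray.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(255):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def otsu_oracle_matches(n_images: int = 100, seed: int = 0) -> tuple:
    """Implementation vs exhaustive per-threshold scan on random images."""
    rng = np.random.default_rng(seed)
    good = 0
    for _ in range(n_images):
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        good += otsu_threshold(img) == _brute_otsu(img)
    return good, n_images


def _brute_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    off = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    pad = radius + 1
    world = np.pad(mask, pad, constant_values=False)
    h, w = world.shape
    dil = np.zeros_like(world)
    ero = np.zeros_like(world)
    for r in range(h):
        for c in range(w):
            dil[r, c] = any(
                0 <= r + dr < h and 0 <= c + dc < w and world[r + dr, c + dc]
                for dr, dc in off
            )
    for r in range(h):
        for c in range(w):
            ero[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and dil[r + dr, c + dc]
                for dr, dc in off
            )
    return ero[pad:-pad, pad:-pad]


def closing_oracle_matches(n_masks: int = 20, seed: int = 0) -> tuple:
    """close_mask vs brute-force set-arithmetic dilate/erode."""
    rng = np.random.default_rng(seed)
    good = 0
    for _ in range(n_masks):
        m = rng.random((32, 32)) < 0.4
        good += bool(np.array_equal(close_mask(m, 2), _brute_closing(m, 2)))
    return good, n_masks


def _brute_sinus(contour: Contour, a: int, b: int):
    pts = contour.points
    n = len(pts)
    p1 = pts[a].astype(float)
    p2 = pts[b].astype(float)
    dx, dy = p2[1] - p1[1], p2[0] - p1[0]
    norm = math.hypot(dx, dy)
    best, best_d = None, 0.0
    for t in range(1, (b - a) % n):
        i = (a + t) % n
        q = pts[i].astype(float)
        d = (dx * (q[0] - p1[0]) - dy * (q[1] - p1[1])) / norm
        if d > best_d:
            best, best_d = i, d
    return best


def sinus_oracle_matches(n_leaves: int = 15, seed: int = 0) -> tuple:
    """find_sinus vs exhaustive scan on every apex pair of a suite."""
    from .features import analyze_mask

    good = total = 0
    for _, img, _ in generate_suite(n_leaves, seed):
        mask = segment(img)
        _, contour, _, _, tps = analyze_mask(mask)
        for k in range(tps.n_teeth):
            a = tps.apices[k]
            b = tps.apices[(k + 1) % tps.n_teeth]
            total += 1
            good += find_sinus(a, b, contour) == _brute_sinus(contour, a, b)
    return good, total


# ---------------------------------------------------------------------------
# analytic curvature

def circle_curvature_errors(radii=(20, 50, 100), delta: float = 4.0) -> dict:
    """Max relative |kappa| error against 1/r on parametric circles."""
    out = {}
    for r in radii:
        n = int(2 * math.pi * r)
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        pts = np.stack([r * np.sin(t) + r + 5, r * np.cos(t) + r + 5], axis=1)
        curve = smooth_curve(Contour(points=pts, closed=True), delta)
        err = np.abs(np.abs(curve.kappa) - 1.0 / r) * r
        out[r] = float(err.max())
    return out


def ellipse_curvature_error(a=60.0, b=30.0, delta: float = 4.0) -> float:
    """Median relative error against the ellipse closed form."""
    n = 600
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = np.stack([b * np.sin(t) + b + 5, a * np.cos(t) + a + 5], axis=1)
    curve = smooth_curve(Contour(points=pts, closed=True), delta)
    expected = (a * b) / (
        (a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2) ** 1.5
    )
    rel = np.abs(np.abs(curve.kappa) - expected) / expected
    return float(np.median(rel))


# ---------------------------------------------------------------------------
# symmetry

def symmetry_checks(n_leaves: int = 6, seed: int = 0) -> dict:
    """Rotation fixes all characters; mirroring fixes them too (the
    tooth-shape rule is anchored at the apex end of each flank)."""
    rot_ok = mir_ok = 0
    suite = generate_suite(n_leaves, seed)
    for _, img, _ in suite:
        rec = extract_features(img)
        rot = extract_features(np.rot90(img).copy())
        mir = extract_features(np.fliplr(img).copy())

        def same(a, b):
            return (
                a.n_teeth == b.n_teeth and a.n_orders == b.n_orders
                and a.spacing == b.spacing and a.sinus_shape == b.sinus_shape
                and a.tooth_shape == b.tooth_shape
            )

        rot_ok += same(rec, rot)
        mir_ok += same(rec, mir)
    return {"n": n_leaves, "rotation": rot_ok, "mirror": mir_ok}


def rule_boundary_checks() -> tuple:
    """The three strict inequalities at their printed boundaries."""
    from .features import count_orders, normalize_lengths, spacing_regularity

    ok = 0
    ok += spacing_regularity([6.0, 10.0]) == "irregular"   # min == 0.6*max
    ok += count_orders([1.0, 0.9, 0.95, 0.4, 0.45, 0.42])[0] == 1  # tie
    ok += np.allclose(normalize_lengths([10, 10, 10, 20]),
                      [0.5, 0.5, 0.5, 1.0])                 # 2x mean kept
    return ok, 3
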