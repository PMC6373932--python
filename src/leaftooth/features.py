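"""The five leaf-margin tooth characters, per the Manual of Leaf
Architecture: number of orders of teeth, tooth spacing, number of teeth,
sinus shape, and tooth (flank) shape.

Character definitions
---------------------
* **Tooth length** is the perpendicular distance from a tooth apex to the
  chord through its two flanking sinuses.  Lengths are normalised by the
  longest tooth after discarding outliers longer than twice the mean.
* **Orders of teeth**: if strictly more than half the teeth are shorter
  than half the (normalised) maximum, the leaf has two orders of teeth,
  otherwise one.
* **Tooth spacing** is regular iff the minimum inter-apex distance
  strictly exceeds 0.6 times the maximum.
* **Sinus shape** is angular (V-like) when the mean |curvature| at the
  sinus points exceeds 0.05 px^-1 at the normalised working scale,
  otherwise rounded (U-like).
* **Tooth shape** labels each flank relative to its sinus-apex chord as
  convex (cv), straight (st), concave (cc), flexuous (fl) or
  retroflexed (rt); the leaf-level label is the majority over flanks.

Pixel-class convention: the mask's foreground (the leaf blade) plays the
role of "black" in the region-counting rules; a chord-arc region that is
mostly leaf marks a convex flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon
from skimage.measure import label as _sklabel, regionprops
from skimage.transform import rescale as _skrescale

from .config import PipelineConfig
from .css import SmoothedCurve, detect_corners_with_curve
from .errors import NoLeafError
from .preprocess import (
    Contour,
    close_mask,
    extract_contour,
    load_image,
    otsu_binarize,
    to_grayscale,
)
from .tooth_points import ToothPointSet, extract_tooth_points

FLANK_PRECEDENCE = ("cv", "st", "cc", "fl", "rt")


@dataclass
class Tooth:
    """One tooth: apex and flanking sinus contour indices plus measures."""

    apex: int
    left_sinus: int | None
    right_sinus: int | None
    length: float = np.nan
    order: int | None = None
    flank_labels: tuple = ()


@dataclass
class ToothFeatureRecord:
    """The five extracted characters for one leaf."""

    n_teeth: int
    n_orders: int | None
    spacing: str | None
    sinus_shape: str | None
    tooth_shape: str | None
    mean_sinus_curvature: float | None
    per_tooth: list = field(default_factory=list)
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "n_teeth": self.n_teeth,
            "n_orders": self.n_orders,
            "spacing": self.spacing,
            "sinus_shape": self.sinus_shape,
            "tooth_shape": self.tooth_shape,
            "mean_sinus_curvature": self.mean_sinus_curvature,
            "status": self.status,
        }


@dataclass
class FlankRegionCounts:
    """Foreground/background pixel counts of the chord-arc region(s)."""

    n_B: int = 0
    n_W: int = 0
    n_BB: int = 0
    n_BW: int = 0
    n_DB: int = 0
    n_DW: int = 0


# ---------------------------------------------------------------------------
# tooth length / orders

def _point_line_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, dtype=np.float64) for v in (p, a, b))
    d = b - a
    norm = float(np.hypot(*d))
    if norm < 1e-12:
        return float(np.hypot(*(p - a)))
    return abs(float(d[0] * (p[1] - a[1]) - d[1] * (p[0] - a[0]))) / norm


def tooth_lengths(points: ToothPointSet, contour: Contour) -> np.ndarray:
    """Per-tooth length: apex distance to the chord of its two sinuses.

    Teeth missing a sinus get NaN and are excluded from length-based
    characters downstream.
    """
    n = points.n_teeth
    out = np.full(n, np.nan)
    pts = contour.points
    for k in range(n):
        left = points.sinuses[(k - 1) % n]
        right = points.sinuses[k]
        if left is None or right is None:
            continue
        out[k] = _point_line_distance(
            pts[points.apices[k]], pts[left], pts[right]
        )
    return out


def normalize_lengths(lengths) -> np.ndarray:
    """Outlier-pruned, max-normalised tooth lengths.

    Lengths strictly greater than twice the mean are removed; the
    remainder are divided by their maximum, giving values in (0, 1].
    """
    arr = np.asarray(lengths, dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return arr
    kept = arr[arr <= 2.0 * arr.mean()]
    return kept / kept.max()


def _normalize_with_mask(lengths: np.ndarray):
    """As :func:`normalize_lengths` but aligned to the input positions."""
    arr = np.asarray(lengths, dtype=np.float64)
    valid = np.isfinite(arr)
    out = np.full(arr.shape, np.nan)
    if not valid.any():
        return out
    mean = arr[valid].mean()
    kept = valid & (arr <= 2.0 * mean)
    if not kept.any():
        return out
    out[kept] = arr[kept] / arr[kept].max()
    return out


def count_orders(normalized) -> tuple:
    """Number of orders of teeth and the per-tooth order assignment.

    ``n_short`` counts normalised lengths strictly below 0.5; the leaf
    has two orders iff ``n_short`` strictly exceeds half the tooth
    count.  With two orders, teeth at or above 0.5 are first order.
    NaN entries (excluded teeth) get order None.
    """
    arr = np.asarray(normalized, dtype=np.float64)
    valid = np.isfinite(arr)
    vals = arr[valid]
    if vals.size == 0:
        return 1, [None] * len(arr)
    n_short = int(np.sum(vals < 0.5))
    n_orders = 2 if n_short > vals.size / 2.0 else 1
    orders: list = []
    for v in arr:
        if not np.isfinite(v):
            orders.append(None)
        elif n_orders == 2:
            orders.append(1 if v >= 0.5 else 2)
        else:
            orders.append(1)
    return n_orders, orders


# ---------------------------------------------------------------------------
# spacing

def spacing_distances(points: ToothPointSet, contour: Contour) -> np.ndarray:
    """Euclidean distances between cyclically adjacent tooth apices.

    With exactly two apices both cyclic chords coincide, so a single
    distance is reported.
    """
    n = points.n_teeth
    if n < 2:
        return np.array([])
    pts = contour.points[points.apices].astype(np.float64)
    if n == 2:
        return np.array([float(np.hypot(*(pts[0] - pts[1])))])
    diffs = pts - np.roll(pts, -1, axis=0)
    return np.hypot(diffs[:, 0], diffs[:, 1])


def spacing_regularity(distances, factor: float = 0.6) -> str:
    """"regular" iff min distance strictly exceeds factor * max distance."""
    arr = np.asarray(distances, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("spacing undefined without distances")
    return "regular" if arr.min() > factor * arr.max() else "irregular"


# ---------------------------------------------------------------------------
# sinus shape

def sinus_mean_curvature(
    points: ToothPointSet, curve: SmoothedCurve
) -> float:
    """Mean |curvature| (1/px) over the sinus points."""
    idx = [s for s in points.sinuses if s is not None]
    if not idx:
        raise ValueError("no sinus points")
    return float(np.mean(np.abs(curve.kappa[idx])))


def classify_sinus_shape(mean_curvature: float, threshold: float = 0.05) -> str:
    """"angular" iff the mean sinus curvature strictly exceeds threshold."""
    return "angular" if mean_curvature > threshold else "rounded"


# ---------------------------------------------------------------------------
# tooth (flank) shape

def _arc_between(contour: Contour, i: int, j: int) -> np.ndarray:
    """Contour points along the shorter cyclic span from i to j, inclusive."""
    n = len(contour.points)
    fwd = (j - i) % n
    bwd = (i - j) % n
    if fwd <= bwd:
        idx = (i + np.arange(fwd + 1)) % n
    else:
        idx = (j + np.arange(bwd + 1)) % n
        idx = idx[::-1]
    return contour.points[idx]


def _region_counts(arc_pts: np.ndarray, mask: np.ndarray) -> tuple:
    """Foreground/background pixel counts of the polygon closed by the chord."""
    rr, cc = _draw_polygon(
        arc_pts[:, 0].astype(np.float64),
        arc_pts[:, 1].astype(np.float64),
        shape=mask.shape,
    )
    if rr.size == 0:
        return 0, 0
    vals = mask[rr, cc]
    n_fg = int(np.count_nonzero(vals))
    return n_fg, int(vals.size - n_fg)


def _interior_sign(arc: np.ndarray, u: np.ndarray, a_xy: np.ndarray,
                   mask: np.ndarray) -> int:
    """Which side of the chord (sign of the s coordinate) is leaf interior."""
    mid = arc[len(arc) // 2].astype(np.float64)
    n_hat = np.array([-u[1], u[0]])  # left of chord direction, in (x, y)
    for eta in (3.0, 6.0):
        for sgn in (1, -1):
            x, y = mid[1] + sgn * eta * n_hat[0], mid[0] + sgn * eta * n_hat[1]
            r, c = int(round(y)), int(round(x))
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
                if mask[r, c]:
                    return sgn
    return 1


def classify_flank_shape(
    sinus_idx: int,
    apex_idx: int,
    contour: Contour,
    mask: np.ndarray,
    st_tol_factor: float = 0.12,
    return_counts: bool = False,
):
    """Classify one tooth flank as cv, st, cc, fl or rt.

    The flank arc is the (shorter) contour span between the sinus and
    the apex, oriented apex (A) -> sinus (E).  The arc is rotated into a
    frame with the chord AE on the abscissa and fitted with a quadratic;
    |quadratic coefficient| below ``st_tol_factor / chord_length`` means
    straight.  Otherwise the chord-arc region decides: with no chord
    crossing, a mostly-leaf region is convex and a mostly-background
    region concave; with a crossing at C, region P (A..C, apex side) and
    region Q (C..E, sinus side) are labelled by majority pixel class —
    P leaf & Q background is retroflexed (the flank bends back toward
    the apex), the reverse is flexuous.  Multiple crossings (rare) use
    the crossing nearest the arc midpoint.  Arcs shorter than 4 points
    are straight by convention.
    """
    counts = FlankRegionCounts()
    arc = _arc_between(contour, apex_idx, sinus_idx)  # apex first
    label = _flank_label(arc, mask, st_tol_factor, counts)
    if return_counts:
        return label, counts
    return label


def _flank_label(arc: np.ndarray, mask: np.ndarray, st_tol_factor: float,
                 counts: FlankRegionCounts) -> str:
    m = len(arc)
    if m < 4:
        return "st"
    a_xy = np.array([arc[0][1], arc[0][0]], dtype=np.float64)   # (x, y) of A
    e_xy = np.array([arc[-1][1], arc[-1][0]], dtype=np.float64)
    chord = e_xy - a_xy
    c_len = float(np.hypot(*chord))
    if c_len < 4.0:
        return "st"
    u = chord / c_len
    px = arc[:, 1].astype(np.float64) - a_xy[0]
    py = arc[:, 0].astype(np.float64) - a_xy[1]
    t = px * u[0] + py * u[1]
    s = u[0] * py - u[1] * px  # signed offset, left of A->E positive
    coeffs = np.polyfit(t, s, 2)
    tol = st_tol_factor / c_len
    if abs(coeffs[0]) < tol:
        return "st"
    # interior chord-arc crossings, with 1 px hysteresis so pixel-level
    # flutter where the arc grazes the chord is not read as a crossing
    sgn = np.where(np.abs(s) > 1.0, np.sign(s), 0.0)
    crossings = []
    last_sign = 0.0
    last_k = None
    for k in range(1, m - 1):
        if sgn[k] == 0:
            continue
        if last_sign != 0 and sgn[k] != last_sign:
            crossings.append((last_k, k))
        last_sign = sgn[k]
        last_k = k
    if not crossings:
        n_fg, n_bg = _region_counts(arc, mask)
        counts.n_B, counts.n_W = n_fg, n_bg
        if n_fg == 0 and n_bg == 0:
            # degenerate thin region: decide geometrically
            side = _interior_sign(arc, u, a_xy, mask)
            return "cv" if np.sign(np.nanmean(s)) == side else "cc"
        return "cv" if n_fg > n_bg else "cc"
    if len(crossings) == 1:
        kc = (crossings[0][0] + crossings[0][1]) // 2
    else:
        mid = m // 2
        kc = min(((a + b) // 2 for a, b in crossings),
                 key=lambda k: abs(k - mid))
    p_fg, p_bg = _region_counts(arc[: kc + 1], mask)
    q_fg, q_bg = _region_counts(arc[kc:], mask)
    counts.n_BB, counts.n_BW = p_fg, p_bg
    counts.n_DB, counts.n_DW = q_fg, q_bg
    p_black = p_fg > p_bg
    q_black = q_fg > q_bg
    if p_black and not q_black:
        return "rt"
    if q_black and not p_black:
        return "fl"
    # degenerate: both regions same class; fall back to the no-crossing rule
    n_fg, n_bg = p_fg + q_fg, p_bg + q_bg
    counts.n_B, counts.n_W = n_fg, n_bg
    return "cv" if n_fg > n_bg else "cc"


def aggregate_tooth_shape(labels) -> str:
    """Majority flank label; ties broken by cv > st > cc > fl > rt."""
    labels = list(labels)
    if not labels:
        raise ValueError("no flank labels")
    best = None
    best_count = -1
    for lab in FLANK_PRECEDENCE:
        c = labels.count(lab)
        if c > best_count:
            best, best_count = lab, c
    return best


# ---------------------------------------------------------------------------
# full pipeline

def normalize_mask_scale(mask: np.ndarray, target: int) -> np.ndarray:
    """Rescale a mask so the largest component's major axis is ``target`` px."""
    lab = _sklabel(mask)
    props = regionprops(lab)
    if not props:
        raise NoLeafError("empty mask")
    major = max(props, key=lambda p: p.area).axis_major_length
    if major < 1:
        raise NoLeafError("degenerate leaf region")
    scale = target / major
    if abs(scale - 1.0) < 0.01:
        return mask
    out = _skrescale(mask.astype(np.float64), scale, order=1,
                     anti_aliasing=scale < 1)
    return out > 0.5


def segment(image, config: PipelineConfig | None = None) -> np.ndarray:
    """Image -> closed, scale-normalised binary leaf mask."""
    cfg = config or PipelineConfig()
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = load_image(image)
    gray = to_grayscale(np.asarray(image))
    mask = otsu_binarize(gray, cfg.polarity)
    mask = close_mask(mask, cfg.close_radius)
    if cfg.normalize_size:
        mask = normalize_mask_scale(mask, cfg.normalize_size)
    return mask


def analyze_mask(mask: np.ndarray, config: PipelineConfig | None = None):
    """Mask -> (record, contour, curve, corners, tooth points).

    The workhorse behind :func:`extract_features`; returns the
    intermediate objects for inspection and debug overlays.
    """
    cfg = config or PipelineConfig()
    contour = extract_contour(mask)
    corners, curve = detect_corners_with_curve(contour, cfg.css)
    tps = extract_tooth_points(contour, corners, mask, cfg.convexity_params())
    record = _features_from_points(tps, contour, curve, mask, cfg)
    return record, contour, curve, corners, tps


def _features_from_points(
    points: ToothPointSet,
    contour: Contour,
    curve: SmoothedCurve,
    mask: np.ndarray,
    cfg: PipelineConfig,
) -> ToothFeatureRecord:
    if points.toothless:
        return ToothFeatureRecord(
            n_teeth=len(points.apices), n_orders=None, spacing=None,
            sinus_shape=None, tooth_shape=None, mean_sinus_curvature=None,
            status="toothless",
        )
    n = points.n_teeth
    lengths = tooth_lengths(points, contour)
    norm = _normalize_with_mask(lengths)
    n_orders, orders = count_orders(norm)
    dists = spacing_distances(points, contour)
    spacing = spacing_regularity(dists, cfg.spacing_factor) if dists.size else None
    have_sinus = any(s is not None for s in points.sinuses)
    if have_sinus:
        msc = sinus_mean_curvature(points, curve)
        sinus_shape = classify_sinus_shape(msc, cfg.sinus_threshold)
    else:
        msc, sinus_shape = None, None
    flank_labels: list = []
    teeth: list = []
    for k in range(n):
        left = points.sinuses[(k - 1) % n]
        right = points.sinuses[k]
        labels = []
        for sid in (left, right):
            if sid is None:
                continue
            labels.append(
                classify_flank_shape(
                    sid, points.apices[k], contour, mask,
                    st_tol_factor=cfg.st_tol_factor,
                )
            )
        flank_labels.extend(labels)
        teeth.append(
            Tooth(
                apex=points.apices[k], left_sinus=left, right_sinus=right,
                length=float(lengths[k]), order=orders[k],
                flank_labels=tuple(labels),
            )
        )
    tooth_shape = aggregate_tooth_shape(flank_labels) if flank_labels else None
    return ToothFeatureRecord(
        n_teeth=n, n_orders=n_orders, spacing=spacing,
        sinus_shape=sinus_shape, tooth_shape=tooth_shape,
        mean_sinus_curvature=msc, per_tooth=teeth, status="ok",
    )


def extract_features(
    image, config: PipelineConfig | None = None
) -> ToothFeatureRecord:
    """Full pipeline: image (array or path) -> ToothFeatureRecord."""
    cfg = config or PipelineConfig()
    mask = segment(image, cfg)
    record, *_ = analyze_mask(mask, cfg)
    return record


def records_to_dataframe(records, files=None) -> pd.DataFrame:
    """One row per leaf; ``files`` adds a file column when given."""
    rows = [r.to_dict() for r in records]
    df = pd.DataFrame(rows)
    if files is not None:
        df.insert(0, "file", list(files))
    return df
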