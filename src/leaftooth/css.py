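"""Curvature-scale-space (CSS) corner detection on leaf contours.

The detector smooths the boundary with a Gaussian of width ``delta``,
computes signed curvature from Gaussian-derivative convolutions, takes
local maxima of |curvature| as corner candidates, and then prunes them
with two classic CSS filters:

* *round-corner removal*: a candidate is kept only if its curvature is at
  least ``C`` times the mean |curvature| over its region of support (the
  contour span between its neighbouring candidates);
* *false-corner removal*: a candidate whose opening angle (measured from
  rays to points a fixed number of samples away along the contour) is
  larger than ``T_angle`` is a near-straight inflection and is removed.

A non-maximum-suppression step between the two merges the fragmented
near-equal maxima that pixel quantisation produces at fine scales.

On open curves, endpoints far from every surviving corner may be added
as corners when the ``endpoint`` flag is set.

Smaller ``delta`` resolves dense fine serrations; larger ``delta``
suppresses noise on sparsely toothed margins.  The corner count is
non-increasing in ``delta`` on a fixed contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import TooShortCurveError
from .preprocess import Contour

_TRUNCATE = 6.0  # DoG truncation; at 4 the order-2 kernel's residual floor biases low curvatures


@dataclass
class CSSParams:
    """Corner-detector tunables.

    delta : Gaussian smoothing width in contour samples (~pixels).
    C : round-corner removal factor (candidate kept iff
        |kappa| >= C * mean |kappa| over its region of support).
    t_angle : false-corner angle threshold in degrees; candidates with
        opening angle strictly greater are removed.
    canny_h, canny_l : Canny high/low thresholds for the grayscale
        contour route (fractions of the intensity range).
    gap_size : endpoint gap (px) at or below which a curve is closed.
    endpoint : mark open-curve endpoints as corners when isolated.
    """

    delta: float = 4.0
    C: float = 1.5
    t_angle: float = 162.0
    canny_h: float = 0.35
    canny_l: float = 0.0
    gap_size: float = 3.0
    endpoint: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if not 0 < self.t_angle < 180:
            raise ValueError("t_angle must be in (0, 180)")
        if self.canny_l > self.canny_h:
            raise ValueError("canny_l must not exceed canny_h")
        if self.gap_size < 1:
            raise ValueError("gap_size must be >= 1")


@dataclass
class SmoothedCurve:
    """Gaussian-smoothed contour with per-point signed curvature.

    ``kappa`` is positive where the curve bends toward the leaf interior
    (convex margin), assuming the contour orientation convention of
    :func:`leaftooth.preprocess.extract_contour`.  Points where the
    smoothed speed vanishes get kappa 0 and are flagged in
    ``zero_speed``.
    """

    x: np.ndarray
    y: np.ndarray
    kappa: np.ndarray
    closed: bool
    delta: float
    zero_speed: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class CornerSet:
    """Detected corners: contour indices with |curvature| and opening angle."""

    indices: np.ndarray
    curvatures: np.ndarray
    angles: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def empty(cls) -> "CornerSet":
        z = np.array([], dtype=np.int64)
        return cls(z, np.array([]), np.array([]))


def classify_curve(points: np.ndarray, gap_size: float = 3.0) -> str:
    """Label a point sequence "closed" or "open" by its endpoint gap.

    The curve is closed iff the Euclidean distance between its endpoints
    is at most ``gap_size`` (boundary inclusive).
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        raise ValueError("empty curve")
    gap = float(np.hypot(*(points[0] - points[-1])))
    return "closed" if gap <= gap_size else "open"


def _kernel_size(delta: float) -> int:
    return 2 * int(_TRUNCATE * delta + 0.5) + 1


def smooth_curve(contour: Contour, delta: float = 4.0) -> SmoothedCurve:
    """Smooth contour coordinates with a unit-sum Gaussian of width delta.

    Closed curves use periodic (wrap-around) convolution, open curves a
    reflective extension.  Curvature is computed by Gaussian-derivative
    convolution at the same width:
    ``kappa = (x'y'' - x''y') / (x'^2 + y'^2)^(3/2)``.
    The sign is normalised so that, on closed curves, the total turning
    is +2*pi — convex (interior-bending) margin points then carry
    positive curvature regardless of traversal direction.
    """
    pts = np.asarray(contour.points, dtype=np.float64)
    n = len(pts)
    if n < _kernel_size(delta) and not (contour.closed and n >= 8):
        raise TooShortCurveError(
            f"contour of {n} points is shorter than the Gaussian kernel "
            f"support ({_kernel_size(delta)})"
        )
    mode = "wrap" if contour.closed else "reflect"
    y = pts[:, 0]  # rows
    x = pts[:, 1]  # cols
    xs = gaussian_filter1d(x, delta, mode=mode, truncate=_TRUNCATE)
    ys = gaussian_filter1d(y, delta, mode=mode, truncate=_TRUNCATE)
    xp = gaussian_filter1d(x, delta, order=1, mode=mode, truncate=_TRUNCATE)
    yp = gaussian_filter1d(y, delta, order=1, mode=mode, truncate=_TRUNCATE)
    xpp = gaussian_filter1d(x, delta, order=2, mode=mode, truncate=_TRUNCATE)
    ypp = gaussian_filter1d(y, delta, order=2, mode=mode, truncate=_TRUNCATE)
    speed2 = xp * xp + yp * yp
    zero = speed2 < 1e-12
    denom = np.where(zero, 1.0, speed2**1.5)
    kappa = np.where(zero, 0.0, (xp * ypp - xpp * yp) / denom)
    if contour.closed and n >= 3:
        # total turning = integral of kappa ds; normalise winding to +2*pi
        turning = float(np.sum(kappa * np.sqrt(speed2)))
        if turning < 0:
            kappa = -kappa
    return SmoothedCurve(
        x=xs, y=ys, kappa=kappa, closed=contour.closed, delta=delta,
        zero_speed=zero,
    )


def curvature(curve: SmoothedCurve) -> np.ndarray:
    """Per-point signed curvature of a smoothed curve (1/pixels)."""
    return curve.kappa


def find_candidates(curve: SmoothedCurve) -> CornerSet:
    """Indices of local maxima of |kappa| (plateaus -> central index).

    The neighbourhood is circular on closed curves; on open curves the
    two endpoints are not candidates.
    """
    a = np.abs(curve.kappa)
    n = len(a)
    if n < 3:
        return CornerSet.empty()
    # group consecutive equal values into runs
    run_starts = [0]
    for i in range(1, n):
        if a[i] != a[run_starts[-1]]:
            run_starts.append(i)
    run_vals = [a[s] for s in run_starts]
    m = len(run_starts)
    idx = []
    for r in range(m):
        s = run_starts[r]
        e = run_starts[r + 1] - 1 if r + 1 < m else n - 1
        if curve.closed:
            prev_val = run_vals[(r - 1) % m]
            next_val = run_vals[(r + 1) % m]
            if m == 1:
                break  # constant |kappa|: no strict maxima
        else:
            if r == 0 or r == m - 1:
                continue
            prev_val, next_val = run_vals[r - 1], run_vals[r + 1]
        if run_vals[r] > prev_val and run_vals[r] > next_val:
            center = (s + e) // 2
            if curve.closed or (0 < center < n - 1):
                idx.append(center)
    idx = np.array(sorted(idx), dtype=np.int64)
    return CornerSet(
        indices=idx,
        curvatures=a[idx] if len(idx) else np.array([]),
        angles=np.full(len(idx), np.nan),
    )


def suppress_fragments(
    cands: CornerSet, curve: SmoothedCurve, delta: float
) -> CornerSet:
    """Merge candidate clusters belonging to a single corner.

    At fine smoothing scales pixel quantisation splits one corner's
    curvature peak into several near-equal local maxima a few samples
    apart; left unmerged they truncate each other's regions of support
    and the adaptive round-corner filter removes the whole cluster.
    Greedy non-maximum suppression within ``2 * delta`` samples keeps
    the strongest candidate of each cluster.
    """
    m = len(cands)
    if m <= 1:
        return cands
    n = len(curve.x)
    window = max(2, int(round(2 * delta)))
    order = np.argsort(-cands.curvatures)
    accepted: list = []
    for k in order:
        i = int(cands.indices[k])
        if curve.closed:
            ok = all(
                min((i - j) % n, (j - i) % n) >= window for j in accepted
            )
        else:
            ok = all(abs(i - j) >= window for j in accepted)
        if ok:
            accepted.append(i)
    keep = np.array(
        [k for k in range(m) if int(cands.indices[k]) in set(accepted)],
        dtype=np.int64,
    )
    return CornerSet(
        indices=cands.indices[keep],
        curvatures=cands.curvatures[keep],
        angles=cands.angles[keep],
    )


def _ros_spans(indices: np.ndarray, n: int, closed: bool):
    """Per-candidate region of support: span to neighbour candidates.

    Yields (lo, hi) index pairs; on closed curves hi may exceed n
    (wrapped).  A single candidate on a closed curve gets the whole
    curve.  On open curves the curve ends bound the terminal spans.
    """
    m = len(indices)
    for k in range(m):
        if closed:
            lo = indices[(k - 1) % m]
            hi = indices[(k + 1) % m]
            if m == 1:
                lo, hi = indices[0], indices[0] + n
            else:
                if lo >= indices[k]:
                    lo -= n
                if hi <= indices[k]:
                    hi += n
        else:
            lo = indices[k - 1] if k > 0 else 0
            hi = indices[k + 1] if k + 1 < m else n - 1
        yield int(lo), int(hi)


def remove_round_corners(
    cands: CornerSet, curve: SmoothedCurve, C: float = 1.5
) -> CornerSet:
    """Adaptive-threshold pruning of low-curvature (round) candidates.

    Keeps candidate i iff ``|kappa_i| >= C * mean(|kappa|)`` over its
    region of support.
    """
    if len(cands) == 0:
        return cands
    a = np.abs(curve.kappa)
    n = len(a)
    keep = []
    for k, (lo, hi) in enumerate(_ros_spans(cands.indices, n, curve.closed)):
        span = np.arange(lo, hi + 1) % n
        mean = float(a[span].mean())
        if a[cands.indices[k]] >= C * mean:
            keep.append(k)
    keep = np.array(keep, dtype=np.int64)
    return CornerSet(
        indices=cands.indices[keep],
        curvatures=cands.curvatures[keep],
        angles=cands.angles[keep],
    )


#: Arm-length cap (contour samples) for corner opening angles.  A fixed
#: cap keeps the false-corner filter monotone in the smoothing width:
#: stronger smoothing can only widen a corner's angle past T_angle, so
#: the detected corner count is non-increasing in delta.
ANGLE_ARM_CAP = 12


def corner_angles(
    cands: CornerSet, curve: SmoothedCurve, delta: float
) -> np.ndarray:
    """Opening angle (degrees, in (0, 180]) of each candidate.

    The angle is between the two rays from the corner to points at the
    ends of its region of support, with arm length capped at
    ``ANGLE_ARM_CAP`` samples.
    """
    n = len(curve.x)
    cap = ANGLE_ARM_CAP
    angles = np.empty(len(cands))
    for k in range(len(cands)):
        i = int(cands.indices[k])
        arm_l = arm_r = max(min(cap, (n - 1) // 2), 1)
        ia = (i - arm_l) % n if curve.closed else max(i - arm_l, 0)
        ib = (i + arm_r) % n if curve.closed else min(i + arm_r, n - 1)
        v1 = np.array([curve.x[ia] - curve.x[i], curve.y[ia] - curve.y[i]])
        v2 = np.array([curve.x[ib] - curve.x[i], curve.y[ib] - curve.y[i]])
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-12 or n2 < 1e-12:
            angles[k] = 180.0
            continue
        cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
        ang = math.degrees(math.acos(cosang))
        angles[k] = 180.0 if ang <= 0 else ang
    return angles


def remove_false_corners(
    cands: CornerSet, curve: SmoothedCurve, t_angle: float = 162.0,
    delta: float | None = None,
) -> CornerSet:
    """Remove near-straight candidates (opening angle > t_angle, strict).

    A candidate whose rays are almost collinear (angle approaching 180
    degrees) is an inflection or noise point, not a corner; a candidate
    at exactly ``t_angle`` is retained.
    """
    if len(cands) == 0:
        return cands
    if delta is None:
        delta = curve.delta
    angles = corner_angles(cands, curve, delta)
    keep = angles <= t_angle
    return CornerSet(
        indices=cands.indices[keep],
        curvatures=cands.curvatures[keep],
        angles=angles[keep],
    )


def detect_corners(
    contour: Contour, params: CSSParams | None = None
) -> CornerSet:
    """Full CSS corner detection on a contour.

    Pipeline: open/closed classification, Gaussian smoothing and
    curvature, |kappa| local maxima, round-corner removal, false-corner
    removal, and (open curves only, with the ``endpoint`` flag) endpoint
    marking.  Returns corners in contour order.
    """
    if params is None:
        params = CSSParams()
    kind = classify_curve(contour.points, params.gap_size)
    work = Contour(points=contour.points, closed=(kind == "closed"))
    curve = smooth_curve(work, params.delta)
    cands = find_candidates(curve)
    cands = suppress_fragments(cands, curve, params.delta)
    cands = remove_round_corners(cands, curve, params.C)
    cands = remove_false_corners(cands, curve, params.t_angle, params.delta)
    if kind == "open" and params.endpoint:
        n = len(curve.x)
        far = max(2, int(round(3 * params.delta)))
        idx = list(cands.indices)
        curv = list(cands.curvatures)
        ang = list(cands.angles)
        for end in (0, n - 1):
            if all(abs(end - i) > far for i in idx):
                idx.append(end)
                curv.append(abs(curve.kappa[end]))
                ang.append(np.nan)
        order = np.argsort(idx)
        cands = CornerSet(
            indices=np.asarray(idx, dtype=np.int64)[order],
            curvatures=np.asarray(curv)[order],
            angles=np.asarray(ang)[order],
        )
    return cands


def detect_corners_with_curve(
    contour: Contour, params: CSSParams | None = None
) -> tuple[CornerSet, SmoothedCurve]:
    """As :func:`detect_corners`, also returning the smoothed curve."""
    if params is None:
        params = CSSParams()
    kind = classify_curve(contour.points, params.gap_size)
    work = Contour(points=contour.points, closed=(kind == "closed"))
    curve = smooth_curve(work, params.delta)
    corners = detect_corners(contour, params)
    return corners, curve
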