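"""Splitting CSS corners into tooth apices and locating sinus points.

A detected corner may be a tooth apex (convex), a sinus bottom
(concave), or neither.  The apex test is a disk-counting rule: centre a
disk of radius L on the corner and count leaf (target) versus
background pixels; a corner with strictly fewer leaf pixels than
background pixels is convex.  Sinuses are then found independently of
the corner set: between each pair of adjacent apices, the sinus is the
contour point at maximum perpendicular distance from the apex-apex
chord, searched on the leaf-interior side only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .css import CornerSet
from .preprocess import Contour


@dataclass
class ConvexityTestParams:
    """Disk radius L (pixels) for the convex-point counting test.

    The default scales with the smoothing width so the disk dominates
    single-pixel boundary roughness at the working scale.
    """

    disk_radius: int = 6

    def __post_init__(self) -> None:
        if self.disk_radius < 2:
            raise ValueError("disk_radius must be >= 2")

    @classmethod
    def from_delta(cls, delta: float) -> "ConvexityTestParams":
        return cls(disk_radius=max(5, int(round(1.5 * delta))))


@dataclass
class ToothPointSet:
    """Alternating tooth apices and sinuses along the contour.

    ``apices[k]`` and ``apices[(k+1) % n]`` flank ``sinuses[k]``
    (``None`` where a pair has no interior-side point, i.e. the apices
    flank a smooth lobe).  All values are contour indices.
    """

    apices: list
    sinuses: list
    status: str = "ok"  # "ok" or "toothless"

    @property
    def n_teeth(self) -> int:
        return len(self.apices)

    @property
    def toothless(self) -> bool:
        return self.status == "toothless"


def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    keep = rr * rr + cc * cc <= radius * radius
    return np.stack([rr[keep], cc[keep]], axis=1)


def is_convex(
    corner_idx: int,
    contour: Contour,
    mask: np.ndarray,
    params: ConvexityTestParams | None = None,
) -> bool:
    """Disk-counting convexity test at a contour point.

    Counts foreground (leaf) and background pixels inside the disk of
    radius ``disk_radius`` centred on the corner; convex iff the leaf
    count is strictly less than the background count.  Disks extending
    past the image border are clipped to the image.
    """
    if params is None:
        params = ConvexityTestParams()
    r0, c0 = contour.points[corner_idx]
    off = _disk_offsets(params.disk_radius)
    rr = off[:, 0] + int(r0)
    cc = off[:, 1] + int(c0)
    inb = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    vals = mask[rr[inb], cc[inb]]
    n_fg = int(np.count_nonzero(vals))
    n_bg = int(vals.size - n_fg)
    return n_fg < n_bg


def split_corners(
    corners: CornerSet,
    contour: Contour,
    mask: np.ndarray,
    params: ConvexityTestParams | None = None,
) -> list:
    """Contour indices of the convex corners (tooth apices), in order."""
    if params is None:
        params = ConvexityTestParams()
    return [
        int(i)
        for i in corners.indices
        if is_convex(int(i), contour, mask, params)
    ]


def find_sinus(
    apex_a: int, apex_b: int, contour: Contour
) -> int | None:
    """Sinus between two adjacent apices: max chord distance, interior side.

    Scans contour points strictly between ``apex_a`` and ``apex_b``
    (following contour orientation, wrapping on closed contours) and
    returns the index maximising perpendicular distance to the chord,
    counting only points on the leaf-interior side (the left of the
    chord under the package's orientation convention).  Ties go to the
    first point reached from ``apex_a``.  Returns None when no
    interior-side point exists (the pair flanks a smooth lobe).
    """
    pts = contour.points
    n = len(pts)
    seg_len = (apex_b - apex_a) % n
    if seg_len <= 1:
        return None
    idx = (apex_a + np.arange(1, seg_len)) % n
    p1 = pts[apex_a].astype(np.float64)
    p2 = pts[apex_b].astype(np.float64)
    # work in (x=col, y=row); interior is on the left of p1->p2
    d = np.array([p2[1] - p1[1], p2[0] - p1[0]])
    norm = float(np.hypot(*d))
    if norm < 1e-12:
        # coincident apices: fall back to plain distance from the point
        q = pts[idx].astype(np.float64)
        dist = np.hypot(q[:, 1] - p1[1], q[:, 0] - p1[0])
        return int(idx[int(np.argmax(dist))])
    q = pts[idx].astype(np.float64)
    cross = (d[0] * (q[:, 0] - p1[0]) - d[1] * (q[:, 1] - p1[1]))
    signed = cross / norm  # positive on the interior (left) side
    if not np.any(signed > 0):
        return None
    best = int(np.argmax(signed))  # first max along the segment
    return int(idx[best])


def extract_tooth_points(
    contour: Contour,
    corners: CornerSet,
    mask: np.ndarray,
    params: ConvexityTestParams | None = None,
) -> ToothPointSet:
    """Apices from the convexity split plus one sinus per adjacent pair.

    With fewer than two apices the leaf is reported toothless (entire
    margin) and the point set is empty.
    """
    if params is None:
        params = ConvexityTestParams()
    apices = split_corners(corners, contour, mask, params)
    if len(apices) < 2:
        return ToothPointSet(apices=[], sinuses=[], status="toothless")
    sinuses = []
    n = len(apices)
    for k in range(n):
        a, b = apices[k], apices[(k + 1) % n]
        sinuses.append(find_sinus(a, b, contour))
    return ToothPointSet(apices=apices, sinuses=sinuses, status="ok")
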