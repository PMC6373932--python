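"""Image preprocessing: grayscale conversion, Otsu segmentation, closing,
and single-pixel boundary tracing.

The pipeline front end turns a leaf photograph into (a) a clean binary
mask whose foreground is the leaf blade and (b) an ordered, closed,
single-pixel-wide boundary contour of that blade.  Segmentation is plain
Otsu thresholding followed by a morphological closing with a small disc,
which fills pinholes and hairline breaks in the blade without visibly
distorting the margin.  The boundary is obtained by Moore-neighbour
tracing of the mask, which guarantees an ordered 8-connected pixel chain;
a Canny-based route is provided for grayscale-only operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import feature as _skfeature
from skimage.morphology import closing as _gray_closing, disk

from .errors import (
    DegenerateSegmentationError,
    InvalidInputError,
    NoLeafError,
)

#: Grayscale channel weights (ITU-R BT.601 luma).
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class Contour:
    """Ordered single-pixel boundary of a connected region.

    Attributes
    ----------
    points : (N, 2) int array
        Boundary pixels as (row, col), consecutive points 8-adjacent.
        Traversal is normalised so that the enclosed signed area in
        (x=col, y=row) coordinates is positive, i.e. the region interior
        lies on the *left* of the direction of travel.
    closed : bool
        True if the last point is an 8-neighbour of the first.
    """

    points: np.ndarray
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an RGB or grayscale uint8 array."""
    with Image.open(path) as im:
        if im.mode in ("RGB", "L"):
            arr = np.asarray(im)
        elif im.mode in ("RGBA", "P", "CMYK", "I", "F", "LA"):
            arr = np.asarray(im.convert("RGB"))
        else:
            arr = np.asarray(im.convert("RGB"))
    return arr


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (foreground=255)."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Weighted-average grayscale conversion.

    Each output pixel is ``0.299 R + 0.587 G + 0.114 B`` rounded half-up
    to the nearest integer.  A 2-D (already grayscale) input passes
    through unchanged.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(
            f"expected HxWx3 RGB or HxW grayscale, got shape {img.shape}"
        )
    w = np.asarray(GRAY_WEIGHTS, dtype=np.float64)
    gray = img.astype(np.float64) @ w
    # round-half-up, not banker's rounding
    return np.floor(gray + 0.5).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Exhaustive between-class-variance maximising threshold.

    Scans every integer threshold t in [0, 254]; class 0 holds pixels
    <= t, class 1 pixels > t.  Returns the t maximising
    ``w0 * w1 * (mu0 - mu1)**2`` (first argmax on ties).
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(
        np.float64
    )
    if np.count_nonzero(hist) < 2:
        raise DegenerateSegmentationError("image has a single intensity value")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]                       # pixels <= t, t=0..254
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * levels)[:-1]
    s1 = (hist * levels).sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.zeros(255)
    mu0 = np.divide(s0, w0, out=np.zeros(255), where=valid)
    mu1 = np.divide(s1, w1, out=np.zeros(255), where=valid)
    var_between[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    return int(np.argmax(var_between))


def otsu_binarize(gray: np.ndarray, polarity: str = "auto") -> np.ndarray:
    """Threshold a grayscale image, returning a boolean leaf mask.

    Parameters
    ----------
    gray : HxW uint8 array
    polarity : {"auto", "dark", "light"}
        Which intensity class is the leaf.  "auto" picks the class with
        the smaller number of image-border pixels (leaves are centred on
        a plain background); "dark"/"light" force the below-/above-
        threshold class.
    """
    gray = np.asarray(gray)
    t = otsu_threshold(gray)
    dark = gray <= t
    if polarity == "dark":
        return dark
    if polarity == "light":
        return ~dark
    if polarity != "auto":
        raise InvalidInputError(f"unknown polarity {polarity!r}")
    border = np.zeros_like(dark)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    dark_border = int(np.count_nonzero(dark & border))
    light_border = int(np.count_nonzero(~dark & border))
    return dark if dark_border <= light_border else ~dark


def close_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a disc.

    The mask is padded before closing so that the operation behaves as
    the pure set-arithmetic closing against an unbounded background;
    closing is then extensive (output foreground contains the input
    foreground).
    """
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    pad = radius + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = _gray_closing(padded, disk(radius))
    return closed[pad:-pad, pad:-pad]


# ---------------------------------------------------------------------------
# Boundary tracing

# Moore neighbourhood in clockwise order starting from west (row, col)
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)],
    dtype=np.int64,
)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoLeafError("mask has no foreground component")
    if n == 1:
        return mask & (lab == 1)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def _trace_moore(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour boundary tracing of a single connected component.

    Starts at the row-major first foreground pixel (whose west neighbour
    is guaranteed background) and walks the boundary clockwise in array
    coordinates, stopping when the initial (pixel, entry-direction) state
    recurs (Jacob's criterion).
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([start], dtype=np.int64)

    points = [start]
    cur = start
    backtrack_dir = 0  # index into _MOORE of the background we came from (west)
    first_move = None
    while True:
        nxt = None
        for k in range(1, 9):
            d = (backtrack_dir + k) % 8
            r, c = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(r, c):
                nxt = (r, c)
                move_dir = d
                break
        if nxt is None:  # isolated pixel (already handled above)
            break
        state = (cur, move_dir)
        if first_move is None:
            first_move = state
        elif state == first_move:
            break
        if len(points) > 1 or nxt != start:
            points.append(nxt)
        # new backtrack: the neighbour index pointing back toward the
        # previously examined (background) position
        backtrack_dir = (move_dir + 5) % 8
        cur = nxt
        if len(points) > 4 * mask.size:  # safety net
            break
    # drop the duplicated closing point if present
    if len(points) > 1 and points[-1] == points[0]:
        points.pop()
    return np.array(points, dtype=np.int64)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area in (x=col, y=row) coordinates."""
    x = points[:, 1].astype(np.float64)
    y = points[:, 0].astype(np.float64)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_contour(mask: np.ndarray) -> Contour:
    """Ordered single-pixel boundary of the largest foreground component.

    Orientation is normalised so the signed area in (x=col, y=row)
    coordinates is positive: the leaf interior lies on the left of the
    traversal direction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoLeafError("empty mask")
    comp = _largest_component(mask)
    pts = _trace_moore(comp)
    if len(pts) >= 3 and signed_area(pts) < 0:
        pts = pts[::-1].copy()
        pts = np.roll(pts, 1, axis=0)  # keep the original start point first
    return Contour(points=pts, closed=True)


def contour_from_gray(
    gray: np.ndarray, canny_h: float = 0.35, canny_l: float = 0.0
) -> Contour:
    """Alternative contour route: Canny edges filled to a region, then traced.

    Canny thresholds are fractions of the intensity range, matching the
    high/low convention of the corner-detector parameter set.  On clean
    binary-like input this agrees with the mask-tracing route.
    """
    gray = np.asarray(gray, dtype=np.float64) / 255.0
    edges = _skfeature.canny(
        gray, sigma=1.0, low_threshold=canny_l, high_threshold=canny_h
    )
    filled = ndimage.binary_fill_holes(edges)
    if filled is None or not filled.any():
        raise NoLeafError("Canny route found no closed region")
    return extract_contour(filled)
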