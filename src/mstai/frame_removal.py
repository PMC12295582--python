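"""Unsupervised detection of the dark/white frame around dermoscopic images.

Many dermoscopy photographs carry a solid black (occasionally white)
vignette at the corners or a full border from the imaging optics.  The
detector here is a fixed seven-step classical pipeline:

1. extreme whites are painted black, so white frames behave like dark ones;
2. grayscale by the per-pixel **maximum** of R, G, B (contrast-enhancing);
3. min-max normalization to [0, 1];
4. thresholding at the black threshold ``Bth``, separating dark regions;
5. 8-connected dark components smaller than ``Oth`` pixels are dropped
   (dark spots such as small lesions are not frame);
6. bright holes inside the dark mask smaller than ``Hth`` pixels are
   filled (specular spots inside the frame);
7. the convex hull of the remaining non-frame content becomes the region
   of interest (ROI); everything outside the hull is frame.

Thresholding yields 1 for non-dark pixels; the connected-component cleanup
of steps 5-6 operates on the dark (frame-candidate) complement, and the
hull is taken over the surviving bright content.

The hull uses pixel *centers* as the point set, with exact integer
cross-product tests, so results are reproducible bit-for-bit across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label

from ._validate import as_mask, as_rgb_image
from .errors import ValidationError


@dataclass(frozen=True)
class FrameParams:
    """Thresholds of the frame detector.

    ``white_threshold`` and ``black_threshold`` are fractions of the
    intensity range bounding the non-frame colors from above and below;
    ``object_threshold`` and ``hole_threshold`` are minimum pixel areas
    for frame components and for bright holes inside the frame.  The
    defaults (0.95, 0.05, 64, 64) are the heuristic settings used for
    dermoscopy archives.
    """

    white_threshold: float = 0.95
    black_threshold: float = 0.05
    object_threshold: int = 64
    hole_threshold: int = 64

    def __post_init__(self) -> None:
        if not (0.0 < self.black_threshold < self.white_threshold < 1.0):
            raise ValidationError(
                "black_threshold/white_threshold: require 0 < Bth < Wth < 1"
            )
        if self.object_threshold < 0 or self.hole_threshold < 0:
            raise ValidationError("object_threshold/hole_threshold: must be nonnegative")


def whites_to_black(image: np.ndarray, white_threshold: float = 0.95) -> np.ndarray:
    """Step 1: set pixels whose channel mean reaches ``256 * Wth`` to black.

    The comparison is done on the integer channel sum (R+G+B vs
    ``3 * 256 * Wth``) so the boundary does not drift with float rounding.
    """
    image = as_rgb_image(image)
    channel_sum = image.sum(axis=2, dtype=np.int64)
    out = image.copy()
    out[channel_sum >= 3 * 256.0 * white_threshold] = 0
    return out


def grayscale_max(image: np.ndarray) -> np.ndarray:
    """Step 2: per-pixel maximum over the three channels."""
    return as_rgb_image(image).max(axis=2)


def normalize_unit(gray: np.ndarray) -> np.ndarray:
    """Step 3: min-max normalize to [0, 1]; a constant image maps to all zeros."""
    gray = np.asarray(gray, dtype=float)
    if gray.size == 0:
        raise ValidationError("gray: empty matrix")
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        return np.zeros_like(gray)
    return (gray - lo) / (hi - lo)


def binarize_black(normed: np.ndarray, black_threshold: float = 0.05) -> np.ndarray:
    """Step 4: 1 where value >= ``Bth`` (non-dark), 0 for the dark regions."""
    normed = np.asarray(normed, dtype=float)
    return normed >= black_threshold


def remove_small_objects(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Step 5: drop 8-connected foreground components with area < ``min_area``."""
    mask = as_mask(mask)
    if min_area <= 1:
        return mask.copy()
    labels, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def remove_small_holes(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Step 6: fill background components with area < ``min_area``.

    Identical to step 5 run on the complement of the mask.
    """
    mask = as_mask(mask)
    return ~remove_small_objects(~mask, min_area)


def convex_hull_roi(mask: np.ndarray) -> np.ndarray:
    """Step 7: filled convex hull of the foreground pixel centers.

    A pixel belongs to the hull iff its center lies inside (or on) the
    convex hull of all foreground centers.  Membership is decided with
    integer cross products, so the result is exact.  An empty mask yields
    an empty hull.
    """
    mask = as_mask(mask)
    pts = np.argwhere(mask).astype(np.int64)
    if len(pts) == 0:
        return np.zeros_like(mask)
    if len(pts) == 1:
        return mask.copy()

    try:
        hull = ConvexHull(pts)
    except QhullError:
        return _collinear_hull(mask, pts)

    verts = pts[hull.vertices]  # counter-clockwise order in (row, col) plane
    rmin, cmin = pts.min(axis=0)
    rmax, cmax = pts.max(axis=0)
    rows = np.arange(rmin, rmax + 1, dtype=np.int64)
    cols = np.arange(cmin, cmax + 1, dtype=np.int64)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = np.ones(rr.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        a = verts[i]
        b = verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (cc - a[1]) - (b[1] - a[1]) * (rr - a[0])
        inside &= cross >= 0
    out = np.zeros_like(mask)
    out[rmin : rmax + 1, cmin : cmax + 1] = inside
    return out


def _collinear_hull(mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Degenerate hull: all points on one line -> lattice points on the segment."""
    a = pts[0]
    d = pts[-1] - a
    rmin, cmin = pts.min(axis=0)
    rmax, cmax = pts.max(axis=0)
    rows = np.arange(rmin, rmax + 1, dtype=np.int64)
    cols = np.arange(cmin, cmax + 1, dtype=np.int64)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    on_line = d[0] * (cc - a[1]) - d[1] * (rr - a[0]) == 0
    out = np.zeros_like(mask)
    out[rmin : rmax + 1, cmin : cmax + 1] = on_line
    return out


def detect_frame(
    image: np.ndarray, params: FrameParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full seven-step detector.

    Returns ``(frame_mask, roi_mask)``: a partition of the image into the
    frame and the convex region of interest containing skin and lesion.
    An image with no detectable content (everything dark) yields an empty
    ROI; callers treat that as an excluded sample.
    """
    params = params or FrameParams()
    image = as_rgb_image(image)
    i1 = whites_to_black(image, params.white_threshold)
    i3 = normalize_unit(grayscale_max(i1))
    bright = binarize_black(i3, params.black_threshold)
    dark = ~bright
    dark = remove_small_objects(dark, params.object_threshold)
    dark = remove_small_holes(dark, params.hole_threshold)
    roi = convex_hull_roi(~dark)
    return ~roi, roi
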