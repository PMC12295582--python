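"""Array-contract helpers shared across modules.

Images are ``uint8`` arrays of shape ``(rows, cols, 3)`` (RGB order) and
masks are boolean arrays of shape ``(rows, cols)``.  The pixel grid is
row-major and 0-based with the origin at the top-left corner; every module
in the package uses this convention.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def as_rgb_image(image, name: str = "image") -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"{name}: expected shape (rows, cols, 3), got {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValidationError(f"{name}: expected 8-bit channel values in [0, 255]")
    if arr.size == 0:
        raise ValidationError(f"{name}: image is empty")
    return arr


def as_mask(mask, name: str = "mask", shape: tuple[int, int] | None = None) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"{name}: expected shape (rows, cols), got {arr.shape}")
    if arr.dtype != bool:
        values = np.unique(arr)
        if not np.isin(values, (0, 1, 255)).all():
            raise ValidationError(f"{name}: expected a binary mask, found values {values[:5]}")
        arr = arr > 0
    if shape is not None and arr.shape != tuple(shape):
        raise ValidationError(f"{name}: shape {arr.shape} does not match image shape {tuple(shape)}")
    return arr
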