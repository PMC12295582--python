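"""Synthetic dermoscopy-like images with known ground truth.

Real dermoscopic photographs contain three regions: a dark (occasionally
white) frame or vignette around the optics, the lesion itself, and the
surrounding normal skin.  This module paints images with exactly that
structure — a frame of configurable style, an elliptical lesion and skin
pixels drawn i.i.d. from a known Gaussian mixture in RGB space — together
with the exact frame and lesion masks.  Because the generating mixture is
known, downstream density fits can be checked against the truth.

Everything is deterministic given ``rng_seed``.  Colors are clipped to
[0, 255] after noise; the pre-clip parameters live in the spec object so
moment checks can avoid saturated regions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._validate import as_rgb_image
from .errors import ValidationError

FRAME_STYLES = ("none", "corner_circle_dark", "corner_circle_white", "full_border")

_FRAME_DARK_RGB = (10, 10, 10)
_FRAME_WHITE_RGB = (250, 250, 250)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dermoscopy image.

    ``frame_radius_fraction`` controls the frame geometry: for the corner
    styles it is the diameter of the clear central disk relative to the
    short image side; for ``full_border`` the border width is
    ``round(frame_radius_fraction * min(h, w) / 2)`` so the same fraction
    removes a comparable fraction of the field of view.
    """

    image_height: int = 64
    image_width: int = 64
    frame_style: str = "none"
    frame_radius_fraction: float = 0.9
    lesion_present: bool = False
    lesion_center: tuple[int, int] = (32, 32)
    lesion_axes: tuple[int, int] = (8, 6)
    lesion_color_rgb: tuple[int, int, int] = (70, 45, 40)
    skin_mixture: list[tuple[float, tuple[float, float, float], np.ndarray]] = field(
        default_factory=lambda: [(1.0, (200.0, 150.0, 120.0), np.eye(3) * 25.0)]
    )
    noise_sd: float = 2.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValidationError("image_height/image_width: must be positive")
        if self.frame_style not in FRAME_STYLES:
            raise ValidationError(f"frame_style: {self.frame_style!r} not in {FRAME_STYLES}")
        if not (0.0 < self.frame_radius_fraction <= 1.0):
            raise ValidationError("frame_radius_fraction: must lie in (0, 1]")
        if not self.skin_mixture:
            raise ValidationError("skin_mixture: at least one component required")
        weights = np.array([w for w, _, _ in self.skin_mixture], dtype=float)
        if (weights <= 0).any():
            raise ValidationError("skin_mixture: component weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(f"skin_mixture: weights sum to {weights.sum()}, expected 1")
        for i, (_, mean, cov) in enumerate(self.skin_mixture):
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (3, 3) or not np.allclose(cov, cov.T, atol=1e-9):
                raise ValidationError(f"skin_mixture: covariance {i} is not symmetric 3x3")
            if np.linalg.eigvalsh(cov).min() < -1e-9:
                raise ValidationError(f"skin_mixture: covariance {i} is not positive semi-definite")
            if np.asarray(mean).shape != (3,):
                raise ValidationError(f"skin_mixture: mean {i} is not a 3-vector")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be nonnegative")
        if self.lesion_present:
            frame = self._frame_mask()
            lesion = self._lesion_mask()
            if not lesion.any():
                raise ValidationError("lesion_axes: lesion ellipse contains no pixels")
            if (lesion & frame).any():
                raise ValidationError("lesion_center/lesion_axes: lesion overlaps the frame region")

    # -- geometry -------------------------------------------------------

    def _frame_mask(self) -> np.ndarray:
        h, w = self.image_height, self.image_width
        if self.frame_style == "none":
            return np.zeros((h, w), dtype=bool)
        if self.frame_style == "full_border":
            bw = int(round(self.frame_radius_fraction * min(h, w) / 2))
            mask = np.zeros((h, w), dtype=bool)
            if bw > 0:
                mask[:bw, :] = mask[-bw:, :] = True
                mask[:, :bw] = mask[:, -bw:] = True
            return mask
        # corner-circle vignette: frame is the complement of a centered disk
        radius = self.frame_radius_fraction * min(h, w) / 2.0
        rows, cols = np.ogrid[:h, :w]
        dist2 = (rows - (h - 1) / 2.0) ** 2 + (cols - (w - 1) / 2.0) ** 2
        return dist2 > radius**2

    def _lesion_mask(self) -> np.ndarray:
        h, w = self.image_height, self.image_width
        if not self.lesion_present:
            return np.zeros((h, w), dtype=bool)
        r0, c0 = self.lesion_center
        a, b = self.lesion_axes
        if a <= 0 or b <= 0:
            raise ValidationError("lesion_axes: axes must be positive")
        rows, cols = np.ogrid[:h, :w]
        inside = ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0
        if r0 - a < 0 or r0 + a >= h or c0 - b < 0 or c0 + b >= w:
            raise ValidationError("lesion_center/lesion_axes: lesion extends beyond the image")
        return inside

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["skin_mixture"] = [
            {"weight": float(w), "mean_rgb": list(map(float, m)), "covariance_rgb": np.asarray(c).tolist()}
            for w, m, c in self.skin_mixture
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        mixture = [
            (comp["weight"], tuple(comp["mean_rgb"]), np.asarray(comp["covariance_rgb"], dtype=float))
            for comp in d.pop("skin_mixture")
        ]
        for key in ("lesion_center", "lesion_axes", "lesion_color_rgb"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(skin_mixture=mixture, **d)


def generate_image(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render ``spec`` into ``(image, frame_truth, lesion_truth)``.

    Every pixel belongs to exactly one of frame / lesion / skin.  Skin
    pixels are i.i.d. draws from the spec's Gaussian mixture; frame and
    lesion pixels get their nominal color plus isotropic Gaussian noise of
    sd ``noise_sd``.  All values are clipped to [0, 255] at the end.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_height, spec.image_width
    frame_truth = spec._frame_mask()
    lesion_truth = spec._lesion_mask()
    lesion_truth &= ~frame_truth  # defensive; validation already forbids overlap

    out = np.empty((h, w, 3), dtype=float)

    skin = ~(frame_truth | lesion_truth)
    n_skin = int(skin.sum())
    if n_skin:
        weights = np.array([wk for wk, _, _ in spec.skin_mixture])
        comp = rng.choice(len(weights), size=n_skin, p=weights / weights.sum())
        samples = np.empty((n_skin, 3), dtype=float)
        for k, (_, mean, cov) in enumerate(spec.skin_mixture):
            idx = np.flatnonzero(comp == k)
            if idx.size:
                samples[idx] = rng.multivariate_normal(
                    np.asarray(mean, dtype=float), np.asarray(cov, dtype=float), size=idx.size,
                    method="cholesky" if _is_pd(cov) else "svd",
                )
        out[skin] = samples

    if frame_truth.any():
        base = _FRAME_WHITE_RGB if spec.frame_style == "corner_circle_white" else _FRAME_DARK_RGB
        n = int(frame_truth.sum())
        out[frame_truth] = np.asarray(base, float) + rng.normal(0.0, spec.noise_sd, size=(n, 3))
    if lesion_truth.any():
        n = int(lesion_truth.sum())
        out[lesion_truth] = np.asarray(spec.lesion_color_rgb, float) + rng.normal(
            0.0, spec.noise_sd, size=(n, 3)
        )

    image = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return image, frame_truth, lesion_truth


def _is_pd(cov) -> bool:
    return np.linalg.eigvalsh(np.asarray(cov, dtype=float)).min() > 1e-12


def generate_swatch(
    mean_rgb: tuple[int, int, int], spread: float, n_pixels: int, rng_seed: int = 0
) -> np.ndarray:
    """A 1 x n_pixels RGB swatch with Gaussian pixel noise around ``mean_rgb``.

    Emulates a flat reference color patch (e.g. one Monk scale swatch)
    photographed with sensor noise; ``spread`` is the per-channel sd in
    intensity units before clipping to [0, 255].
    """
    if n_pixels <= 0:
        raise ValidationError("n_pixels: must be positive")
    if spread < 0:
        raise ValidationError("spread: must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    vals = np.asarray(mean_rgb, dtype=float)[None, None, :] + rng.normal(
        0.0, spread, size=(1, n_pixels, 3)
    )
    return np.clip(np.rint(vals), 0, 255).astype(np.uint8)


def write_synthetic(spec: SyntheticSpec, out_dir: str | Path, stem: str = "synthetic") -> dict[str, Path]:
    """Render ``spec`` and write image, masks and a JSON sidecar to ``out_dir``."""
    from . import io as mio  # local import to avoid a cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image, frame_truth, lesion_truth = generate_image(spec)
    paths = {
        "image": out_dir / f"{stem}.png",
        "frame": out_dir / f"{stem}_frame.png",
        "lesion": out_dir / f"{stem}_lesion.png",
        "spec": out_dir / f"{stem}.json",
    }
    mio.write_image(as_rgb_image(image), paths["image"])
    mio.write_mask(frame_truth, paths["frame"])
    mio.write_mask(lesion_truth, paths["lesion"])
    paths["spec"].write_text(json.dumps(spec.to_dict(), indent=2))
    return paths
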