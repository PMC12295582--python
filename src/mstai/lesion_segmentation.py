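"""Lesion masks and segmentation metrics.

The lesion must be excluded before skin-color estimation because its
color differs sharply from normal skin.  Production use feeds externally
produced masks (e.g. from a fully convolutional network trained on the
public lesion-segmentation challenges) through the ``file`` provider; for
self-contained experiments the package ships a small trainable per-pixel
color segmenter — a logistic model over quadratic RGB features optimized
with Adam on the soft Jaccard loss

    L = -log( sum(X * Y) / (sum X + sum Y - sum(X * Y)) )

where X is the reference binary mask and Y the sigmoid output.  A small
smoothing epsilon keeps L finite at zero intersection.  The DICE
coefficient ``2 |X ^ Y| / (|X| + |Y|)`` is reported for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import ProjectiveTransform, SimilarityTransform, resize, warp

from ._validate import as_mask, as_rgb_image
from .errors import ValidationError

#: Smoothing added to numerator and denominator of the Jaccard loss so the
#: loss (and its gradient) stay finite when prediction and truth are disjoint.
JACCARD_EPS = 1e-7


def jaccard_loss(actual: np.ndarray, predicted_soft: np.ndarray, eps: float = JACCARD_EPS) -> float:
    """Negative log intersection-over-union between a binary mask and a soft mask."""
    x = np.asarray(as_mask(actual, "actual"), dtype=float)
    y = np.asarray(predicted_soft, dtype=float)
    if y.shape != x.shape:
        raise ValidationError(f"predicted: shape {y.shape} does not match actual {x.shape}")
    if y.min() < -1e-9 or y.max() > 1 + 1e-9:
        raise ValidationError("predicted: soft mask values must lie in [0, 1]")
    inter = float((x * y).sum())
    union = float(x.sum() + y.sum() - inter)
    if x.sum() == 0 and y.sum() == 0:
        raise ValidationError("actual/predicted: both masks empty; the loss is undefined")
    return float(-np.log((inter + eps) / (union + eps)))


def dice(actual: np.ndarray, predicted: np.ndarray) -> float:
    """DICE overlap of two binary masks: 2 |X ^ Y| / (|X| + |Y|)."""
    x = as_mask(actual, "actual")
    y = as_mask(predicted, "predicted")
    if x.shape != y.shape:
        raise ValidationError(f"predicted: shape {y.shape} does not match actual {x.shape}")
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        raise ValidationError("actual/predicted: both masks empty; DICE is undefined")
    return 2.0 * int((x & y).sum()) / total


@dataclass
class MaskProvider:
    """Where lesion masks come from: a file, a trained model, or nowhere.

    ``none`` treats every pixel as candidate skin — appropriate for images
    without a visible lesion or when no segmenter is available.
    """

    mode: str
    source: object = None

    @classmethod
    def none(cls) -> "MaskProvider":
        return cls(mode="none")

    @classmethod
    def from_file(cls, path: str | Path) -> "MaskProvider":
        return cls(mode="file", source=Path(path))

    @classmethod
    def from_model(cls, model: "PixelSegmenter") -> "MaskProvider":
        return cls(mode="model", source=model)

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "MaskProvider":
        """An in-memory mask, e.g. ground truth or a precomputed segmentation."""
        return cls(mode="array", source=np.asarray(mask))


def lesion_mask(image: np.ndarray, provider: MaskProvider) -> np.ndarray:
    """Resolve a binary lesion mask for ``image`` through ``provider``."""
    from . import io as mio

    image = as_rgb_image(image)
    if provider.mode == "none":
        return np.zeros(image.shape[:2], dtype=bool)
    if provider.mode == "file":
        mask = mio.read_mask(provider.source)
        return as_mask(mask, f"mask file {provider.source}", image.shape[:2])
    if provider.mode == "model":
        return provider.source.predict(image)
    if provider.mode == "array":
        return as_mask(provider.source, "mask array", image.shape[:2])
    raise ValidationError(f"provider.mode: unknown mode {provider.mode!r}")


@dataclass
class TrainingConfig:
    """Training hyperparameters for the toy segmenter.

    Defaults follow the standard recipe for lesion-segmentation
    fine-tuning: Adam at learning rate 1e-4, batches of 32 images, 20
    epochs, inputs resized to 256 x 256 and normalized to [0, 1], with
    joint geometric augmentation of image and mask (flips, translation,
    rotation, scale, shear, perspective).  The tiny from-scratch color
    model typically needs a larger learning rate or more epochs than a
    pre-trained network to converge; both are configurable.
    """

    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 32
    seed: int = 0
    resize_to: tuple[int, int] = (256, 256)
    augment: bool = True
    flip: bool = True
    translate: bool = True
    rotate: bool = True
    scale: bool = True
    shear: bool = True
    perspective: bool = True
    eps: float = JACCARD_EPS


def _features(image01: np.ndarray) -> np.ndarray:
    """Quadratic RGB feature map, shape (n_pixels, 9)."""
    rgb = image01.reshape(-1, 3)
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    return np.stack([r, g, b, r * r, g * g, b * b, r * g, r * b, g * b], axis=1)


@dataclass
class PixelSegmenter:
    """Per-pixel logistic lesion model over quadratic RGB features.

    Resolution-independent: prediction runs at the native image size.
    """

    weights: np.ndarray = field(default_factory=lambda: np.zeros(9))
    bias: float = 0.0
    threshold: float = 0.5

    def predict_soft(self, image: np.ndarray) -> np.ndarray:
        image = as_rgb_image(image)
        z = _features(image.astype(float) / 255.0) @ self.weights + self.bias
        return _sigmoid(z).reshape(image.shape[:2])

    def predict(self, image: np.ndarray) -> np.ndarray:
        return self.predict_soft(image) >= self.threshold

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(
                {"weights": self.weights.tolist(), "bias": self.bias, "threshold": self.threshold}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelSegmenter":
        import json

        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            threshold=float(d.get("threshold", 0.5)),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _augment_pair(image01: np.ndarray, mask: np.ndarray, cfg: TrainingConfig, rng) -> tuple:
    """Apply one random joint geometric transform to image and mask."""
    h, w = mask.shape
    if cfg.flip:
        if rng.random() < 0.5:
            image01, mask = image01[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            image01, mask = image01[::-1, :], mask[::-1, :]
    tf = SimilarityTransform(translation=(-w / 2, -h / 2))
    tf += SimilarityTransform(
        rotation=np.deg2rad(rng.uniform(-25, 25)) if cfg.rotate else 0.0,
        scale=rng.uniform(0.85, 1.15) if cfg.scale else 1.0,
    )
    if cfg.shear:
        sh = np.deg2rad(rng.uniform(-8, 8))
        tf += ProjectiveTransform(np.array([[1, np.tan(sh), 0], [0, 1, 0], [0, 0, 1]]))
    tf += SimilarityTransform(translation=(w / 2, h / 2))
    if cfg.translate:
        tf += SimilarityTransform(translation=rng.uniform(-0.08, 0.08, size=2) * (w, h))
    if cfg.perspective:
        jitter = rng.uniform(-2e-4, 2e-4, size=2)
        tf += ProjectiveTransform(np.array([[1, 0, 0], [0, 1, 0], [jitter[0], jitter[1], 1]]))
    image01 = warp(image01, tf.inverse, order=1, mode="edge")
    mask = warp(mask.astype(float), tf.inverse, order=0, mode="constant", cval=0.0) > 0.5
    return image01, mask


def train_toy_segmenter(
    images: list[np.ndarray], masks: list[np.ndarray], config: TrainingConfig | None = None
) -> tuple[PixelSegmenter, dict]:
    """Train the per-pixel segmenter; returns the model and a training history.

    Minimizes the smoothed Jaccard loss with Adam over batches of images;
    the gradient for one image is
    ``dL/dy_j = -x_j / (I + eps) + (1 - x_j) / (U + eps)`` chained through
    the sigmoid.  The history records the mean loss per epoch, evaluated
    on the un-augmented inputs, so convergence can be inspected.
    """
    cfg = config or TrainingConfig()
    if len(images) == 0 or len(images) != len(masks):
        raise ValidationError("images/masks: need a non-empty, aligned dataset")
    prepared = []
    for img, msk in zip(images, masks):
        img = as_rgb_image(img).astype(float) / 255.0
        msk = as_mask(msk, "mask", img.shape[:2])
        if cfg.resize_to is not None and img.shape[:2] != tuple(cfg.resize_to):
            img = resize(img, cfg.resize_to, order=1, anti_aliasing=True)
            msk = resize(msk.astype(float), cfg.resize_to, order=0) > 0.5
        prepared.append((img, msk))

    rng = np.random.default_rng(cfg.seed)
    model = PixelSegmenter(weights=np.zeros(9), bias=0.0)
    # Adam state
    m = np.zeros(10)
    v = np.zeros(10)
    beta1, beta2, adam_eps, t = 0.9, 0.999, 1e-8, 0
    history = {"epoch_loss": []}

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            grad = np.zeros(10)
            for idx in batch:
                img, msk = prepared[idx]
                if cfg.augment:
                    img, msk = _augment_pair(img, msk, cfg, rng)
                feats = _features(img)
                x = msk.ravel().astype(float)
                y = _sigmoid(feats @ model.weights + model.bias)
                inter = float((x * y).sum())
                union = float(x.sum() + y.sum() - inter)
                dl_dy = -x / (inter + cfg.eps) + (1.0 - x) / (union + cfg.eps)
                dl_dz = dl_dy * y * (1.0 - y)
                grad[:9] += feats.T @ dl_dz
                grad[9] += dl_dz.sum()
            grad /= len(batch)
            t += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            step = cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
            model.weights = model.weights - step[:9]
            model.bias = float(model.bias - step[9])
        losses = []
        for img, msk in prepared:
            y = _sigmoid(_features(img) @ model.weights + model.bias).reshape(msk.shape)
            losses.append(jaccard_loss(msk, y, eps=cfg.eps))
        history["epoch_loss"].append(float(np.mean(losses)))
    return model, history
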