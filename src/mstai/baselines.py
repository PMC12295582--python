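"""Mean-RGB nearest-reference baselines.

Both comparison methods collapse a pixel set to its mean RGB point and
score MST membership by Euclidean distance to the ten reference mean-RGB
points, reusing the same softmax machinery as the density pipeline:

* **Image K-means** — the mean over *all* pixels, frame and lesion included;
* **Skin K-means** — the mean over the detected normal-skin pixels only.

Despite the names, no iterative clustering is involved: each method is a
nearest-reference assignment of a single mean-RGB point.  The names are
kept because that is what these comparison methods are called in the
skin-tone estimation literature.
"""

from __future__ import annotations

import numpy as np

from ._validate import as_mask, as_rgb_image
from .errors import ExclusionError
from .frame_removal import FrameParams, detect_frame
from .membership import MembershipVector, MstReference, membership_scores


def mean_rgb(image: np.ndarray, scope_mask: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic per-channel mean over the scoped pixels (all pixels if no mask)."""
    image = as_rgb_image(image)
    if scope_mask is None:
        return image.reshape(-1, 3).mean(axis=0)
    scope_mask = as_mask(scope_mask, "scope_mask", image.shape[:2])
    if not scope_mask.any():
        raise ExclusionError("excluded: empty pixel scope for mean RGB")
    return image[scope_mask].astype(float).mean(axis=0)


def euclidean_membership(point: np.ndarray, reference: MstReference) -> MembershipVector:
    """Membership scores with Euclidean distance standing in for the divergence."""
    point = np.asarray(point, dtype=float)
    distances = np.linalg.norm(reference.mean_rgbs - point[None, :], axis=1)
    return membership_scores(distances)


def preclassify(
    image: np.ndarray,
    reference: MstReference,
    params: FrameParams | None = None,
    provider=None,
) -> int:
    """Weak nearest-neighbor skin-tone label from the skin-region mean RGB.

    Used to balance sampling across scales before annotation; equidistant
    references resolve to the smaller scale id.
    """
    from .lesion_segmentation import MaskProvider, lesion_mask

    provider = provider or MaskProvider.none()
    frame, _roi = detect_frame(image, params or FrameParams())
    lesion = lesion_mask(image, provider)
    skin = ~(frame | lesion)
    point = mean_rgb(image, skin)
    return euclidean_membership(point, reference).top1
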