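"""Membership of a skin-color density in the ten Monk Skin Tone scales.

The skin density fitted to one image is compared with each of the ten MST
reference densities by a Kullback-Leibler divergence evaluated on a
regular lattice over the RGB cube (default 100 points per axis, i.e. one
million lattice points — matching the 256 discrete states per channel
closely enough that finer grids change nothing material).  On the grid
both densities are renormalized to discrete distributions, which makes
the divergence a proper discrete KLD: nonnegative by Gibbs' inequality
and zero only for identical grid profiles.  With the MST density as P
and the skin density as Q, D(P || Q) measures the information lost when
the skin color stands in for that scale.

The ten divergences are mapped to similarity scores
``s_m = 1 - D_m / max_m D_m`` and passed through a softmax, giving ten
membership scores in (0, 1) that sum to one; the induced descending-score
order ranks the scales from best to worst match.

All evaluation is carried out in the log domain (log-sum-exp mixtures, a
log-space floor for the discrete Q) so no intermediate quantity under- or
overflows even for very peaked mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from ._validate import as_rgb_image
from .color_density import MixtureDensity, PixelCloud, extract_skin_pixels, fit_vbgmm
from .errors import ExclusionError, ValidationError
from .frame_removal import FrameParams, detect_frame

logger = logging.getLogger(__name__)

#: Floor for discrete log-probabilities of Q, preventing +inf divergences
#: where Q has no support under P.  Occurrences are counted and logged.
LOG_FLOOR = np.log(1e-300)


@dataclass
class EvaluationGrid:
    """Cubic lattice over [0, 1]^3 at cell centers ``(i + 0.5) / N``."""

    samples_per_axis: int = 100
    _points: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.samples_per_axis < 2:
            raise ValidationError("samples_per_axis: must be at least 2")

    @property
    def n_points(self) -> int:
        return self.samples_per_axis**3

    @property
    def points(self) -> np.ndarray:
        if self._points is None:
            n = self.samples_per_axis
            axis = (np.arange(n) + 0.5) / n
            g = np.meshgrid(axis, axis, axis, indexing="ij")
            self._points = np.stack([a.ravel() for a in g], axis=1)
        return self._points

    @property
    def cell_volume(self) -> float:
        return 1.0 / self.n_points


def grid_riemann_integral(density: MixtureDensity, grid: EvaluationGrid) -> float:
    """Riemann sum of the density over the unit cube (should be close to 1)."""
    return float(np.exp(density.log_density(grid.points)).mean())


def _normalized_log_profile(density: MixtureDensity, grid: EvaluationGrid) -> np.ndarray:
    logp = density.log_density(grid.points)
    return logp - logsumexp(logp)


def kld(P: MixtureDensity, Q: MixtureDensity, grid: EvaluationGrid | None = None) -> float:
    """Discrete Kullback-Leibler divergence D(P || Q) on the grid.

    Both densities are renormalized over the lattice before the sum
    ``sum_x p(x) (log p(x) - log q(x))``; the floored log q keeps the
    result finite when Q vanishes where P does not.
    """
    grid = grid or EvaluationGrid()
    logp = _normalized_log_profile(P, grid)
    logq = _normalized_log_profile(Q, grid)
    return kld_from_log_profiles(logp, logq)


def kld_from_log_profiles(logp: np.ndarray, logq: np.ndarray) -> float:
    """KLD between two already-normalized discrete log-distributions."""
    p = np.exp(logp)
    floored = logq < LOG_FLOOR
    n_floored = int(floored.sum())
    if n_floored:
        # only noteworthy when Q vanishes where P actually carries mass
        mass = float(p[floored].sum())
        logger.log(
            logging.WARNING if mass > 1e-9 else logging.DEBUG,
            "KLD: floored %d grid log-probabilities of Q (P mass %.3g)",
            n_floored,
            mass,
        )
    logq = np.maximum(logq, LOG_FLOOR)
    d = float(np.sum(p * (logp - logq)))
    # clamp tiny negative round-off; Gibbs guarantees d >= 0 exactly
    return max(d, 0.0) if d > -1e-9 else d


@dataclass
class MembershipVector:
    """Ten membership scores, their source divergences and the induced ranking.

    ``ranking`` lists scale ids (1-based) from best to worst match; ties in
    score are broken toward the smaller scale id.
    """

    scores: np.ndarray
    divergences: np.ndarray
    ranking: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.divergences = np.asarray(self.divergences, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if abs(self.scores.sum() - 1.0) > 1e-9:
            raise ValidationError("scores: must sum to 1 within 1e-9")

    @property
    def n_scales(self) -> int:
        return len(self.scores)

    @property
    def top1(self) -> int:
        return int(self.ranking[0])

    def rank_of(self, scale_id: int) -> int:
        """1-based position of ``scale_id`` in the ranking."""
        return int(np.flatnonzero(self.ranking == scale_id)[0]) + 1


def membership_scores(divergences: np.ndarray) -> MembershipVector:
    """Convert divergences to softmax membership scores and a ranking.

    ``s_m = 1 - D_m / max_m D_m`` followed by a softmax.  If every
    divergence is zero the similarities are all set to zero (uniform
    membership) instead of dividing by zero.
    """
    d = np.asarray(divergences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValidationError("divergences: expected a 1-D vector of length >= 2")
    if not np.isfinite(d).all() or (d < 0).any():
        raise ValidationError("divergences: must be finite and nonnegative")
    dmax = d.max()
    s = np.zeros_like(d) if dmax == 0 else 1.0 - d / dmax
    scores = softmax(s)
    ids = np.arange(1, len(d) + 1)
    order = np.lexsort((ids, -scores))
    return MembershipVector(scores=scores, divergences=d, ranking=ids[order])


@dataclass
class MstReference:
    """The ten MST swatch definitions with fitted reference densities.

    ``swatch_rgbs[m]`` holds one or more representative RGB triples for
    scale ``m+1``; ``mean_rgbs`` are the per-scale mean RGB points used by
    the nearest-reference baselines; ``densities`` are mixture densities
    fitted to swatch pixel clouds in normalized RGB space.
    """

    swatch_rgbs: list[np.ndarray]
    mean_rgbs: np.ndarray
    densities: list[MixtureDensity]
    scale_ids: np.ndarray = field(default_factory=lambda: np.arange(1, 11))
    _grid_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.scale_ids)
        if not (len(self.swatch_rgbs) == len(self.densities) == len(self.mean_rgbs) == n):
            raise ValidationError("reference: scales, swatches, means and densities must align")

    @property
    def n_scales(self) -> int:
        return len(self.scale_ids)

    def log_profiles(self, grid: EvaluationGrid) -> np.ndarray:
        """Normalized log-profiles of all reference densities, shape (10, N^3).

        Cached per grid resolution: the references are fixed, so the grid
        evaluation is paid once per batch instead of once per image.
        """
        key = grid.samples_per_axis
        if key not in self._grid_cache:
            self._grid_cache[key] = np.stack(
                [_normalized_log_profile(dens, grid) for dens in self.densities]
            )
        return self._grid_cache[key]


def build_reference(
    swatch_rgbs: list,
    spread: float = 0.02,
    n_pixels: int = 4000,
    n_components: int = 8,
    seed: int = 0,
) -> MstReference:
    """Fit reference densities from swatch RGB values.

    Each scale's pixel cloud is drawn around its swatch triples in
    normalized RGB space with isotropic sd ``spread`` (default 0.02,
    about 5 intensity levels — the scatter of a photographed flat patch),
    then fitted with the same VB-GMM settings used for images.
    """
    if len(swatch_rgbs) != 10:
        raise ValidationError(f"swatch_rgbs: expected 10 scales, got {len(swatch_rgbs)}")
    swatches, densities, means = [], [], []
    for m, rgbs in enumerate(swatch_rgbs):
        arr = np.atleast_2d(np.asarray(rgbs, dtype=float))
        if arr.shape[1] != 3 or arr.min() < 0 or arr.max() > 255:
            raise ValidationError(f"swatch_rgbs: scale {m + 1} needs RGB triples in [0, 255]")
        rng = np.random.default_rng(np.random.SeedSequence([seed, m]))
        centers = arr[rng.integers(0, len(arr), size=n_pixels)] / 255.0
        cloud = np.clip(centers + rng.normal(0.0, spread, size=(n_pixels, 3)), 0.0, 1.0)
        densities.append(
            fit_vbgmm(PixelCloud(cloud, source=f"mst-swatch-{m + 1}"), n_components, seed=seed + m)
        )
        swatches.append(arr)
        means.append(arr.mean(axis=0))
    return MstReference(swatch_rgbs=swatches, mean_rgbs=np.asarray(means), densities=densities)


@dataclass
class EstimateResult:
    """Outcome of the full pipeline on one image.

    ``membership`` is ``None`` when the image was excluded (e.g. the frame
    covers everything); ``reason`` then says why.  ``provenance`` records
    the thresholds, seeds and grid used, enough to re-run identically.
    """

    membership: MembershipVector | None
    excluded: bool = False
    reason: str | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def top1(self) -> int | None:
        return None if self.membership is None else self.membership.top1


def klds_against_reference(
    skin_density: MixtureDensity, reference: MstReference, grid: EvaluationGrid
) -> np.ndarray:
    """The ten divergences D(P_m || Q), with Q the skin density."""
    logq = _normalized_log_profile(skin_density, grid)
    logps = reference.log_profiles(grid)
    return np.array([kld_from_log_profiles(logp, logq) for logp in logps])


def estimate_image(
    image: np.ndarray,
    reference: MstReference,
    params: FrameParams | None = None,
    provider=None,
    grid: EvaluationGrid | None = None,
    seed: int = 0,
    n_components: int = 8,
) -> EstimateResult:
    """Full pipeline: frame removal, lesion masking, VB-GMM fit, ten KLDs, softmax.

    ``provider`` is a lesion :class:`~mstai.lesion_segmentation.MaskProvider`
    (``None`` means no lesion mask).  Exclusion conditions (no usable skin
    pixels) return a structured excluded result rather than raising.
    """
    from .lesion_segmentation import MaskProvider, lesion_mask

    params = params or FrameParams()
    grid = grid or EvaluationGrid()
    provider = provider or MaskProvider.none()
    image = as_rgb_image(image)
    provenance = {
        "frame_params": {k: getattr(params, k) for k in params.__dataclass_fields__},
        "grid": grid.samples_per_axis,
        "seed": int(seed),
        "n_components": int(n_components),
        "provider": provider.mode,
    }
    frame, _roi = detect_frame(image, params)
    lesion = lesion_mask(image, provider)
    try:
        cloud = extract_skin_pixels(image, frame, lesion)
        if len(cloud) < n_components:
            raise ExclusionError("excluded: insufficient skin area")
    except ExclusionError as exc:
        return EstimateResult(membership=None, excluded=True, reason=exc.reason, provenance=provenance)
    skin_density = fit_vbgmm(cloud, n_components=n_components, seed=seed)
    divergences = klds_against_reference(skin_density, reference, grid)
    return EstimateResult(membership=membership_scores(divergences), provenance=provenance)
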