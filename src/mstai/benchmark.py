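"""End-to-end synthetic benchmark of the three membership methods.

Generates framed, lesion-bearing synthetic dermoscopy images whose skin
mixtures are drawn around the ten MST reference swatches, computes the
gold-standard membership from a fixed annotation rectangle of pure skin,
runs the density pipeline (MST-AI) and both mean-RGB baselines on every
image, and compares their rankings with the evaluation metrics.  This is
a desk-scale analog of a manual-annotation validation campaign: scales
are visited round-robin so the benchmark is balanced by construction.

Study conditions (fixed here, not tuning knobs): 64 x 64 images; frame
styles cycling through dark vignette, no frame, full border, no frame and
white vignette (frames are common but far from universal in dermoscopy
archives); a three-component skin mixture centered on the scale's swatch
whose component means scatter with sd 16 intensity units — comparable to
the spacing of neighboring swatches, so an image's tones genuinely
straddle scales.  Normal skin is multi-tone (several base colors around
one overall shade), which is precisely where a single mean-RGB point
misleads while a density comparison does not.  Per-component sd is 6
intensity units; each image carries one elliptical lesion; a 16 x 16
annotation rectangle of pure skin is the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import euclidean_membership, mean_rgb
from .errors import ValidationError
from .evaluation import MethodComparison, annotation_membership, compare_methods
from .fixtures import SyntheticSpec, generate_image
from .frame_removal import FrameParams, detect_frame
from .lesion_segmentation import MaskProvider
from .membership import EvaluationGrid, MstReference, estimate_image

_STYLES = ("corner_circle_dark", "none", "full_border", "none", "corner_circle_white")

IMAGE_SIZE = 64
ANNOTATION_RECT = (18, 18, 34, 34)  # half-open; pure skin for the geometry below
LESION_CENTER = (42, 42)
LESION_AXES = (6, 5)


def benchmark_spec(scale_rgb: np.ndarray, index: int, seed: int) -> SyntheticSpec:
    """The generating recipe for benchmark image ``index`` of one scale."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
    base = np.asarray(scale_rgb, dtype=float)
    shift = rng.normal(0.0, 16.0, size=(3, 3))
    lesion_rgb = np.clip(base * 0.35 + rng.normal(0.0, 5.0, size=3), 0, 255)
    style = _STYLES[index % len(_STYLES)]
    return SyntheticSpec(
        image_height=IMAGE_SIZE,
        image_width=IMAGE_SIZE,
        frame_style=style,
        frame_radius_fraction=0.88 if style != "full_border" else 0.28,
        lesion_present=True,
        lesion_center=LESION_CENTER,
        lesion_axes=LESION_AXES,
        lesion_color_rgb=tuple(int(v) for v in lesion_rgb),
        skin_mixture=[
            (0.5, tuple(np.clip(base + shift[0], 0, 255)), np.eye(3) * 36.0),
            (0.3, tuple(np.clip(base + shift[1], 0, 255)), np.eye(3) * 36.0),
            (0.2, tuple(np.clip(base + shift[2], 0, 255)), np.eye(3) * 36.0),
        ],
        noise_sd=2.0,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class BenchmarkResult:
    """Per-sample memberships, true generating scales and the metric comparison."""

    comparison: MethodComparison
    annotations: list = field(default_factory=list)
    methods: dict = field(default_factory=dict)
    true_scales: list = field(default_factory=list)
    n_excluded: int = 0


def run_synthetic_benchmark(
    reference: MstReference,
    n_images: int = 300,
    grid: EvaluationGrid | None = None,
    seed: int = 0,
    ks: tuple[int, ...] = (1, 2, 3, 4),
    n_components: int = 8,
) -> BenchmarkResult:
    """Generate ``n_images`` benchmark images and compare the three methods.

    Returns per-sample membership vectors for the annotation gold standard
    and for MST-AI, Image K-means and Skin K-means, plus the aggregated
    :class:`~mstai.evaluation.MethodComparison`.  Images whose pipeline run
    is excluded (none at these conditions) are dropped from the comparison
    and counted.
    """
    if n_images < 10:
        raise ValidationError("n_images: need at least one image per scale")
    grid = grid or EvaluationGrid(64)
    params = FrameParams()
    annotations, true_scales = [], []
    methods: dict[str, list] = {"image_kmeans": [], "skin_kmeans": [], "mstai": []}
    n_excluded = 0
    for i in range(n_images):
        scale = i % 10  # 0-based index; scale id = scale + 1
        spec = benchmark_spec(reference.mean_rgbs[scale], index=i, seed=seed)
        image, frame_truth, lesion_truth = generate_image(spec)

        # the true lesion mask stands in for a trained segmenter, so every
        # method sees the same lesion knowledge
        provider = MaskProvider.from_array(lesion_truth)
        est = estimate_image(
            image,
            reference,
            params=params,
            provider=provider,
            grid=grid,
            seed=seed + i,
            n_components=n_components,
        )
        if est.excluded:
            n_excluded += 1
            continue

        gold = annotation_membership(
            image, ANNOTATION_RECT, reference, grid=grid, seed=seed + i, n_components=n_components
        )
        frame, _roi = detect_frame(image, params)
        skin_scope = ~(frame | lesion_truth)
        methods["mstai"].append(est.membership)
        methods["image_kmeans"].append(euclidean_membership(mean_rgb(image), reference))
        methods["skin_kmeans"].append(
            euclidean_membership(mean_rgb(image, skin_scope), reference)
        )
        annotations.append(gold)
        true_scales.append(scale + 1)

    comparison = compare_methods(annotations, methods, ks=ks)
    return BenchmarkResult(
        comparison=comparison,
        annotations=annotations,
        methods=methods,
        true_scales=true_scales,
        n_excluded=n_excluded,
    )
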