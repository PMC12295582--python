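"""Rank-based comparison of membership methods against annotations.

Each annotated image yields two membership vectors over the ten MST
scales: one computed from the hand-drawn normal-skin rectangle (the gold
standard) and one from the method under test.  Agreement between the two
induced rankings is measured over the top-k scales with Kendall's tau,
Spearman's rho and NDCG, and method means are compared with two-tailed
tests that use the standard deviation of a uniform variable over the
metric's range, sigma = (b - a) / sqrt(12).

Rank conventions (the literature leaves these open; they are fixed here
once): the top-k item set is taken from the gold-standard ranking for the
correlation metrics, with A_i = 1..k by construction; an item outside the
method's top-k keeps its full ten-scale detected rank, so d_i = A_i - D_i
is always defined.  NDCG orders items by the method's ranking but draws
gains 2^m - 1 from the gold-standard membership scores, discounted by
log2(i + 1); the ideal ordering is the gold ranking itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._validate import as_rgb_image
from .color_density import PixelCloud, fit_vbgmm
from .errors import ValidationError
from .membership import (
    EvaluationGrid,
    MembershipVector,
    MstReference,
    klds_against_reference,
    membership_scores,
)


@dataclass
class RankingPair:
    """Gold-standard and detected membership vectors with a top-k cutoff."""

    actual: MembershipVector
    detected: MembershipVector
    k: int

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > self.actual.n_scales:
            raise ValidationError(f"k: must be in 1..{self.actual.n_scales}")
        if self.actual.n_scales != self.detected.n_scales:
            raise ValidationError("actual/detected: differing numbers of scales")

    def topk_ranks(self) -> tuple[np.ndarray, np.ndarray]:
        """(A_i, D_i) over the gold top-k items, in gold rank order."""
        items = self.actual.ranking[: self.k]
        a = np.arange(1, self.k + 1)
        d = np.array([self.detected.rank_of(i) for i in items])
        return a, d


def kendall_tau(pair: RankingPair) -> float:
    """Kendall's tau over the top-k items: (concordant - discordant) / C(k, 2).

    Pairs with tied detected ranks count as discordant, per the strict
    ``> 0`` concordance rule; ties are effectively absent in practice.
    """
    if pair.k < 2:
        raise ValidationError("k: Kendall's tau is undefined for k < 2")
    a, d = pair.topk_ranks()
    total = 0
    for i, j in itertools.combinations(range(pair.k), 2):
        total += 1 if (a[i] - a[j]) * (d[i] - d[j]) > 0 else -1
    return total / (pair.k * (pair.k - 1) / 2)


def spearman_rho(pair: RankingPair) -> float:
    """Spearman's rho 1 - 6 sum d_i^2 / (k (k^2 - 1)) over the top-k items."""
    if pair.k < 2:
        raise ValidationError("k: Spearman's rho is undefined for k < 2")
    a, d = pair.topk_ranks()
    diffs = a - d
    return 1.0 - 6.0 * float(diffs @ diffs) / (pair.k * (pair.k**2 - 1))


def ndcg(pair: RankingPair, as_printed: bool = False) -> float:
    """Normalized discounted cumulative gain of the detected ordering.

    ``as_printed=True`` returns the complementary ``1 - DCG/IDCG`` variant
    for auditability; the default is the standard ratio, which is 1 when
    the detected order is gain-optimal.
    """
    if pair.k < 1:
        raise ValidationError("k: NDCG requires k >= 1")
    gold = dict(zip(pair.actual.ranking.tolist(), _scores_by_rank(pair.actual)))
    discounts = 1.0 / np.log2(np.arange(1, pair.k + 1) + 1)
    det_items = pair.detected.ranking[: pair.k]
    act_items = pair.actual.ranking[: pair.k]
    dcg = float(sum(_gain(gold[int(i)]) * w for i, w in zip(det_items, discounts)))
    idcg = float(sum(_gain(gold[int(i)]) * w for i, w in zip(act_items, discounts)))
    value = dcg / idcg
    return 1.0 - value if as_printed else value


def _gain(m: float) -> float:
    return 2.0**m - 1.0


def _scores_by_rank(mv: MembershipVector) -> list[float]:
    return [float(mv.scores[int(i) - 1]) for i in mv.ranking]


def uniform_sigma(a: float, b: float) -> float:
    """Standard deviation of a uniform variable on [a, b]: (b - a) / sqrt(12)."""
    if b <= a:
        raise ValidationError("bounds: require b > a")
    return (b - a) / np.sqrt(12.0)


def two_tailed_t(mean1: float, mean2: float, n1: int, n2: int, sigma: float) -> float:
    """Two-tailed test of two means under a known, shared sigma.

    The statistic ``(mean1 - mean2) / (sigma * sqrt(1/n1 + 1/n2))`` is
    referred to the standard normal (the known-sigma limit of the
    two-sample t-test; at the sample sizes involved the distinction is
    immaterial).  Differences at p < 0.05 are treated as significant.
    """
    if sigma <= 0:
        raise ValidationError("sigma: must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("n1/n2: need at least two samples per group")
    z = (mean1 - mean2) / (sigma * np.sqrt(1.0 / n1 + 1.0 / n2))
    return float(2.0 * norm.sf(abs(z)))


def top1_histogram(memberships: list[MembershipVector], n_scales: int = 10) -> np.ndarray:
    """Counts of the top-1 scale over a batch; index 0 is scale 1."""
    if not memberships:
        raise ValidationError("memberships: empty list")
    counts = np.zeros(n_scales, dtype=int)
    for mv in memberships:
        counts[mv.top1 - 1] += 1
    return counts


def annotation_membership(
    image: np.ndarray,
    rect: tuple[int, int, int, int],
    reference: MstReference,
    grid: EvaluationGrid | None = None,
    seed: int = 0,
    n_components: int = 8,
) -> MembershipVector:
    """Membership of the pixels inside an annotation rectangle.

    ``rect`` is ``(row_min, col_min, row_max, col_max)``, half-open and
    0-based.  The rectangle is the annotator's statement of "this is what
    the normal skin looks like"; its pixels go through the same VB-GMM +
    KLD machinery as the automatic pipeline.
    """
    image = as_rgb_image(image)
    grid = grid or EvaluationGrid()
    r0, c0, r1, c1 = rect
    h, w = image.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValidationError(f"rect: {rect} is empty or outside the {h}x{w} image")
    cloud = PixelCloud(image[r0:r1, c0:c1].reshape(-1, 3).astype(float) / 255.0, source="annotation")
    density = fit_vbgmm(cloud, n_components=n_components, seed=seed)
    return membership_scores(klds_against_reference(density, reference, grid))


#: Metric ranges for the uniform-sigma significance tests.
METRIC_RANGES = {"kendall_tau": (-1.0, 1.0), "spearman_rho": (-1.0, 1.0), "ndcg": (0.0, 1.0)}


@dataclass
class MethodComparison:
    """Mean ranking metrics per method and pairwise significance tests.

    ``means[metric][method][k]`` is the mean metric at cutoff k (absent
    for the correlations at k=1, where they are undefined);
    ``p_values[metric][k][(m1, m2)]`` is the two-tailed p-value for the
    difference of means between methods m1 and m2.
    """

    n_samples: int
    ks: list[int]
    means: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    per_sample: dict = field(default_factory=dict)


def compare_methods(
    annotations: list[MembershipVector],
    methods: dict[str, list[MembershipVector]],
    ks: tuple[int, ...] = (1, 2, 3, 4),
) -> MethodComparison:
    """Score every method against the annotation memberships at each cutoff."""
    n = len(annotations)
    if n < 2:
        raise ValidationError("annotations: need at least two samples")
    for name, mvs in methods.items():
        if len(mvs) != n:
            raise ValidationError(f"methods[{name}]: {len(mvs)} samples, expected {n}")
    metric_fns = {"kendall_tau": kendall_tau, "spearman_rho": spearman_rho, "ndcg": ndcg}
    result = MethodComparison(n_samples=n, ks=list(ks))
    for metric, fn in metric_fns.items():
        result.means[metric] = {}
        result.per_sample[metric] = {}
        for name, mvs in methods.items():
            result.means[metric][name] = {}
            result.per_sample[metric][name] = {}
            for k in ks:
                if metric != "ndcg" and k < 2:
                    continue  # correlations undefined at k=1
                vals = [fn(RankingPair(actual=a, detected=d, k=k)) for a, d in zip(annotations, mvs)]
                result.per_sample[metric][name][k] = np.asarray(vals)
                result.means[metric][name][k] = float(np.mean(vals))
        sigma = uniform_sigma(*METRIC_RANGES[metric])
        result.p_values[metric] = {}
        for k in ks:
            if metric != "ndcg" and k < 2:
                continue
            result.p_values[metric][k] = {}
            for m1, m2 in itertools.combinations(methods, 2):
                p = two_tailed_t(
                    result.means[metric][m1][k], result.means[metric][m2][k], n, n, sigma
                )
                result.p_values[metric][k][(m1, m2)] = p
    return result
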