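import itertools

import numpy as np
import pytest

from mstai import (
    RankingPair,
    SyntheticSpec,
    ValidationError,
    annotation_membership,
    compare_methods,
    estimate_image,
    generate_image,
    kendall_tau,
    ndcg,
    spearman_rho,
    top1_histogram,
    two_tailed_t,
    uniform_sigma,
)

from .conftest import mv_from_ranking
from .oracles import bf_kendall_tau, bf_ndcg, bf_spearman_rho

IDENTITY = list(range(1, 11))


def pair_with_detected_top4(perm, k=4):
    """Gold = identity ranking; detected permutes the top-4 items."""
    detected = list(perm) + [i for i in IDENTITY if i not in perm]
    return RankingPair(actual=mv_from_ranking(IDENTITY), detected=mv_from_ranking(detected), k=k)


class TestRankCorrelations:
    def test_identity_and_reversal(self):
        assert kendall_tau(pair_with_detected_top4((1, 2, 3, 4))) == 1.0
        assert spearman_rho(pair_with_detected_top4((1, 2, 3, 4))) == 1.0
        assert kendall_tau(pair_with_detected_top4((4, 3, 2, 1))) == -1.0
        assert spearman_rho(pair_with_detected_top4((4, 3, 2, 1))) == -1.0

    def test_single_swap_cases(self):
        pair = pair_with_detected_top4((2, 1, 3, 4))
        assert kendall_tau(pair) == pytest.approx(4 / 6)
        assert spearman_rho(pair) == pytest.approx(0.8)

    def test_k1_is_undefined(self):
        pair = pair_with_detected_top4((1, 2, 3, 4), k=1)
        with pytest.raises(ValidationError):
            kendall_tau(pair)
        with pytest.raises(ValidationError):
            spearman_rho(pair)

    def test_all_permutations_match_bruteforce(self):
        for perm in itertools.permutations((1, 2, 3, 4)):
            pair = pair_with_detected_top4(perm)
            a, d = pair.topk_ranks()
            assert kendall_tau(pair) == pytest.approx(bf_kendall_tau(a, d), abs=1e-15)
            assert spearman_rho(pair) == pytest.approx(bf_spearman_rho(a, d), abs=1e-15)

    def test_invariant_to_consistent_relabeling(self):
        relabel = {i: ((i + 4) % 10) + 1 for i in IDENTITY}
        for perm in [(2, 1, 3, 4), (3, 4, 1, 2)]:
            pair = pair_with_detected_top4(perm)
            mapped_actual = [relabel[i] for i in pair.actual.ranking]
            mapped_detected = [relabel[i] for i in pair.detected.ranking]
            mapped = RankingPair(
                actual=mv_from_ranking(mapped_actual),
                detected=mv_from_ranking(mapped_detected),
                k=4,
            )
            assert kendall_tau(mapped) == pytest.approx(kendall_tau(pair))
            assert spearman_rho(mapped) == pytest.approx(spearman_rho(pair))


class TestNdcg:
    def test_identical_order_is_one(self):
        assert ndcg(pair_with_detected_top4((1, 2, 3, 4))) == pytest.approx(1.0)

    def test_k1_with_matching_top(self):
        assert ndcg(pair_with_detected_top4((1, 3, 2, 4), k=1)) == pytest.approx(1.0)

    def test_two_item_swap_hand_value(self):
        # gold memberships 0.3 then 0.2; detected order swapped
        g = lambda m: 2.0**m - 1.0
        actual = mv_from_ranking(IDENTITY, scores_by_rank=[0.3, 0.2] + [0.5 / 8] * 8)
        detected = mv_from_ranking([2, 1] + IDENTITY[2:], scores_by_rank=[0.3, 0.2] + [0.5 / 8] * 8)
        value = ndcg(RankingPair(actual=actual, detected=detected, k=2))
        expected = (g(0.2) + g(0.3) / np.log2(3)) / (g(0.3) + g(0.2) / np.log2(3))
        assert value == pytest.approx(expected, abs=1e-12)
        # hand evaluation: g(0.3)=0.231144, g(0.2)=0.148698, log2(3)=1.584963
        # DCG = 0.148698 + 0.231144/1.584963 = 0.294531
        # IDCG = 0.231144 + 0.148698/1.584963 = 0.324961
        assert expected == pytest.approx(0.90636, abs=5e-5)

    def test_matches_bruteforce_over_permutations(self):
        actual = mv_from_ranking(IDENTITY)
        gold = {int(i): float(actual.scores[i - 1]) for i in IDENTITY}
        for perm in itertools.permutations((1, 2, 3, 4)):
            detected = mv_from_ranking(list(perm) + [i for i in IDENTITY if i not in perm])
            pair = RankingPair(actual=actual, detected=detected, k=4)
            assert ndcg(pair) == pytest.approx(
                bf_ndcg(gold, list(perm), [1, 2, 3, 4]), abs=1e-12
            )

    def test_as_printed_variant_is_complement(self):
        pair = pair_with_detected_top4((2, 1, 4, 3))
        assert ndcg(pair, as_printed=True) == pytest.approx(1.0 - ndcg(pair))

    def test_bounded_in_unit_interval(self):
        for perm in itertools.permutations((1, 2, 3, 4)):
            v = ndcg(pair_with_detected_top4(perm))
            assert 0.0 <= v <= 1.0


class TestUniformSigmaAndTTest:
    def test_analytic_values(self):
        assert uniform_sigma(-1, 1) == pytest.approx(0.5774, abs=5e-5)
        assert uniform_sigma(0, 1) == pytest.approx(0.2887, abs=5e-5)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValidationError):
            uniform_sigma(0, 0)

    def test_equal_means_give_p_one(self):
        assert two_tailed_t(0.5, 0.5, 100, 100, 0.2887) == pytest.approx(1.0)

    def test_symmetry_in_means(self):
        p1 = two_tailed_t(0.6, 0.5, 50, 50, 0.2887)
        p2 = two_tailed_t(0.5, 0.6, 50, 50, 0.2887)
        assert p1 == pytest.approx(p2)

    def test_large_sample_small_gap_significant(self):
        # NDCG-scale gap of 0.05 at n=1600 per group
        p = two_tailed_t(0.95, 0.90, 1600, 1600, 0.2887)
        assert p < 1e-5


class TestHistogramsAndComparison:
    def test_top1_histogram_counts(self):
        mvs = [mv_from_ranking([5] + [i for i in IDENTITY if i != 5])] * 7
        hist = top1_histogram(mvs)
        assert hist[4] == 7 and hist.sum() == 7

    def test_identical_method_scores_perfectly(self):
        mvs = [mv_from_ranking(np.random.default_rng(s).permutation(IDENTITY)) for s in range(6)]
        comparison = compare_methods(mvs, {"self": mvs, "other": mvs}, ks=(1, 2, 4))
        for metric in ("kendall_tau", "spearman_rho", "ndcg"):
            for k, mean in comparison.means[metric]["self"].items():
                assert mean == pytest.approx(1.0)
        # identical methods: every pairwise p-value is 1
        for metric, per_k in comparison.p_values.items():
            for k, pairs in per_k.items():
                for p in pairs.values():
                    assert p == pytest.approx(1.0)

    def test_correlations_omitted_at_k1(self):
        mvs = [mv_from_ranking(IDENTITY)] * 3
        comparison = compare_methods(mvs, {"m": mvs}, ks=(1, 2))
        assert 1 not in comparison.means["kendall_tau"]["m"]
        assert 1 in comparison.means["ndcg"]["m"]


class TestAnnotationMembership:
    def test_full_rect_matches_pipeline_on_clean_image(self, reference, small_grid):
        spec = SyntheticSpec(frame_style="none", lesion_present=False, rng_seed=21)
        image, _, _ = generate_image(spec)
        mv_rect = annotation_membership(image, (0, 0, 64, 64), reference, small_grid, seed=3)
        result = estimate_image(image, reference, grid=small_grid, seed=3)
        assert np.allclose(mv_rect.scores, result.membership.scores, atol=1e-12)

    def test_flat_rect_recovers_reference_scale(self, reference, palette, small_grid):
        base = tuple(float(v) for v in palette[7])
        spec = SyntheticSpec(
            frame_style="none", skin_mixture=[(1.0, base, np.eye(3) * 25.0)], rng_seed=22
        )
        image, _, _ = generate_image(spec)
        mv = annotation_membership(image, (8, 8, 40, 40), reference, small_grid, seed=4)
        assert mv.top1 == 8

    def test_degenerate_rect_rejected(self, reference, small_grid):
        image = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValidationError):
            annotation_membership(image, (4, 4, 4, 10), reference, small_grid)
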