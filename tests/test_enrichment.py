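import numpy as np
import pytest

from mirprop.enrichment import (
    RankedGeneList,
    leading_edge,
    permutation_test,
    rank_by_effect,
    running_sum,
    screen_families,
)
from mirprop.io_formats import GeneScoreEntry, GeneScoreList
from mirprop.netprop import PropagationResult

from conftest import random_score_list


def _prop(effects: dict[str, float], family_id="fam") -> PropagationResult:
    return PropagationResult(family_id, effects, frozenset(), 1, True)


def naive_running_sum(ranked_ids, weight_of):
    """Independent per-rank loop oracle for the weighted KS running sum."""
    in_univ = [g for g in ranked_ids if g in weight_of]
    denom = sum(abs(weight_of[g]) for g in in_univ)
    n, n_hit = len(ranked_ids), len(in_univ)
    total, best, best_rank = 0.0, -np.inf, 0
    for rank, g in enumerate(ranked_ids, start=1):
        if g in weight_of:
            total += weight_of[g] / denom
        else:
            total -= 1.0 / (n - n_hit)
        if total > best:
            best, best_rank = total, rank
    return best, best_rank


class TestRanking:
    def test_descending_by_effect(self):
        ranked = rank_by_effect(_prop({"A": 0.5, "B": 0.25, "C": 0.125}), ["A", "B", "C"])
        assert ranked.gene_ids == ("A", "B", "C")

    def test_all_zero_effects_rank_lexicographically(self):
        ranked = rank_by_effect(_prop({}), ["b", "a", "c"])
        assert ranked.gene_ids == ("a", "b", "c")

    def test_ties_break_lexicographically(self):
        ranked = rank_by_effect(_prop({"z": 1.0, "a": 1.0, "m": 2.0}), ["z", "a", "m"])
        assert ranked.gene_ids == ("m", "a", "z")

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            rank_by_effect(_prop({}), [])


class TestRunningSum:
    def test_hand_worked_five_gene_example(self, toy_scores):
        ranked = RankedGeneList(("g1", "g2", "g3", "g4", "g5"), (5, 4, 3, 2, 1))
        npes, argmax_rank, curve = running_sum(ranked, toy_scores)
        np.testing.assert_allclose(curve, [2 / 3, 1 / 3, 0.0, 1 / 3, 0.0])
        assert npes == pytest.approx(2 / 3)
        assert argmax_rank == 1

    def test_all_genes_scored_equal_weights_curve_ends_at_one(self):
        scores = GeneScoreList(
            entries=tuple(GeneScoreEntry(g, np.e, 1.0) for g in "abcd")
        )
        ranked = RankedGeneList(tuple("abcd"), (4, 3, 2, 1))
        npes, _, curve = running_sum(ranked, scores)
        assert curve[-1] == pytest.approx(1.0)
        assert npes == pytest.approx(1.0)

    def test_hits_at_bottom_bounded_by_single_hit_weight(self):
        scores = GeneScoreList(
            entries=(GeneScoreEntry("g9", np.e, 1.0), GeneScoreEntry("g8", np.e, 1.0))
        )
        ranked = RankedGeneList(
            tuple(f"g{i}" for i in range(10)), tuple(range(10, 0, -1))
        )
        npes, _, _ = running_sum(ranked, scores)
        assert npes <= 0.5 + 1e-12

    def test_agrees_with_naive_loop_on_random_lists(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(10, 300))
            universe = [f"g{i:04d}" for i in range(n)]
            scores = random_score_list(rng, universe, int(rng.integers(2, n // 2 + 2)))
            order = list(rng.permutation(universe))
            ranked = RankedGeneList(tuple(order), tuple(range(n, 0, -1)))
            npes, argmax_rank, _ = running_sum(ranked, scores)
            exp_npes, exp_rank = naive_running_sum(order, scores.log_weight_of())
            assert npes == pytest.approx(exp_npes)
            assert argmax_rank == exp_rank

    def test_positive_scaling_of_weights_leaves_npes_invariant(self, toy_scores):
        ranked = RankedGeneList(("g1", "g2", "g3", "g4", "g5"), (5, 4, 3, 2, 1))
        scaled = GeneScoreList(
            entries=tuple(
                GeneScoreEntry(e.gene_id, e.reliability, e.log_reliability * 7.3)
                for e in toy_scores.entries
            )
        )
        assert running_sum(ranked, toy_scores)[0] == pytest.approx(
            running_sum(ranked, scaled)[0]
        )

    def test_no_scored_gene_in_universe_rejected(self):
        ranked = RankedGeneList(("a", "b"), (2, 1))
        scores = GeneScoreList(entries=(GeneScoreEntry("zzz", 2.0, np.log(2.0)),))
        with pytest.raises(ValueError, match="empty candidate set"):
            running_sum(ranked, scores)


class TestPermutationTest:
    def _ranked(self, n=50):
        return RankedGeneList(
            tuple(f"g{i:03d}" for i in range(n)), tuple(range(n, 0, -1))
        )

    def test_p_respects_add_one_lower_bound(self):
        # scores packed at the very top: the observed NPES is hard to beat
        scores = GeneScoreList(
            entries=tuple(GeneScoreEntry(f"g{i:03d}", np.e, 1.0) for i in range(5))
        )
        p = permutation_test(self._ranked(), scores, n_permutations=99, rng_seed=3)
        assert p >= 1 / 100
        assert p == pytest.approx(1 / 100)

    def test_degenerate_constant_statistic_gives_p_one(self):
        # every gene scored with equal weight: any reassignment is identical
        n = 10
        scores = GeneScoreList(
            entries=tuple(GeneScoreEntry(f"g{i:03d}", np.e, 1.0) for i in range(n))
        )
        p = permutation_test(self._ranked(n), scores, n_permutations=50, rng_seed=0)
        assert p == 1.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(21)
        universe = [f"g{i:03d}" for i in range(80)]
        scores = random_score_list(rng, universe, 12)
        ranked = self._ranked(80)
        p1 = permutation_test(ranked, scores, 200, rng_seed=7)
        p2 = permutation_test(ranked, scores, 200, rng_seed=7)
        assert p1 == p2

    def test_null_is_roughly_calibrated(self):
        """Random score placement should give ~uniform p-values (coarse
        check at n=200 lists; the fine-grained audit runs in acceptance)."""
        rng = np.random.default_rng(2)
        n, hits, m = 100, 10, 200
        universe = [f"g{i:03d}" for i in range(n)]
        count = 0
        for i in range(m):
            scores = random_score_list(rng, universe, hits)
            order = tuple(rng.permutation(universe))
            ranked = RankedGeneList(order, tuple(range(n, 0, -1)))
            p = permutation_test(ranked, scores, 200, rng_seed=int(rng.integers(2**31)))
            count += p <= 0.05
        assert 0.01 <= count / m <= 0.10


class TestLeadingEdge:
    def test_toy_leading_edge_is_top_hit(self, toy_scores):
        ranked = RankedGeneList(("g1", "g2", "g3", "g4", "g5"), (5, 4, 3, 2, 1))
        assert leading_edge(ranked, toy_scores, 1) == {"g1"}

    def test_argmax_at_last_rank_returns_all_scored(self, toy_scores):
        ranked = RankedGeneList(("g1", "g2", "g3", "g4", "g5"), (5, 4, 3, 2, 1))
        assert leading_edge(ranked, toy_scores, 5) == {"g1", "g4"}

    def test_invalid_rank_rejected(self, toy_scores):
        ranked = RankedGeneList(("g1",), (1,))
        with pytest.raises(ValueError):
            leading_edge(ranked, toy_scores, 2)


class TestScreenFamilies:
    def test_single_family_q_equals_p(self, toy_scores):
        universe = ["g1", "g2", "g3", "g4", "g5"]
        prop = _prop({"g1": 5.0, "g4": 1.0}, "solo")
        (res,) = screen_families([prop], toy_scores, universe, n_permutations=99)
        assert res.q_value == res.p_value

    def test_bh_adjustment_matches_hand_computation(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.9], method="fdr_bh")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.9])

    def test_results_sorted_by_q_then_npes(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i:03d}" for i in range(60)]
        scores = random_score_list(rng, universe, 10)
        props = [
            _prop({g: float(rng.random()) for g in universe[:20]}, f"fam{k}")
            for k in range(4)
        ]
        results = screen_families(props, scores, universe, n_permutations=99, rng_seed=1)
        keys = [(r.q_value, -r.npes) for r in results]
        assert keys == sorted(keys)

    def test_negative_enrichment_never_significant(self):
        # single scored gene pinned to the bottom rank: the curve is
        # negative until the end, and a max ≤ 0 must not be flagged
        universe = [f"g{i:03d}" for i in range(20)]
        scores = GeneScoreList(entries=(GeneScoreEntry("g019", np.e, 1.0),))
        prop = _prop({g: 20.0 - i for i, g in enumerate(universe)}, "neg")
        (res,) = screen_families([prop], scores, universe, n_permutations=49, rng_seed=0)
        assert res.npes <= 1.0
        if res.npes <= 0:
            assert not res.significant
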