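import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfet._errors import ConfigError, DataError
from rfet.ensemble import (
    aggregate_rankings,
    composite_score,
    make_cv_plan,
    merge_fold_lists,
    occurrence_table,
    run_ensemble,
    top_n_occurrence,
)
from rfet.io_core import ExpressionMatrix, RankedEntry, RankedList
from rfet.svm_rfe import SVMConfig

from .conftest import make_matrix


def build_list(order_best_to_worst: list[str], criteria: list[float]) -> RankedList:
    """RankedList from an explicit rank order and per-gene criterion values."""
    g = len(order_best_to_worst)
    return RankedList(
        [
            RankedEntry(p, g - i, c)
            for i, (p, c) in enumerate(zip(order_best_to_worst, criteria))
        ]
    )


class TestMakeCvPlan:
    def test_six_fold_on_twelve(self):
        plan = make_cv_plan(12, 6, 1, seed=0)
        folds = plan.splits[0]
        assert len(folds) == 6
        assert all(len(f) == 2 for f in folds)
        held = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(held, np.arange(12))
        # training set = all minus one subset
        for f in folds:
            assert len(np.setdiff1d(np.arange(12), f)) == 10

    def test_leave_one_out_boundary(self):
        plan = make_cv_plan(8, 8, 1, seed=1)
        assert all(len(f) == 1 for f in plan.splits[0])

    def test_each_sample_excluded_once_per_repetition(self):
        plan = make_cv_plan(10, 4, 3, seed=5)
        for folds in plan.splits:
            counts = np.zeros(10, dtype=int)
            for f in folds:
                counts[f] += 1
            np.testing.assert_array_equal(counts, np.ones(10, dtype=int))

    def test_fold_sizes_near_equal(self):
        plan = make_cv_plan(10, 3, 2, seed=2)
        for folds in plan.splits:
            sizes = sorted(len(f) for f in folds)
            assert max(sizes) - min(sizes) <= 1

    def test_same_seed_reproducible(self):
        a = make_cv_plan(12, 6, 5, seed=42)
        b = make_cv_plan(12, 6, 5, seed=42)
        for fa, fb in zip(a.splits, b.splits):
            for x, y in zip(fa, fb):
                np.testing.assert_array_equal(x, y)

    def test_different_seeds_differ(self):
        a = make_cv_plan(12, 6, 5, seed=1)
        b = make_cv_plan(12, 6, 5, seed=2)
        assert any(
            not np.array_equal(x, y)
            for fa, fb in zip(a.splits, b.splits)
            for x, y in zip(fa, fb)
        )

    def test_stratified_balances_classes(self):
        labels = np.array([1] * 6 + [0] * 6)
        plan = make_cv_plan(12, 6, 4, seed=3, labels=labels, stratified=True)
        for folds in plan.splits:
            for f in folds:
                assert labels[f].sum() == 1  # one of each class per size-2 fold

    def test_folds_exceeding_samples(self):
        with pytest.raises(ConfigError):
            make_cv_plan(5, 6, 1, seed=0)

    def test_too_few_folds(self):
        with pytest.raises(ConfigError):
            make_cv_plan(5, 1, 1, seed=0)

    def test_stratified_needs_labels(self):
        with pytest.raises(ConfigError):
            make_cv_plan(6, 3, 1, seed=0, stratified=True)


class TestRunEnsemble:
    def _signal_matrix(self, rng, g=12, n=12):
        y = np.array([1, 0] * (n // 2))
        values = rng.normal(size=(g, n))
        values[0, y == 1] += 4.0  # strong planted gene
        return make_matrix(values), y

    def test_per_repetition_list_count(self, rng):
        m, y = self._signal_matrix(rng)
        plan = make_cv_plan(12, 6, 7, seed=0)
        lists, acc = run_ensemble(m, y, plan)
        assert len(lists) == 7
        assert len(acc) == 7 * 6
        for fl in lists:
            assert sorted(fl.probe_ids) == sorted(m.probe_ids)

    def test_pooled_list_count(self, rng):
        m, y = self._signal_matrix(rng)
        plan = make_cv_plan(12, 3, 2, seed=0)
        lists, _ = run_ensemble(m, y, plan, mode="pooled")
        assert len(lists) == 6

    def test_loocv_perfect_gene_ranked_first(self):
        y = np.array([1, 0] * 4)
        values = np.vstack([np.where(y == 1, 1.0, -1.0), np.full(8, 0.1), np.zeros(8)])
        values[1] = np.random.default_rng(0).normal(scale=0.1, size=8)
        m = make_matrix(values)
        plan = make_cv_plan(8, 8, 1, seed=0)
        lists, _ = run_ensemble(m, y, plan)
        assert len(lists) == 1
        assert lists[0].ordered_probes()[0] == "g001"

    def test_single_class_training_set_rejected(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        m = make_matrix(np.random.default_rng(1).normal(size=(5, 6)))
        # 2 folds of 3: some seed puts all of one class in a fold
        for seed in range(50):
            plan = make_cv_plan(6, 2, 1, seed=seed)
            if any(len(set(y[f])) == 1 for f in plan.splits[0]):
                with pytest.raises(DataError, match="single-class"):
                    run_ensemble(m, y, plan)
                return
        pytest.skip("no degenerate split found in 50 seeds")

    def test_accuracy_log_high_for_strong_signal(self, rng):
        # several informative genes so the full-feature classifier generalizes
        y = np.array([1, 0] * 6)
        values = rng.normal(size=(12, 12))
        values[:5, y == 1] += 3.0
        plan = make_cv_plan(12, 6, 3, seed=1)
        _, acc = run_ensemble(make_matrix(values), y, plan)
        assert np.mean([a.accuracy for a in acc]) > 0.8

    def test_determinism_end_to_end(self, rng):
        m, y = self._signal_matrix(rng)
        plan = make_cv_plan(12, 6, 3, seed=9)
        lists1, _ = run_ensemble(m, y, plan)
        lists2, _ = run_ensemble(m, y, plan)
        for a, b in zip(lists1, lists2):
            assert a.ordered_probes() == b.ordered_probes()
            assert [e.criterion for e in a.entries] == [e.criterion for e in b.entries]


class TestMergeFoldLists:
    def test_mean_rank_merge(self):
        l1 = build_list(["A", "B", "C"], [3.0, 2.0, 1.0])
        l2 = build_list(["B", "A", "C"], [4.0, 2.0, 0.5])
        merged = merge_fold_lists([l1, l2], ["A", "B", "C"])
        # A mean rank 1.5, B 1.5, C 3; tie broken by mean criterion (B: 3.0 > A: 2.5)
        assert merged.ordered_probes() == ["B", "A", "C"]

    def test_tie_falls_back_to_probe_order(self):
        l1 = build_list(["A", "B"], [1.0, 1.0])
        l2 = build_list(["B", "A"], [1.0, 1.0])
        merged = merge_fold_lists([l1, l2], ["B", "A"])
        assert merged.ordered_probes() == ["B", "A"]

    def test_mismatched_universe_rejected(self):
        l1 = build_list(["A", "B"], [1.0, 1.0])
        l2 = build_list(["A", "C"], [1.0, 1.0])
        with pytest.raises(DataError):
            merge_fold_lists([l1, l2], ["A", "B", "C"])


class TestAggregateRankings:
    def _three_lists(self):
        l1 = build_list(["A", "B", "C", "D", "E"], [4.0, 3.0, 2.0, 1.0, 0.5])
        l2 = build_list(["A", "C", "B", "D", "E"], [5.0, 2.5, 1.5, 1.0, 0.2])
        l3 = build_list(["B", "A", "D", "C", "E"], [6.0, 2.0, 3.0, 0.5, 0.1])
        return [l1, l2, l3]

    def test_hand_computed_oracle_n2(self):
        # manual arithmetic over all (gene, list) pairs with N=2:
        #   rank 1 contributes w * 1.0, rank 2 contributes w * 0.5
        # A: 4.0 + 5.0 + 2.0*0.5 = 10.0  (O=3, S=11.0)
        # B: 3.0*0.5 + 6.0      = 7.5    (O=2, S=9.0)
        # C: 2.5*0.5            = 1.25   (O=1, S=2.5)
        # D, E: never in top-2 -> score 0, ordered by mean rank (D 11/3 < E 5)
        agg = aggregate_rankings(self._three_lists(), N=2)
        assert agg.ordered_probes() == ["A", "B", "C", "D", "E"]
        by_id = {e.probe_id: e for e in agg.entries}
        assert by_id["A"].score == pytest.approx(10.0)
        assert by_id["B"].score == pytest.approx(7.5)
        assert by_id["C"].score == pytest.approx(1.25)
        assert by_id["A"].occurrence == 3
        assert by_id["B"].occurrence == 2
        assert by_id["C"].occurrence == 1
        assert by_id["A"].weight_sum == pytest.approx(11.0)
        assert by_id["B"].weight_sum == pytest.approx(9.0)
        assert by_id["C"].weight_sum == pytest.approx(2.5)
        assert by_id["D"].score == 0.0 and by_id["D"].occurrence == 0
        assert by_id["D"].final_rank == 4 and by_id["E"].final_rank == 5

    def test_single_list_identity_with_monotone_weights(self):
        lst = build_list(["A", "B", "C", "D"], [9.0, 4.0, 1.0, 0.25])
        agg = aggregate_rankings([lst], N=4)
        assert agg.ordered_probes() == ["A", "B", "C", "D"]

    def test_dominant_gene_final_rank_one(self):
        lists = [
            build_list(["X", "B", "C"], [5.0, 1.0, 0.5]),
            build_list(["X", "C", "B"], [4.0, 1.2, 0.3]),
        ]
        agg = aggregate_rankings(lists, N=2)
        assert agg.entries[0].probe_id == "X"
        assert agg.entries[0].final_rank == 1

    def test_order_invariance(self):
        lists = self._three_lists()
        a = aggregate_rankings(lists, N=2)
        b = aggregate_rankings(list(reversed(lists)), N=2)
        assert a.ordered_probes() == b.ordered_probes()
        assert [e.score for e in a.entries] == [e.score for e in b.entries]

    def test_score_nonnegative_and_monotone_in_n(self):
        lists = self._three_lists()
        prev = {p: 0.0 for p in "ABCDE"}
        for N in (1, 2, 3, 4, 5):
            agg = aggregate_rankings(lists, N=N)
            for e in agg.entries:
                assert e.score >= 0.0
                assert e.score >= prev[e.probe_id] - 1e-12
                prev[e.probe_id] = e.score

    def test_score_monotone_in_weight(self):
        ranks = np.array([1.0, 3.0, 2.0])
        w = np.array([2.0, 1.0, 0.5])
        base = composite_score(ranks, w, N=2)
        bumped = composite_score(ranks, w + np.array([1.0, 0.0, 0.0]), N=2)
        assert bumped > base

    def test_p_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_rankings(self._three_lists(), N=2, p=5)

    def test_n_exceeding_list_length(self):
        with pytest.raises(ConfigError):
            aggregate_rankings(self._three_lists(), N=6)

    def test_empty_lists(self):
        with pytest.raises(DataError):
            aggregate_rankings([], N=1)

    def test_final_ranking_strict_total_order(self):
        agg = aggregate_rankings(self._three_lists(), N=2)
        ranks = [e.final_rank for e in agg.entries]
        assert ranks == list(range(1, 6))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_property_permutation_and_order_invariance(self, seed):
        local = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(6)]
        lists = []
        for _ in range(4):
            order = [genes[i] for i in local.permutation(6)]
            lists.append(build_list(order, local.uniform(0.1, 5.0, 6).tolist()))
        agg = aggregate_rankings(lists, N=3)
        assert sorted(agg.ordered_probes()) == sorted(genes)
        shuffled = [lists[i] for i in local.permutation(4)]
        agg2 = aggregate_rankings(shuffled, N=3)
        assert agg.ordered_probes() == agg2.ordered_probes()


class TestTopNOccurrence:
    def test_always_first(self):
        lists = [build_list(["A", "B", "C"], [3.0, 2.0, 1.0]) for _ in range(100)]
        assert top_n_occurrence(lists, "A", 10) == 100

    def test_never_in_top_n(self):
        lists = [build_list(["A", "B", "C"], [3.0, 2.0, 1.0]) for _ in range(5)]
        assert top_n_occurrence(lists, "C", 2) == 0

    def test_absent_gene_counts_zero(self):
        lists = [build_list(["A", "B"], [1.0, 0.5])]
        assert top_n_occurrence(lists, "Z", 2) == 0

    def test_occurrence_table_shape(self):
        lists = [build_list(["A", "B", "C"], [3.0, 2.0, 1.0])]
        table = occurrence_table(lists, ["A", "B", "C"], Ns=(1, 2))
        assert table["A"] == {1: 1, 2: 1}
        assert table["B"] == {1: 0, 2: 1}
        assert table["C"] == {1: 0, 2: 0}

    def test_planted_gene_ensemble_occurrence(self, rng):
        # one planted gene at 3 sigma among 100 nulls: occurrence >= 95/100
        y = np.array([1, 0] * 6)
        values = rng.normal(size=(101, 12))
        values[0, y == 1] += 3.0
        m = make_matrix(values)
        plan = make_cv_plan(12, 6, 100, seed=7)
        lists, _ = run_ensemble(m, y, plan)
        occ = top_n_occurrence(lists, "g001", 10)
        assert occ >= 95
        # stability: no null beats the planted gene, and the great majority
        # of nulls sit far below it (a few lucky nulls can tie at n=12)
        null_occ = np.array([top_n_occurrence(lists, p, 10) for p in m.probe_ids[1:]])
        assert occ >= null_occ.max()
        assert np.median(null_occ) < occ / 2
        from rfet.ensemble import aggregate_rankings as _agg

        assert _agg(lists, N=10).final_ranks()["g001"] == 1
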