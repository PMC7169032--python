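import math

import numpy as np
import pandas as pd
import pytest

from recruitcbr import (
    RankedList,
    auc_quality_label,
    average_precision,
    bootstrap_ci,
    evaluate_ranked_list,
    optimal_cutoff,
    precision_at_k,
    rank_people,
    reciprocal_rank,
    reference_bounds,
    roc_auc,
    top_k_overlap,
)
from recruitcbr.evaluation import cutoff_sweep


def auc_oracle(scores, labels):
    """All-pairs count: 1 per win, 0.5 per tie."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ranked(relevance, db=None, scores=None):
    n = len(relevance)
    scores = np.linspace(1, 0, n) if scores is None else np.asarray(scores)
    db = np.zeros(n, dtype=int) if db is None else np.asarray(db)
    return RankedList(
        person_ids=np.array([f"p{i}" for i in range(n)]),
        scores=scores,
        relevance=np.asarray(relevance),
        db_flags=db,
    )


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(41)
        for _ in range(60):
            n = int(rng.integers(3, 40))
            scores = rng.integers(0, 6, n) / 5.0  # coarse grid forces ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.all():
                labels[0] = 0
            assert roc_auc(scores, labels) == auc_oracle(scores, labels)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(43)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_strictly_increasing_transforms(self):
        rng = np.random.default_rng(47)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3.0 * scores + 7.0, labels) == pytest.approx(base, abs=1e-12)


class TestQualityBands:
    @pytest.mark.parametrize(
        "auc,label",
        [
            (0.95, "excellent"),
            (0.90, "excellent"),
            (0.815, "good"),
            (0.75, "fair"),
            (0.65, "poor"),
            (0.55, "fail"),
            (0.337, "worse_than_random"),
        ],
    )
    def test_band_assignment(self, auc, label):
        assert auc_quality_label(auc) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_quality_label(1.2)


class TestBootstrapCI:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(51)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a = bootstrap_ci(scores, labels, n_replicates=300, seed=5)
        b = bootstrap_ci(scores, labels, n_replicates=300, seed=5)
        assert a == b

    def test_perfect_separation_collapses_to_one(self):
        scores = np.concatenate([np.linspace(0.6, 1, 40), np.linspace(0, 0.4, 60)])
        labels = np.array([1] * 40 + [0] * 60)
        lo, hi = bootstrap_ci(scores, labels, n_replicates=200, seed=1)
        assert lo == hi == 1.0

    def test_single_positive_gives_na_marker(self):
        scores = [0.9, 0.2, 0.3, 0.4]
        lo, hi = bootstrap_ci(scores, [1, 0, 0, 0], seed=0)
        assert math.isnan(lo) and math.isnan(hi)

    def test_interval_brackets_the_point_estimate(self):
        rng = np.random.default_rng(53)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 70)])
        labels = np.array([1] * 30 + [0] * 70)
        auc = roc_auc(scores, labels)
        lo, hi = bootstrap_ci(scores, labels, n_replicates=500, seed=2)
        assert lo <= auc <= hi

    def test_non_stratified_option(self):
        rng = np.random.default_rng(57)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        lo, hi = bootstrap_ci(
            scores, labels, n_replicates=200, seed=3, stratified=False
        )
        assert 0.0 <= lo <= hi <= 1.0


class TestOptimalCutoff:
    def test_clean_gap_takes_smallest_grid_maximizer(self):
        cutoff, metric = optimal_cutoff([0.9, 0.1], [1, 0])
        assert cutoff == pytest.approx(0.11)
        assert metric == 1.0

    def test_full_separation_attains_one(self):
        scores = np.concatenate([np.linspace(0.7, 1, 20), np.linspace(0, 0.3, 30)])
        labels = np.array([1] * 20 + [0] * 30)
        _, metric = optimal_cutoff(scores, labels)
        assert metric == 1.0

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(61)
        scores = rng.random(400)
        maxima = []
        for _ in range(50):
            labels = np.zeros(400, dtype=int)
            labels[rng.choice(400, 200, replace=False)] = 1
            maxima.append(optimal_cutoff(scores, labels)[1])
        assert np.mean(maxima) == pytest.approx(0.5, abs=0.05)

    def test_sweep_covers_unit_grid(self):
        sweep = cutoff_sweep([0.2, 0.8], [0, 1], grid_step=0.01)
        assert len(sweep) == 101
        assert sweep["threshold"].iloc[0] == 0.0
        assert sweep["threshold"].iloc[-1] == 1.0
        assert sweep["metric"].between(0, 1).all()


class TestRankingMetrics:
    def test_precision_at_k_counts_relevant(self):
        r = ranked([1, 0, 1, 0, 0, 0, 0, 0, 0, 0])
        assert precision_at_k(r, 5) == pytest.approx(0.4)
        assert precision_at_k(r, 10) == pytest.approx(0.2)

    def test_no_relevant_in_top_k(self):
        r = ranked([0] * 10 + [1])
        assert precision_at_k(r, 5) == 0.0
        assert precision_at_k(r, 10) == 0.0

    def test_short_list_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            precision_at_k(ranked([1, 0, 1]), 5)

    def test_average_precision_hand_computed(self):
        r = ranked([1, 0, 1] + [0] * 17)
        assert average_precision(r) == pytest.approx((1 + 2 / 3) / 2)

    def test_average_precision_upper_bound(self):
        r = ranked([1] * 4 + [0] * 16)
        assert average_precision(r) == 1.0

    def test_single_relevant_at_rank_n(self):
        r = ranked([0] * 19 + [1])
        assert average_precision(r) == pytest.approx(1 / 20)
        assert reciprocal_rank(r) == pytest.approx(1 / 20)

    def test_reciprocal_rank_of_first_relevant(self):
        assert reciprocal_rank(ranked([0, 0, 0, 1, 1])) == 0.25
        assert reciprocal_rank(ranked([1, 0, 0, 0, 0])) == 1.0
        assert reciprocal_rank(ranked([0, 1, 0, 0, 0, 0, 1, 0, 0, 1])) == 0.5

    def test_zero_relevant_rejected(self):
        with pytest.raises(ValueError):
            average_precision(ranked([0] * 5))
        with pytest.raises(ValueError):
            reciprocal_rank(ranked([0] * 5))

    def test_metrics_never_exceed_upper_reference(self):
        rng = np.random.default_rng(67)
        for _ in range(40):
            n = int(rng.integers(12, 60))
            rel = np.zeros(n, dtype=int)
            k = int(rng.integers(1, min(n, 9)))
            rel[rng.choice(n, k, replace=False)] = 1
            r = ranked(rel)
            refs = reference_bounds(k, n, seed=0)
            assert precision_at_k(r, 5) <= refs["upper_p5"] + 1e-12
            assert precision_at_k(r, 10) <= refs["upper_p10"] + 1e-12
            assert average_precision(r) <= refs["upper_map"] + 1e-12
            assert reciprocal_rank(r) <= refs["upper_mrr"] + 1e-12


class TestReferenceBounds:
    def test_upper_closed_forms(self):
        refs = reference_bounds(7, 1000, seed=0)
        assert refs["upper_p5"] == 1.0
        assert refs["upper_p10"] == pytest.approx(0.7)
        assert refs["upper_map"] == 1.0
        assert refs["upper_mrr"] == 1.0
        assert reference_bounds(2, 1000, seed=0)["upper_p5"] == pytest.approx(0.4)

    def test_lower_is_seeded_and_deterministic(self):
        a = reference_bounds(5, 500, seed=9)
        b = reference_bounds(5, 500, seed=9)
        assert a == b

    def test_random_list_on_huge_pool_has_zero_p5(self):
        refs = reference_bounds(7, 30_007, seed=12)
        assert refs["lower_p5"] == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            reference_bounds(0, 10)
        with pytest.raises(ValueError):
            reference_bounds(11, 10)


class TestTopKOverlapAndRanking:
    def test_overlap_counts_db_flags_in_top_k(self):
        db = np.zeros(60, dtype=int)
        db[:33] = 1
        r = ranked([0] * 60, db=db)
        assert top_k_overlap(r, 50) == pytest.approx(0.66)
        assert top_k_overlap(ranked([0] * 50, db=np.ones(50, dtype=int))) == 1.0
        assert top_k_overlap(ranked([0] * 50)) == 0.0

    def test_metrics_invariant_below_rank_k(self):
        rng = np.random.default_rng(71)
        rel = np.zeros(100, dtype=int)
        rel[[2, 7]] = 1
        db = rng.integers(0, 2, 100)
        r1 = ranked(rel, db=db)
        # reshuffle everything below rank 50
        tail = np.arange(50, 100)
        perm = np.concatenate([np.arange(50), rng.permutation(tail)])
        r2 = RankedList(
            person_ids=r1.person_ids[perm],
            scores=np.linspace(1, 0, 100),
            relevance=rel[perm],
            db_flags=db[perm],
        )
        assert top_k_overlap(r1, 50) == top_k_overlap(r2, 50)
        assert precision_at_k(r1, 10) == precision_at_k(r2, 10)

    def test_rank_people_breaks_ties_by_seed_not_input_order(self):
        scores = np.array([0.5] * 6 + [0.9])
        ids = np.array([f"p{i}" for i in range(7)])
        rel = np.array([0] * 7)
        a = rank_people(ids, scores, rel, rel, tie_seed=1)
        b = rank_people(ids, scores, rel, rel, tie_seed=1)
        c = rank_people(ids, scores, rel, rel, tie_seed=2)
        assert a.person_ids[0] == "p6"  # top score always first
        assert (a.person_ids == b.person_ids).all()
        assert not (a.person_ids == c.person_ids).all()

    def test_ranked_list_validates_ordering_and_uniqueness(self):
        with pytest.raises(ValueError, match="non-increasing"):
            RankedList(
                person_ids=np.array(["a", "b"]),
                scores=np.array([0.1, 0.9]),
                relevance=np.array([0, 1]),
                db_flags=np.array([0, 0]),
            )
        with pytest.raises(ValueError, match="exactly once"):
            RankedList(
                person_ids=np.array(["a", "a"]),
                scores=np.array([0.9, 0.1]),
                relevance=np.array([0, 1]),
                db_flags=np.array([0, 0]),
            )


def test_evaluate_ranked_list_is_self_consistent():
    rng = np.random.default_rng(73)
    n = 400
    scores = np.sort(rng.random(n))[::-1]
    rel = np.zeros(n, dtype=int)
    rel[rng.choice(n, 6, replace=False)] = 1
    db = rng.integers(0, 2, n)
    r = RankedList(
        person_ids=np.array([f"p{i}" for i in range(n)]),
        scores=scores, relevance=rel, db_flags=db,
    )
    ev = evaluate_ranked_list(r, n_bootstrap=100, seed=3)
    assert ev.roc_auc == roc_auc(scores, rel)
    assert ev.p5 == precision_at_k(r, 5)
    assert ev.map == average_precision(r)
    assert ev.mrr == reciprocal_rank(r)
    assert ev.top50_overlap == top_k_overlap(r, 50)
    assert ev.n_test == n and ev.n_relevant == 6
    assert ev.auc_quality == auc_quality_label(ev.roc_auc)
    assert ev.upper_map == 1.0 and ev.upper_mrr == 1.0
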