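import numpy as np
import pytest

from mdgcn import (
    AssociationMatrix,
    FoldReport,
    aggregate,
    compute_metrics,
    make_folds,
    rank_candidates,
)


def _assoc(values):
    values = np.asarray(values)
    return AssociationMatrix(
        mirna_ids=tuple(f"m{i}" for i in range(values.shape[0])),
        disease_ids=tuple(f"d{j}" for j in range(values.shape[1])),
        values=values,
    )


def brute_force_auc(scores, labels):
    """Concordant-pair counting oracle with half-credit for ties."""
    scores = np.asarray(scores)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# --------------------------------------------------------------- folds


def test_fold_sizes_partition_positives(tiny_data):
    a = tiny_data.assoc
    folds = make_folds(a, 4, seed=0)
    test_sets = [set(map(tuple, f.test_pos)) for f in folds]
    all_pos = set(map(tuple, a.positive_pairs()))
    assert set().union(*test_sets) == all_pos
    for i in range(len(test_sets)):
        for j in range(i + 1, len(test_sets)):
            assert not test_sets[i] & test_sets[j]


def test_balanced_negatives_disjoint_roles(tiny_data):
    for f in make_folds(tiny_data.assoc, 3, seed=1):
        assert len(f.train_neg) == len(f.train_pos)
        assert len(f.test_neg) == len(f.test_pos)
        negs = set(map(tuple, f.train_neg)) | set(map(tuple, f.test_neg))
        assert len(negs) == len(f.train_neg) + len(f.test_neg)
        # negatives are zero cells
        vals = tiny_data.assoc.values
        for m, d in negs:
            assert vals[m, d] == 0


def test_exact_division_on_benchmark_scale_counts():
    # 5430 positives split 5 ways -> five folds of 1086; 10 ways -> 543
    rng = np.random.default_rng(0)
    values = np.zeros((495, 383), dtype=np.int8)
    idx = rng.choice(495 * 383, size=5430, replace=False)
    values.flat[idx] = 1
    a = _assoc(values)
    assert sorted(len(f.test_pos) for f in make_folds(a, 5, seed=0)) == [1086] * 5
    assert sorted(len(f.test_pos) for f in make_folds(a, 10, seed=0)) == [543] * 10


def test_same_seed_reproduces_folds(tiny_data):
    f1 = make_folds(tiny_data.assoc, 3, seed=5)
    f2 = make_folds(tiny_data.assoc, 3, seed=5)
    for a, b in zip(f1, f2):
        assert np.array_equal(a.test_pos, b.test_pos)
        assert np.array_equal(a.train_neg, b.train_neg)


def test_too_many_folds_rejected():
    a = _assoc(np.eye(3, dtype=int))
    with pytest.raises(ValueError, match="folds"):
        make_folds(a, 5, seed=0)


# --------------------------------------------------------------- metrics


def test_perfect_separation():
    r = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert r.auc == 1.0 and r.aupr == 1.0 and r.f1 == 1.0


def test_hand_auc_three_quarters():
    r = compute_metrics([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
    assert r.auc == pytest.approx(0.75)


def test_confusion_matrix_closed_forms():
    # TP=3 FP=1 FN=1 TN=5 at threshold 0.5
    scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.2, 0.1, 0.1]
    labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    r = compute_metrics(scores, labels)
    assert r.precision == pytest.approx(0.75)
    assert r.recall == pytest.approx(0.75)
    assert r.f1 == pytest.approx(0.75)
    assert r.mcc == pytest.approx(14 / 24)  # (3*5-1*1)/sqrt(4*4*6*6)


def test_auc_equals_bruteforce_oracle_up_to_200_items():
    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(10, 201))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        r = compute_metrics(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels))


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        compute_metrics([0.1, 0.2], [1, 1])


# --------------------------------------------------------------- aggregation


def test_aggregate_single_report_sd_zero():
    r = FoldReport(auc=0.9, aupr=0.8, mcc=0.5, f1=0.7, precision=0.6, recall=0.7)
    s = aggregate([r])
    assert s.mean["auc"] == 0.9
    assert s.sd_population["auc"] == 0.0
    assert s.sd_sample["auc"] == 0.0


def test_aggregate_mean_recomputable_from_folds():
    rng = np.random.default_rng(9)
    reports = [
        FoldReport(*(rng.random(6))) for _ in range(5)
    ]
    s = aggregate(reports)
    assert s.mean["aupr"] == pytest.approx(np.mean([r.aupr for r in reports]))


# --------------------------------------------------------------- ranking


def test_rank_candidates_sorted_and_thresholded():
    a = _assoc(np.zeros((2, 3), dtype=int))
    scores = np.array([[0.9, 0.2, 0.6], [0.1, 0.8, 0.3]])
    ranked = rank_candidates(scores, a, "m0", ["d0", "d1", "d2"])
    assert [r["id"] for r in ranked] == ["d0", "d2", "d1"]
    assert [r["predicted"] for r in ranked] == [1, 1, 0]


def test_rank_candidates_disease_anchor_and_topk():
    a = _assoc(np.zeros((2, 3), dtype=int))
    scores = np.array([[0.9, 0.2, 0.6], [0.1, 0.8, 0.3]])
    ranked = rank_candidates(scores, a, "d1", ["m0", "m1"], top_k=1)
    assert ranked == [{"id": "m1", "score": 0.8, "predicted": 1}]
    assert rank_candidates(scores, a, "d1", ["m0"], top_k=0) == []


def test_rank_candidates_order_invariant_with_ties():
    a = _assoc(np.zeros((1, 3), dtype=int))
    scores = np.array([[0.5, 0.5, 0.5]])
    r1 = rank_candidates(scores, a, "m0", ["d2", "d0", "d1"])
    r2 = rank_candidates(scores, a, "m0", ["d0", "d1", "d2"])
    assert [x["id"] for x in r1] == [x["id"] for x in r2] == ["d0", "d1", "d2"]


def test_unknown_anchor_rejected():
    a = _assoc(np.zeros((1, 1), dtype=int))
    with pytest.raises(KeyError):
        rank_candidates(np.zeros((1, 1)), a, "nope", ["d0"])
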