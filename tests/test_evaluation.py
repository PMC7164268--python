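"""Confusion counts, ROC/PR curves, and AUC against independent oracles."""

import numpy as np
import pytest
from scipy import stats as scipy_stats
from sklearn import metrics as sk_metrics

from seres import (
    MultipleAlignment,
    ResiduePair,
    SupportAnnotation,
    aggregate_auc,
    confusion_counts,
    pr_auc,
    pr_points,
    roc_auc,
    roc_points,
)
from seres.evaluation import (
    pr_auc_from_points,
    pr_points_from_scores,
    roc_auc_from_points,
    roc_points_from_scores,
)


def annotation(scores):
    return SupportAnnotation(dict(scores), n_replicates=10)


@pytest.fixture
def toy_case():
    """true pairs {(1,0),(2,1),(3,2)}; est pairs {(0,0) FP, (2,1) TP,
    (3,2) TP}; the true pair (1,0) is absent from est and out of scope."""
    true_msa = MultipleAlignment(["a", "b"], ["ACGT-", "-ACGT"])
    est_msa = MultipleAlignment(["a", "b"], ["ACGT-", "A-CGT"])
    return true_msa, est_msa


def test_scope_rule_and_threshold_counts(toy_case):
    true_msa, est_msa = toy_case
    ann = annotation({
        ResiduePair("a", 0, "b", 0): 0.8,   # FP
        ResiduePair("a", 2, "b", 1): 0.9,   # TP
        ResiduePair("a", 3, "b", 2): 0.4,   # true, called negative -> FN
    })
    c = confusion_counts(true_msa, est_msa, ann, threshold=0.5)
    assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 0)


def test_threshold_zero_calls_everything_positive(toy_case):
    true_msa, est_msa = toy_case
    ann = annotation({
        ResiduePair("a", 0, "b", 0): 0.8,
        ResiduePair("a", 2, "b", 1): 0.9,
        ResiduePair("a", 3, "b", 2): 0.4,
    })
    c = confusion_counts(true_msa, est_msa, ann, threshold=0.0)
    assert c.fn == 0 and c.tn == 0


def test_perfect_estimate_has_no_errors():
    msa = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
    ann = annotation({
        ResiduePair("a", i, "b", i): 1.0 for i in range(4)
    })
    for t in (0.0, 0.5, 1.0):
        c = confusion_counts(msa, msa, ann, threshold=t)
        assert (c.fp, c.fn, c.tn) == (0, 0, 0)


def test_missing_score_rejected(toy_case):
    true_msa, est_msa = toy_case
    with pytest.raises(ValueError):
        confusion_counts(true_msa, est_msa, annotation({}), 0.5)


def test_class_totals_threshold_invariant(toy_case):
    true_msa, est_msa = toy_case
    ann = annotation({
        ResiduePair("a", 0, "b", 0): 0.8,
        ResiduePair("a", 2, "b", 1): 0.9,
        ResiduePair("a", 3, "b", 2): 0.4,
    })
    totals = {
        (c.tp + c.fn, c.fp + c.tn)
        for c in (
            confusion_counts(true_msa, est_msa, ann, t)
            for t in (0.0, 0.3, 0.6, 1.0)
        )
    }
    assert totals == {(2, 1)}


def brute_force_points(labels, values):
    roc, pr = [], []
    for t in [np.inf] + sorted(set(values), reverse=True):
        tp = sum(l and v >= t for l, v in zip(labels, values))
        fp = sum((not l) and v >= t for l, v in zip(labels, values))
        fn = sum(l and v < t for l, v in zip(labels, values))
        tn = sum((not l) and v < t for l, v in zip(labels, values))
        roc.append((fp / (fp + tn) if fp + tn else 0.0,
                    tp / (tp + fn) if tp + fn else 0.0))
        pr.append((tp / (tp + fn) if tp + fn else 0.0,
                   tp / (tp + fp) if tp + fp else 1.0))
    return roc, pr


class TestCurves:
    def test_points_match_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 30))
            labels = [bool(b) for b in rng.integers(2, size=n)]
            if not (any(labels) and not all(labels)):
                continue
            values = [float(v) for v in rng.choice(
                [0.0, 0.2, 0.4, 0.5, 0.8, 1.0], size=n)]
            roc_bf, pr_bf = brute_force_points(labels, values)
            assert roc_points_from_scores(labels, values) == pytest.approx(roc_bf)
            assert pr_points_from_scores(labels, values) == pytest.approx(pr_bf)

    def test_perfect_separation_passes_through_0_1(self):
        labels = [True] * 3 + [False] * 3
        values = [0.9, 0.8, 0.7, 0.2, 0.1, 0.0]
        assert (0.0, 1.0) in roc_points_from_scores(labels, values)

    def test_constant_scores_single_nontrivial_point(self):
        pts = roc_points_from_scores([True, False, True], [0.5, 0.5, 0.5])
        assert pts == [(0.0, 0.0), (1.0, 1.0)]


class TestAuc:
    def test_perfect_classifier_auc_one(self):
        labels = [True, True, False, False]
        values = [0.9, 0.8, 0.2, 0.1]
        pts = roc_points_from_scores(labels, values)
        assert roc_auc_from_points(pts) == pytest.approx(1.0)

    def test_four_point_hand_geometry(self):
        # trapezoids: (0,0)->(0,0.5)->(0.5,1)->(1,1)
        pts = [(0.0, 0.0), (0.0, 0.5), (0.5, 1.0), (1.0, 1.0)]
        assert roc_auc_from_points(pts) == pytest.approx(
            0.5 * (0.5 + 1.0) / 2 + 0.5 * 1.0
        )

    def test_random_scores_near_half(self, rng):
        labels = [bool(b) for b in rng.integers(2, size=4000)]
        values = list(rng.random(4000))
        pts = roc_points_from_scores(labels, values)
        assert roc_auc_from_points(pts) == pytest.approx(0.5, abs=0.05)

    def test_roc_auc_equals_normalized_mann_whitney(self, rng):
        """ROC-AUC must equal U / (n_pos * n_neg), the probability a random
        positive outscores a random negative (ties counted half)."""
        for _ in range(10):
            n = int(rng.integers(10, 60))
            labels = np.array([bool(b) for b in rng.integers(2, size=n)])
            if labels.all() or not labels.any():
                continue
            values = rng.choice(np.linspace(0, 1, 7), size=n)
            pts = roc_points_from_scores(labels, values)
            pos, neg = values[labels], values[~labels]
            u = scipy_stats.mannwhitneyu(pos, neg, alternative="two-sided")
            expected = u.statistic / (len(pos) * len(neg))
            assert roc_auc_from_points(pts) == pytest.approx(expected)

    def test_matches_sklearn(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            labels = np.array([bool(b) for b in rng.integers(2, size=n)])
            if labels.all() or not labels.any():
                continue
            values = rng.random(n)
            pts = roc_points_from_scores(labels, values)
            assert roc_auc_from_points(pts) == pytest.approx(
                sk_metrics.roc_auc_score(labels, values)
            )
            pr_pts = pr_points_from_scores(labels, values)
            assert pr_auc_from_points(pr_pts) == pytest.approx(
                sk_metrics.average_precision_score(labels, values)
            )

    def test_monotone_transform_invariance(self, rng):
        labels = [bool(b) for b in rng.integers(2, size=50)]
        values = list(rng.random(50))
        pts1 = roc_points_from_scores(labels, values)
        pts2 = roc_points_from_scores(labels, [v**3 + 1 for v in values])
        assert pts1 == pytest.approx(pts2)


def test_aggregate_modes_differ_but_agree_on_single_dataset(toy_case):
    true_msa, est_msa = toy_case
    ann = annotation({
        ResiduePair("a", 0, "b", 0): 0.3,
        ResiduePair("a", 2, "b", 1): 0.9,
        ResiduePair("a", 3, "b", 2): 0.6,
    })
    data = [(true_msa, est_msa, ann)]
    assert aggregate_auc(data, "roc", "pooled") == pytest.approx(
        aggregate_auc(data, "roc", "mean")
    )
    assert aggregate_auc(data, "roc", "pooled") == pytest.approx(
        roc_auc(true_msa, est_msa, ann)
    )
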