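"""Metric formulas, ROC/AUC against a pairwise oracle, cross-validation."""

import itertools
import math

import numpy as np
import pytest

from glutsite.dataset import LabeledDataset
from glutsite.evaluation import (
    ConfusionCounts,
    compute_metrics,
    cross_validate,
    evaluate_predictions,
    roc_auc,
)
from glutsite.model import ClassifierConfig


def _mannwhitney_auc(labels, scores):
    """Brute-force pairwise oracle: P(random positive outscores random negative)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
        assert (r.acc, r.sn, r.sp, r.mcc, r.f1) == (100.0, 100.0, 100.0, 1.0, 1.0)

    def test_hand_computed_table(self):
        r = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert r.acc == pytest.approx(80.0)
        assert r.sn == pytest.approx(75.0)
        assert r.sp == pytest.approx(83.333333, abs=1e-5)
        assert r.mcc == pytest.approx(14 / 24, abs=1e-9)
        assert r.f1 == pytest.approx(0.75)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="no positive"):
            compute_metrics(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        with pytest.raises(ValueError, match="no negative"):
            compute_metrics(ConfusionCounts(tp=2, fp=0, tn=0, fn=1))

    def test_exhaustive_equivalence_with_error_rate_forms(self):
        """The complement ('1 - error') metric forms and the MCC/F1 edge rules
        agree with the implementation on every table with counts 0..15."""
        for tp, fp, tn, fn in itertools.product(range(16), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue
            r = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            n = tp + fp + tn + fn
            assert r.acc == pytest.approx((1 - (fn + fp) / n) * 100)
            assert r.sn == pytest.approx((1 - fn / (tp + fn)) * 100)
            assert r.sp == pytest.approx((1 - fp / (tn + fp)) * 100)
            # MCC bounds and attainment conditions
            assert -1 - 1e-12 <= r.mcc <= 1 + 1e-12
            if fp == 0 and fn == 0:
                assert r.mcc == pytest.approx(1.0)
            if tp == 0 and tn == 0:
                assert r.mcc == pytest.approx(-1.0)
            # F1 from precision/recall with the zero rule
            pr = tp / (tp + fp) if tp + fp else 0.0
            re = tp / (tp + fn)
            f1 = 2 * pr * re / (pr + re) if pr + re else 0.0
            assert r.f1 == pytest.approx(f1)

    def test_scale_invariance_under_sample_duplication(self):
        a = compute_metrics(ConfusionCounts(tp=3, fp=2, tn=7, fn=1))
        b = compute_metrics(ConfusionCounts(tp=6, fp=4, tn=14, fn=2))
        assert (a.acc, a.sn, a.sp, a.mcc, a.f1) == pytest.approx(
            (b.acc, b.sn, b.sp, b.mcc, b.f1)
        )


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_inverted_scores(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert auc == 0.0

    def test_three_of_four_pairs(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert auc == pytest.approx(0.75)

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.4, 0.5])

    def test_curve_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        points, _ = roc_auc(labels, scores)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        fpr, tpr = zip(*points)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            _, auc = roc_auc(labels, scores)
            assert abs(auc - _mannwhitney_auc(labels, scores)) < 1e-12


class TestCrossValidate:
    def _toy(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 6))
        y = np.array([1, 0] * (n // 2))
        x[y == 1, 0] += 5.0
        return LabeledDataset(
            features=x, labels=y, provenance=tuple(f"T{i}|{i + 1}" for i in range(n))
        )

    def test_two_folds_pool_all_samples(self):
        data = self._toy(n=10)
        report = cross_validate(data, k=2, seed=0, scalars=())
        c = report.counts
        assert c.tp + c.fp + c.tn + c.fn == 10
        assert len(report.fold_accuracies) == 2

    def test_strong_signal_high_pooled_accuracy(self, strong_signal_dataset):
        report = cross_validate(strong_signal_dataset, k=5, seed=0)
        assert report.acc >= 85.0
        assert report.auc >= 0.9

    def test_deterministic_for_fixed_seed(self):
        data = self._toy(n=20, seed=3)
        a = cross_validate(data, k=4, seed=9)
        b = cross_validate(data, k=4, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_class_smaller_than_k_raises(self):
        data = self._toy(n=10)
        with pytest.raises(ValueError, match="class"):
            cross_validate(data, k=8, seed=0)

    def test_label_shuffled_auc_near_half(self):
        """With labels shuffled, held-out performance collapses to chance."""
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = self._toy(n=40, seed=seed)
            shuffled = LabeledDataset(
                features=data.features,
                labels=rng.permutation(data.labels),
                provenance=data.provenance,
            )
            aucs.append(cross_validate(shuffled, k=4, seed=seed, scalars=()).auc)
        mean = float(np.mean(aucs))
        half_width = 1.96 * float(np.std(aucs, ddof=1)) / math.sqrt(len(aucs))
        assert mean - half_width <= 0.5 <= mean + half_width


def test_evaluate_predictions_attaches_roc():
    y = np.array([1, 1, 0, 0, 1, 0])
    pred = np.array([1, 0, 0, 0, 1, 1])
    scores = np.array([0.9, 0.4, 0.2, 0.1, 0.8, 0.6])
    report = evaluate_predictions(y, pred, scores)
    assert report.auc is not None
    assert report.counts.tp == 2 and report.counts.fn == 1


def test_report_json_and_roc_csv(tmp_path):
    report = evaluate_predictions(
        np.array([1, 0, 1, 0]), np.array([1, 0, 0, 0]), np.array([0.9, 0.1, 0.4, 0.3])
    )
    report.write_json(tmp_path / "report.json")
    report.write_roc_csv(tmp_path / "roc.csv")
    import json

    loaded = json.loads((tmp_path / "report.json").read_text())
    assert loaded["counts"] == {"tp": 1, "fp": 0, "tn": 2, "fn": 1}
    assert (tmp_path / "roc.csv").read_text().startswith("fpr,tpr")
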