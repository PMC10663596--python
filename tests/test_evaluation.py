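"""Metrics, fold bookkeeping and the cross-validation harness."""

import numpy as np
import pandas as pd
import pytest

from dwianomaly.evaluation import (
    FoldSplit,
    MetricReport,
    crossvalidate,
    dice,
    roc_auc,
    score_density,
    score_subject,
)
from dwianomaly.io import AnomalyMap, BinaryLesionMask, EvaluationMask


def mann_whitney_auc(scores, labels):
    """O(n²) pairwise-comparison oracle for the AUC."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestDice:
    def test_identical_nonempty(self, rng):
        a = rng.uniform(size=(5, 5, 5)) > 0.5
        assert dice(a, a) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.flat[:100] = True
        b.flat[50:150] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_restricted_to_eval_mask(self):
        a = np.ones((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        b[:2] = True
        mask = EvaluationMask(voxels=b.copy())  # evaluation confined to b's region
        assert dice(a, b, mask) == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.linspace(0, 1, 64).reshape(4, 4, 4)
        labels = scores > 0.7
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_all_tied_scores_half(self):
        scores = np.full((4, 4, 4), 0.5)
        labels = np.zeros((4, 4, 4), bool)
        labels[0] = True
        _, auc = roc_auc(scores, labels)
        assert auc == 0.5

    def test_matches_pairwise_oracle(self, rng):
        scores = np.round(rng.uniform(size=(3, 5, 2)), 1)  # ties on purpose
        labels = rng.uniform(size=(3, 5, 2)) > 0.6
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(
            mann_whitney_auc(scores.ravel(), labels.ravel()), abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=(4, 4, 4))
        labels = rng.uniform(size=(4, 4, 4)) > 0.5
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_error_names_subject(self):
        scores = np.zeros((3, 3, 3))
        labels = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError, match="subj-x"):
            roc_auc(scores, labels, subject_id="subj-x")


class TestScoreDensity:
    def test_densities_integrate_to_one(self, rng):
        amap = AnomalyMap(scores=rng.uniform(size=(8, 8, 8)))
        gt = rng.uniform(size=(8, 8, 8)) > 0.8
        out = score_density([amap], [gt])
        widths = np.diff(out["edges"])
        assert (out["healthy_density"] * widths).sum() == pytest.approx(1.0)
        assert (out["lesion_density"] * widths).sum() == pytest.approx(1.0)

    def test_separated_model_has_positive_separation(self):
        scores = np.zeros((6, 6, 6))
        gt = np.zeros((6, 6, 6), bool)
        gt[2:4] = True
        scores[gt] = 0.9
        out = score_density([AnomalyMap(scores=scores)], [gt])
        assert out["separation"] == pytest.approx(0.9)

    def test_random_scores_near_zero_separation(self, rng):
        amap = AnomalyMap(scores=rng.uniform(size=(12, 12, 12)))
        gt = rng.uniform(size=(12, 12, 12)) > 0.5
        out = score_density([amap], [gt])
        assert abs(out["separation"]) < 0.05


class TestFoldSplit:
    def test_28_subjects_7_folds_of_4(self):
        split = FoldSplit(n_subjects=28, n_folds=7, seed=0)
        sizes = np.bincount(split.assignments, minlength=7)
        assert (sizes == 4).all()

    def test_each_subject_validated_exactly_once(self):
        split = FoldSplit(n_subjects=28, n_folds=7, seed=1)
        seen = np.concatenate([val for _, val in split])
        assert sorted(seen) == list(range(28))
        for train, val in split:
            assert set(train) | set(val) == set(range(28))
            assert not set(train) & set(val)

    def test_seed_determinism(self):
        a = FoldSplit(10, 5, seed=3)
        b = FoldSplit(10, 5, seed=3)
        c = FoldSplit(10, 5, seed=4)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert not np.array_equal(a.assignments, c.assignments)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            FoldSplit(n_subjects=5, n_folds=7)


class _StubScorer:
    """Deterministic pseudo-model: anomaly score from a hash of the position."""

    def fit(self, X, y=None, validation=None):
        self.fitted_ = True
        return self

    def anomaly_map(self, vol):
        rng = np.random.default_rng(abs(hash(vol.subject_id)) % 2**31)
        scores = rng.uniform(size=vol.signal.shape[:3])
        return AnomalyMap(scores=scores, score_range=(0.0, 1.0), source_model="stub")


class TestCrossValidation:
    def test_bookkeeping_and_recomputable_aggregates(self, tiny_cohort, tiny_lesioned):
        cohort = tiny_cohort + tiny_cohort[:1]  # 7 subjects for 7 folds
        report = crossvalidate(
            cohort, _StubScorer, tiny_lesioned, n_folds=7, seed=0,
            threshold_method="fixed", pool_kernel=4,
        )
        assert len(report.table) == 7 * len(tiny_lesioned)
        assert sorted(report.table["fold"].unique()) == list(range(7))
        agg = report.aggregate()
        for col in agg.columns:
            assert agg.loc["mean", col] == pytest.approx(report.table[col].mean())
            assert agg.loc["std", col] == pytest.approx(report.table[col].std(ddof=0))

    def test_score_subject_pipeline_columns(self, tiny_lesioned):
        vol, gt = tiny_lesioned[0]
        row = score_subject(_StubScorer(), vol, gt, threshold_method="otsu")
        assert set(row) >= {"subject", "threshold", "dice_raw", "dice_post", "auc"}
        assert 0 <= row["dice_raw"] <= 1
        assert 0 <= row["auc"] <= 1

    def test_supervised_method_in_pipeline(self, tiny_lesioned):
        vol, gt = tiny_lesioned[0]
        row_youden = score_subject(_StubScorer(), vol, gt, threshold_method="youden")
        assert np.isfinite(row_youden["threshold"])

    def test_format_summary_mentions_all_metrics(self, tiny_cohort, tiny_lesioned):
        report = crossvalidate(
            tiny_cohort + tiny_cohort[:1], _StubScorer, tiny_lesioned[:1],
            n_folds=7, seed=0, threshold_method="fixed",
        )
        text = report.format_summary()
        assert "auc" in text and "±" in text
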