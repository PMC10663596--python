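"""Threshold strategies against brute-force oracles; binarization; morphology."""

import numpy as np
import pytest
from scipy import ndimage

from dwianomaly.io import AnomalyMap, BinaryLesionMask, EvaluationMask
from dwianomaly.thresholding import (
    binarize,
    dice_optimal_threshold,
    fixed_threshold,
    morphological_opening,
    otsu_threshold,
    pooled_max_threshold,
    select_threshold,
    youden_threshold,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_otsu(values, n_bins):
    """Exhaustive between-class-variance maximization over histogram cuts."""
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    best_var, best_edge = -1.0, None
    for cut in range(1, n_bins):
        w0, w1 = counts[:cut].sum(), counts[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        centers = (edges[:-1] + edges[1:]) / 2
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_edge = var, edges[cut]
    return best_edge


def brute_pooled_max(volume, k):
    best = -np.inf
    for i in range(volume.shape[0] - k + 1):
        for j in range(volume.shape[1] - k + 1):
            for l in range(volume.shape[2] - k + 1):
                best = max(best, volume[i : i + k, j : j + k, l : l + k].mean())
    return best


def brute_best_threshold(scores, labels, objective):
    """Exhaustive scan of all cuts (midpoints between sorted unique scores)."""
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2])
    best_val, best_t = -np.inf, None
    for t in cands:
        pred = scores > t
        val = objective(pred, labels)
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return best_t, best_val


def youden_objective(pred, labels):
    tp = (pred & labels).sum()
    fp = (pred & ~labels).sum()
    return tp / labels.sum() - fp / (~labels).sum()


def dice_objective(pred, labels):
    denom = pred.sum() + labels.sum()
    return 2 * (pred & labels).sum() / denom if denom else 1.0


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestFixedThreshold:
    @pytest.mark.parametrize("kind,expected", [("recdisc", 0.5), ("dae", 0.3)])
    def test_model_defaults(self, kind, expected):
        assert fixed_threshold(kind) == expected

    def test_override_passes_through(self):
        assert fixed_threshold("dae", override=0.42) == 0.42

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fixed_threshold("unknown-model")


class TestOtsu:
    def test_separates_bimodal_sample(self):
        scores = np.concatenate([np.full(100, 0.1), np.full(100, 0.9)])
        t = otsu_threshold(scores, n_bins=64)
        assert 0.1 < t < 0.9

    def test_matches_bruteforce_scan(self, rng):
        scores = rng.uniform(size=64)
        assert otsu_threshold(scores, n_bins=32) == pytest.approx(
            brute_otsu(scores, 32), abs=1e-12
        )

    def test_translation_covariance(self, rng):
        scores = rng.normal(size=500)
        t0 = otsu_threshold(scores, n_bins=128)
        t1 = otsu_threshold(scores + 2.5, n_bins=128)
        bin_width = (scores.max() - scores.min()) / 128
        assert abs(t1 - (t0 + 2.5)) <= bin_width + 1e-9

    def test_agrees_with_skimage_within_bin_width(self, rng):
        from skimage.filters import threshold_otsu

        scores = rng.normal(size=2000)
        t = otsu_threshold(scores, n_bins=256)
        ref = threshold_otsu(scores, nbins=256)
        bin_width = (scores.max() - scores.min()) / 256
        assert abs(t - ref) <= bin_width + 1e-9

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(10, 0.5))


class TestPooledMax:
    def test_constant_map(self):
        amap = AnomalyMap(scores=np.full((8, 8, 8), 0.37))
        assert pooled_max_threshold(amap, kernel=4) == pytest.approx(0.37)

    def test_single_hot_voxel_k2(self):
        scores = np.zeros((6, 6, 6))
        scores[3, 3, 3] = 1.0
        assert pooled_max_threshold(AnomalyMap(scores=scores), kernel=2) == pytest.approx(1 / 8)

    def test_matches_bruteforce_sliding_window(self, rng):
        scores = rng.uniform(size=(9, 8, 7))
        amap = AnomalyMap(scores=scores)
        assert pooled_max_threshold(amap, kernel=4) == pytest.approx(
            brute_pooled_max(scores, 4), rel=1e-12
        )

    def test_bounds(self, rng):
        scores = rng.uniform(size=(8, 8, 8))
        t = pooled_max_threshold(AnomalyMap(scores=scores), kernel=3)
        assert t <= scores.max() + 1e-12
        assert t >= scores.mean() - 1e-12  # max window mean ≥ overall mean

    def test_map_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            pooled_max_threshold(AnomalyMap(scores=np.zeros((4, 4, 4))), kernel=8)


class TestSupervisedThresholds:
    def test_youden_perfect_separation_midpoint(self):
        scores = np.concatenate([np.full(10, 0.2), np.full(10, 0.8)])
        labels = np.concatenate([np.zeros(10, bool), np.ones(10, bool)])
        t = youden_threshold(scores, labels)
        assert t == pytest.approx(0.5)
        assert youden_objective(scores > t, labels) == pytest.approx(1.0)

    def test_youden_random_scores_near_zero_j(self, rng):
        scores = rng.uniform(size=5000)
        labels = rng.uniform(size=5000) > 0.5
        t = youden_threshold(scores, labels)
        assert abs(youden_objective(scores > t, labels)) < 0.1

    def test_youden_matches_exhaustive_scan(self, rng):
        for trial in range(5):
            scores = np.round(rng.uniform(size=20), 2)
            labels = rng.uniform(size=20) > 0.6
            if labels.all() or not labels.any():
                continue
            t = youden_threshold(scores, labels)
            t_ref, j_ref = brute_best_threshold(scores, labels, youden_objective)
            assert youden_objective(scores > t, labels) == pytest.approx(j_ref)

    def test_dice_optimal_perfect_separation(self):
        scores = np.concatenate([np.full(10, 0.1), np.full(5, 0.9)])
        labels = np.concatenate([np.zeros(10, bool), np.ones(5, bool)])
        t, d = dice_optimal_threshold(scores, labels)
        assert d == pytest.approx(1.0)
        assert dice_objective(scores > t, labels) == pytest.approx(1.0)

    def test_dice_optimal_matches_exhaustive_scan(self, rng):
        for trial in range(5):
            scores = np.round(rng.uniform(size=24), 2)
            labels = rng.uniform(size=24) > 0.5
            if labels.all() or not labels.any():
                continue
            t, d = dice_optimal_threshold(scores, labels)
            _, d_ref = brute_best_threshold(scores, labels, dice_objective)
            assert d == pytest.approx(d_ref)
            assert dice_objective(scores > t, labels) == pytest.approx(d_ref)

    def test_returned_dice_dominates_all_other_cuts(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.uniform(size=30) > 0.5
        t, d = dice_optimal_threshold(scores, labels)
        for other in np.linspace(-0.1, 1.1, 40):
            assert d >= dice_objective(scores > other, labels) - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            youden_threshold(np.arange(5.0), np.ones(5, bool))

    def test_supervised_dispatch_requires_groundtruth(self, rng):
        amap = AnomalyMap(scores=rng.uniform(size=(5, 5, 5)))
        with pytest.raises(ValueError, match="supervised"):
            select_threshold("youden", amap)


class TestBinarize:
    def _amap(self, rng):
        return AnomalyMap(scores=rng.uniform(size=(6, 6, 6)))

    def test_extremes(self, rng):
        amap = self._amap(rng)
        assert binarize(amap, 1.1).n_voxels == 0
        assert binarize(amap, -0.1).n_voxels == amap.scores.size

    def test_restricted_to_eval_mask(self, rng):
        amap = self._amap(rng)
        voxels = np.zeros((6, 6, 6), bool)
        voxels[:3] = True
        mask = EvaluationMask(voxels=voxels)
        out = binarize(amap, -1.0, mask)
        np.testing.assert_array_equal(out.voxels, voxels)

    def test_monotone_in_threshold(self, rng):
        amap = self._amap(rng)
        lo = binarize(amap, 0.3).voxels
        hi = binarize(amap, 0.6).voxels
        assert (hi <= lo).all()

    def test_strict_inequality(self):
        amap = AnomalyMap(scores=np.full((3, 3, 3), 0.5))
        assert binarize(amap, 0.5).n_voxels == 0


class TestMorphologicalOpening:
    def brute_open(self, voxels):
        """Direct erosion-then-dilation with the 3³ cube via shifts."""
        padded = np.pad(voxels, 1, constant_values=False)
        shifts = [
            padded[1 + dx : padded.shape[0] - 1 + dx,
                   1 + dy : padded.shape[1] - 1 + dy,
                   1 + dz : padded.shape[2] - 1 + dz]
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        ]
        eroded = np.logical_and.reduce(shifts)
        padded = np.pad(eroded, 1, constant_values=False)
        shifts = [
            padded[1 + dx : padded.shape[0] - 1 + dx,
                   1 + dy : padded.shape[1] - 1 + dy,
                   1 + dz : padded.shape[2] - 1 + dz]
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        ]
        return np.logical_or.reduce(shifts)

    def test_removes_isolated_voxel(self):
        voxels = np.zeros((7, 7, 7), bool)
        voxels[3, 3, 3] = True
        assert morphological_opening(BinaryLesionMask(voxels)).n_voxels == 0

    def test_preserves_5cube(self):
        voxels = np.zeros((9, 9, 9), bool)
        voxels[2:7, 2:7, 2:7] = True
        out = morphological_opening(BinaryLesionMask(voxels))
        np.testing.assert_array_equal(out.voxels, voxels)

    def test_matches_bruteforce_oracle(self, rng):
        voxels = rng.uniform(size=(10, 10, 10)) > 0.4
        out = morphological_opening(BinaryLesionMask(voxels))
        np.testing.assert_array_equal(out.voxels, self.brute_open(voxels))

    def test_idempotent_and_antiextensive(self, rng):
        voxels = rng.uniform(size=(10, 10, 10)) > 0.45
        once = morphological_opening(BinaryLesionMask(voxels))
        twice = morphological_opening(once)
        np.testing.assert_array_equal(twice.voxels, once.voxels)
        assert (once.voxels <= voxels).all()
        assert once.postprocessed

    def test_never_increases_count(self, rng):
        for seed in range(5):
            voxels = np.random.default_rng(seed).uniform(size=(8, 8, 8)) > 0.5
            out = morphological_opening(BinaryLesionMask(voxels))
            assert out.n_voxels <= voxels.sum()
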