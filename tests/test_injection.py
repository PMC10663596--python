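"""Corruption generator: brain statistics, noise structure, patch plans."""

import numpy as np
import pytest

from dwianomaly.injection import (
    NoiseSpec,
    PATCH_COUNT_PROBS,
    augment,
    brain_statistics,
    corrupt,
    draw_patch_plan,
    sample_noise_block,
)
from dwianomaly.io import DWIVolume


def _const_volume(tiny_volume, value):
    sig = np.zeros_like(tiny_volume.signal)
    sig[tiny_volume.brain_mask] = value
    return replace_signal(tiny_volume, sig)


def replace_signal(vol, sig):
    return DWIVolume(
        signal=sig, voxel_size=vol.voxel_size, bvals=vol.bvals,
        bvecs=vol.bvecs, tissue_mask=vol.tissue_mask,
        subject_id=vol.subject_id, normalized=False,
    )


class TestBrainStatistics:
    def test_constant_volume(self, tiny_volume):
        mu, sigma = brain_statistics(_const_volume(tiny_volume, 0.25))
        assert np.isclose(mu, 0.25) and np.isclose(sigma, 0.0)

    def test_two_value_volume(self, tiny_volume):
        sig = np.zeros_like(tiny_volume.signal)
        n_vals = sig[tiny_volume.brain_mask].size
        assert n_vals % 2 == 0  # 6 channels → even pooled count
        sig[tiny_volume.brain_mask] = np.resize([0.0, 1.0], n_vals).reshape(-1, 6)
        mu, sigma = brain_statistics(replace_signal(tiny_volume, sig))
        assert np.isclose(mu, 0.5, atol=1e-9)
        assert np.isclose(sigma, 0.5, atol=1e-9)

    def test_matches_pooled_recomputation(self, tiny_volume):
        mu, sigma = brain_statistics(tiny_volume)
        pooled = tiny_volume.signal[tiny_volume.brain_mask].ravel()
        assert np.isclose(mu, pooled.mean())
        assert np.isclose(sigma, pooled.std())

    def test_empty_mask_rejected(self, tiny_volume):
        vol = replace_signal(tiny_volume, tiny_volume.signal)
        vol.tissue_mask = np.zeros_like(vol.tissue_mask)
        with pytest.raises(ValueError, match="empty"):
            brain_statistics(vol)


class TestNoiseBlocks:
    def test_isotropic_constant_across_channels(self, rng):
        block = sample_noise_block(
            (50, 8), NoiseSpec("normal", "full", "isotropic"), 0.5, 0.1, rng, clip=False
        )
        assert np.all(block.var(axis=1) < 1e-30)

    def test_directional_constant_across_space(self, rng):
        block = sample_noise_block(
            (50, 8), NoiseSpec("uniform", "full", "directional"), 0.5, 0.1, rng, clip=False
        )
        assert np.all(block.var(axis=0) < 1e-30)

    def test_random_structure_varies_everywhere(self, rng):
        block = sample_noise_block(
            (50, 8), NoiseSpec("normal", "full", "random"), 0.5, 0.1, rng, clip=False
        )
        assert block.var(axis=0).min() > 0 and block.var(axis=1).min() > 0

    def test_normal_full_large_sample_statistics(self, rng):
        mu, sigma, n = 0.4, 0.1, 100_000
        block = sample_noise_block(
            (n, 1), NoiseSpec("normal", "full", "random"), mu, sigma, rng, clip=False
        )
        assert abs(block.mean() - mu) < 4 * sigma / np.sqrt(n)
        assert abs(block.std() - sigma) < 0.05 * sigma

    def test_half_mode_shifts_mean_by_half_mu(self, rng):
        mu, sigma, n = 0.8, 0.05, 200_000
        full = sample_noise_block(
            (n, 1), NoiseSpec("normal", "full", "random"), mu, sigma,
            np.random.default_rng(0), clip=False,
        )
        half = sample_noise_block(
            (n, 1), NoiseSpec("normal", "half", "random"), mu, sigma,
            np.random.default_rng(0), clip=False,
        )
        np.testing.assert_allclose(full - half, mu / 2.0, atol=1e-12)

    def test_uniform_range_equals_sigma(self, rng):
        mu, sigma = 0.5, 0.2
        block = sample_noise_block(
            (100_000, 1), NoiseSpec("uniform", "full", "random"), mu, sigma, rng, clip=False
        )
        assert block.min() >= mu - sigma / 2 - 1e-12
        assert block.max() <= mu + sigma / 2 + 1e-12
        assert block.max() - block.min() > 0.99 * sigma

    def test_mix_resolves_concrete(self, rng):
        spec = NoiseSpec("mix", "mix", "mix")
        resolved = spec.resolve(rng)
        assert resolved.concrete


class TestCorrupt:
    def test_untouched_outside_groundtruth(self, tiny_volume, rng):
        cv = corrupt(tiny_volume, NoiseSpec("normal", "half", "isotropic"), rng=rng)
        outside = ~cv.artificial_groundtruth
        np.testing.assert_array_equal(cv.signal[outside], tiny_volume.signal[outside])

    def test_zero_patch_plan_is_identity(self, tiny_volume):
        for seed in range(30):
            cv = corrupt(tiny_volume, rng=seed)
            if cv.plan.n_patches == 0:
                np.testing.assert_array_equal(cv.signal, tiny_volume.signal)
                assert cv.n_corrupted_voxels == 0
                return
        pytest.fail("no zero-patch plan in 30 seeds (P ≈ 0.2 each)")

    def test_groundtruth_exactly_marks_replaced_voxels(self, tiny_volume):
        for seed in range(10):
            cv = corrupt(tiny_volume, NoiseSpec("normal", "full", "random"), rng=seed)
            changed = np.any(cv.signal != tiny_volume.signal, axis=3)
            # replaced ⊆ groundtruth (a draw may coincide with the old value)
            assert not (changed & ~cv.artificial_groundtruth).any()
            if cv.plan.n_patches:
                assert cv.artificial_groundtruth.any()

    def test_values_stay_in_unit_interval(self, tiny_volume):
        for seed in range(5):
            cv = corrupt(tiny_volume, NoiseSpec("normal", "full", "random"), rng=seed)
            assert cv.signal.min() >= 0.0 and cv.signal.max() <= 1.0

    def test_patches_never_touch_background(self, tiny_volume):
        for seed in range(10):
            cv = corrupt(tiny_volume, rng=seed)
            assert not cv.artificial_groundtruth[~tiny_volume.brain_mask].any()

    def test_patch_count_distribution_small_sample(self, tiny_volume):
        rng = np.random.default_rng(0)
        counts = np.bincount(
            [draw_patch_plan(tiny_volume, NoiseSpec(), (2, 6), rng).n_patches
             for _ in range(600)],
            minlength=3,
        )
        freqs = counts / 600
        for f, p in zip(freqs, PATCH_COUNT_PROBS):
            assert abs(f - p) < 3 * np.sqrt(p * (1 - p) / 600)


class TestAugment:
    def test_expands_to_four(self, tiny_volume):
        out = augment(tiny_volume, rng=0)
        assert len(out) == 4

    def test_deterministic_under_rng_state(self, tiny_volume):
        a = augment(tiny_volume, rng=np.random.default_rng(9))
        b = augment(tiny_volume, rng=np.random.default_rng(9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.signal, y.signal)
            np.testing.assert_array_equal(x.artificial_groundtruth, y.artificial_groundtruth)

    def test_draws_generically_differ(self, tiny_volume):
        out = augment(tiny_volume, rng=3)
        masks = [cv.artificial_groundtruth for cv in out]
        distinct = sum(
            not np.array_equal(masks[i], masks[j])
            for i in range(4) for j in range(i + 1, 4)
        )
        assert distinct >= 5  # at most one coincident pair among six
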