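"""Augmentation operators: oracles, invariants and probability gates."""

import numpy as np
import pytest

from forceskill.augmentation import (
    AugmentationConfig, apply_augmentation, drift, gaussian_noise, quantize,
    rfft_stack, temporal_jitter, time_warp,
)


def dft_oracle(x):
    """Direct O(T^2) DFT summation over the one-sided coefficients."""
    T = len(x)
    ks = np.arange(T // 2 + 1)
    w = np.exp(-2j * np.pi * np.outer(ks, np.arange(T)) / T)
    return w @ np.asarray(x, dtype=complex)


class TestRfftStack:
    def test_shape_is_3xT(self, rng):
        for T in (2, 17, 300):
            out = rfft_stack(rng.normal(size=T))
            assert out.shape == (3, T)

    def test_row0_is_the_signal(self, rng):
        v = rng.normal(size=40)
        np.testing.assert_array_equal(rfft_stack(v)[0], v)

    def test_constant_input_matches_dft_oracle(self):
        v = np.full(16, 3.0)
        out = rfft_stack(v)
        oracle = dft_oracle(v)
        np.testing.assert_allclose(out[1, :9], oracle.real, atol=1e-9)
        np.testing.assert_allclose(out[2, :9], oracle.imag, atol=1e-9)
        assert np.abs(out[2]).max() < 1e-9
        assert np.abs(out[1, 1:]).max() < 1e-9  # energy only at coefficient 0

    def test_pure_sinusoid_concentrates_at_its_bin(self):
        T, k = 64, 5
        v = np.sin(2 * np.pi * k * np.arange(T) / T)
        out = rfft_stack(v)
        oracle = dft_oracle(v)
        np.testing.assert_allclose(out[1, :T // 2 + 1], oracle.real, atol=1e-9)
        np.testing.assert_allclose(out[2, :T // 2 + 1], oracle.imag, atol=1e-9)
        mag = np.hypot(out[1], out[2])
        assert mag[k] > 1.0
        mask = np.ones(T, dtype=bool)
        mask[k] = False
        assert mag[mask].max() < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rfft_stack(np.array([1.0]))


class TestQuantize:
    def test_matches_brute_force_nearest_level(self, rng):
        v = rng.uniform(0, 10, size=200)
        out = quantize(v, apply_prob=1.0, rng=rng)
        levels = np.linspace(v.min(), v.max(), 10)
        for x, q in zip(v, out):
            dists = np.abs(levels - x)
            best = dists.min()
            candidates = levels[dists <= best + 1e-15]
            assert q == pytest.approx(candidates.min())  # ties go to the lower level

    def test_worked_example(self):
        out = quantize(np.array([0.0, 0.26, 1.0]), apply_prob=1.0,
                       rng=np.random.default_rng(0))
        np.testing.assert_allclose(out, [0.0, 2.0 / 9.0, 1.0])

    def test_prob_zero_is_identity(self, rng):
        v = rng.uniform(0, 10, size=50)
        np.testing.assert_array_equal(quantize(v, apply_prob=0.0, rng=rng), v)

    def test_at_most_ten_distinct_values(self, rng):
        v = rng.uniform(0, 10, size=500)
        out = quantize(v, apply_prob=1.0, rng=rng)
        assert len(np.unique(out)) <= 10

    def test_constant_trace_unchanged(self, rng):
        v = np.full(30, 4.0)
        np.testing.assert_array_equal(quantize(v, apply_prob=1.0, rng=rng), v)


class TestDrift:
    def test_prob_zero_is_identity(self, rng):
        v = rng.uniform(1, 5, size=100)
        np.testing.assert_array_equal(drift(v, apply_prob=0.0, rng=rng), v)

    def test_zero_trace_maps_to_zero(self, rng):
        out = drift(np.zeros(100), apply_prob=1.0, rng=rng)
        np.testing.assert_array_equal(out, 0.0)

    def test_anchor_multipliers_within_10_to_50_percent(self):
        v = np.ones(120)
        for seed in range(30):
            out = drift(v, apply_prob=1.0, rng=np.random.default_rng(seed))
            # replay the generator to recover the anchor indices: one gate
            # draw, then the anchor choice
            replay = np.random.default_rng(seed)
            replay.random()
            anchors = np.sort(replay.choice(np.arange(1, 119), size=5, replace=False))
            ratios = out[anchors] / v[anchors]
            assert np.all(ratios >= 1.1 - 1e-9) and np.all(ratios <= 1.5 + 1e-9)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            drift(np.ones(6), apply_prob=1.0, rng=rng)

    def test_endpoints_unchanged(self, rng):
        v = np.linspace(1, 2, 80)
        out = drift(v, apply_prob=1.0, rng=rng)
        assert out[0] == pytest.approx(v[0])
        assert out[-1] == pytest.approx(v[-1])


class TestTimeWarp:
    def test_output_length_preserved(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            T = int(rng.integers(100, 400))
            v = rng.normal(size=T)
            assert time_warp(v, apply_prob=1.0, rng=rng).size == T

    def test_prob_zero_is_identity(self, rng):
        v = rng.normal(size=200)
        np.testing.assert_array_equal(time_warp(v, apply_prob=0.0, rng=rng), v)

    def test_constant_trace_stays_constant(self, rng):
        out = time_warp(np.full(300, 2.5), apply_prob=1.0, rng=rng)
        np.testing.assert_allclose(out, 2.5)

    def test_stays_within_input_range(self, rng):
        v = rng.uniform(2, 8, size=300)
        out = time_warp(v, apply_prob=1.0, rng=rng)
        assert out.min() >= v.min() - 1e-12 and out.max() <= v.max() + 1e-12

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            time_warp(np.ones(99), apply_prob=1.0, rng=rng)


class TestGaussianNoise:
    def test_sd_zero_is_identity(self, rng):
        v = rng.normal(size=100)
        np.testing.assert_array_equal(gaussian_noise(v, sd=0.0, rng=rng), v)

    def test_moment_recovery(self):
        v = np.zeros(100_000)
        out = gaussian_noise(v, sd=0.1, rng=np.random.default_rng(99))
        diff = out - v
        assert abs(diff.mean()) < 3 * 0.1 / np.sqrt(100_000)
        assert abs(diff.std() - 0.1) < 0.001

    def test_same_seed_identical(self):
        v = np.arange(50, dtype=float)
        a = gaussian_noise(v, rng=np.random.default_rng(5))
        b = gaussian_noise(v, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestTemporalJitter:
    def test_identity_permutation_possible_and_multiset_preserved(self, rng):
        v = rng.normal(size=300)
        out = temporal_jitter(v, rng=rng)
        np.testing.assert_allclose(np.sort(out), np.sort(v))

    def test_segments_move_as_blocks(self):
        v = np.arange(300, dtype=float)
        out = temporal_jitter(v, rng=np.random.default_rng(1))
        blocks = out.reshape(30, 10)
        # every output block is one contiguous input block
        for b in blocks:
            np.testing.assert_array_equal(b, np.arange(b[0], b[0] + 10))

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError):
            temporal_jitter(np.ones(299), rng=rng)


class TestGatesAndConfig:
    @pytest.mark.parametrize("op,kwargs", [
        (quantize, {}),
        (drift, {}),
        (time_warp, {}),
    ])
    def test_gate_fires_at_half_probability(self, op, kwargs):
        rng = np.random.default_rng(2024)
        v = np.arange(1.0, 301.0)
        fired = 0
        n = 10_000
        for _ in range(n):
            out = op(v, apply_prob=0.5, rng=rng, **kwargs)
            fired += int(not np.array_equal(out, v))
        assert 0.47 <= fired / n <= 0.53

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown augmentation"):
            AugmentationConfig(name="mixup")

    def test_apply_augmentation_channel_shapes(self, rng):
        v = np.arange(300, dtype=float)
        assert apply_augmentation("fft", v, rng).shape == (3, 300)
        assert apply_augmentation("timewarp", v, rng).shape == (1, 300)
        assert apply_augmentation("temporal_jitter", v, rng).shape == (1, 300)

    def test_pure_function_of_seed(self):
        v = np.sin(np.arange(300) / 7.0) + 2
        for name in ("quantize", "drift", "timewarp", "gaussian_noise",
                     "temporal_jitter"):
            a = apply_augmentation(name, v, np.random.default_rng(3), apply_prob=1.0)
            b = apply_augmentation(name, v, np.random.default_rng(3), apply_prob=1.0)
            np.testing.assert_array_equal(a, b)
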