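"""Tests for the synthetic-dataset generator: stage semantics, invariants,
and the end-to-end composition."""

import math

import numpy as np
import pytest

from manifolddim import (
    ChannelMatrix,
    LatentMatrix,
    SimulationConfig,
    add_noise,
    exp_activation,
    exp_activation_inverse,
    gaussian_smooth,
    linear_mix,
    rescale_random,
    sample_latents,
    scale_unit,
    simulate_dataset,
)


class TestSampleLatents:
    def test_shape_and_nonnegativity(self):
        lat = sample_latents(6, 1000, seed=1)
        assert lat.values.shape == (6, 1000)
        assert np.all(lat.values >= 0)

    def test_single_row(self):
        lat = sample_latents(1, 10, seed=0)
        assert lat.values.shape == (1, 10)

    def test_rows_uncorrelated(self):
        lat = sample_latents(6, 1000, seed=1)
        r = np.corrcoef(lat.values)
        off = r[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_marginal_matches_source_cdf(self):
        # KS distance between each row's empirical CDF and the exponential
        # source must be small at large M
        from scipy.stats import kstest

        lat = sample_latents(2, 100_000, seed=7)
        for row in lat.values:
            ks = kstest(row, "expon").statistic
            assert ks < 0.01

    def test_empirical_file_source(self, tmp_path):
        sample = np.random.default_rng(0).gamma(2.0, 1.0, size=500)
        f = tmp_path / "rates.txt"
        np.savetxt(f, sample)
        lat = sample_latents(3, 200, latent_source=str(f), seed=2)
        assert set(np.unique(lat.values)) <= set(sample)

    def test_rejects_bad_sources(self, tmp_path):
        with pytest.raises(ValueError, match="unknown latent source"):
            sample_latents(2, 100, latent_source="nope-not-a-source", seed=0)
        short = tmp_path / "short.txt"
        np.savetxt(short, np.ones(10))
        with pytest.raises(ValueError, match="at least 100"):
            sample_latents(2, 100, latent_source=str(short), seed=0)
        neg = tmp_path / "neg.txt"
        np.savetxt(neg, np.linspace(-1, 1, 200))
        with pytest.raises(ValueError, match="negative"):
            sample_latents(2, 100, latent_source=str(neg), seed=0)


class TestGaussianSmooth:
    def test_constant_row_unchanged(self):
        lat = LatentMatrix(np.full((1, 50), 3.0))
        out = gaussian_smooth(lat, 1.0)
        np.testing.assert_allclose(out.values, 3.0, rtol=1e-12)

    def test_zero_sd_is_identity(self):
        lat = sample_latents(2, 100, seed=3)
        out = gaussian_smooth(lat, 0.0)
        np.testing.assert_array_equal(out.values, lat.values)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(sample_latents(1, 10, seed=0), -1.0)

    def test_lag1_autocorrelation_of_smoothed_noise(self):
        # unit-sd Gaussian smoothing of white noise gives lag-1
        # autocorrelation exp(-1/4) ~ 0.779 (continuous-kernel value)
        rng = np.random.default_rng(0)
        lat = LatentMatrix(rng.exponential(1.0, size=(1, 100_000)))
        out = gaussian_smooth(lat, 1.0).values[0]
        x = out - out.mean()
        rho1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert abs(rho1 - math.exp(-0.25)) < 0.01


class TestLinearMix:
    def test_shape_and_determinism(self):
        lat = sample_latents(6, 300, seed=1)
        ch1, W1 = linear_mix(lat, 96, seed=5)
        ch2, W2 = linear_mix(lat, 96, seed=5)
        assert ch1.values.shape == (96, 300)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(ch1.values, ch2.values)

    def test_output_rank_equals_d(self):
        lat = sample_latents(6, 300, seed=2)
        ch, _ = linear_mix(lat, 96, seed=5)
        sv = np.linalg.svd(ch.values, compute_uv=False)
        assert np.sum(sv > sv[0] * 1e-10) == 6

    def test_undercomplete_mixing_rejected(self):
        lat = sample_latents(6, 50, seed=0)
        with pytest.raises(ValueError, match="undercomplete"):
            linear_mix(lat, 4, seed=0)


class TestScaleUnit:
    def test_hand_example(self):
        ch = ChannelMatrix(np.array([[2.0, 4.0, 6.0], [0.0, 1.0, 0.5]]))
        out = scale_unit(ch)
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])

    def test_every_channel_spans_unit_interval(self, rng):
        ch = ChannelMatrix(rng.standard_normal((5, 40)))
        out = scale_unit(ch)
        np.testing.assert_allclose(out.values.min(axis=1), 0.0, atol=1e-15)
        np.testing.assert_allclose(out.values.max(axis=1), 1.0, atol=1e-15)

    def test_already_scaled_channel_unchanged(self):
        v = np.array([[0.0, 0.25, 1.0]])
        out = scale_unit(ChannelMatrix(v))
        np.testing.assert_allclose(out.values, v)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant channel"):
            scale_unit(ChannelMatrix(np.ones((2, 5))))


class TestExpActivation:
    def test_boundary_values(self):
        ch = ChannelMatrix(np.array([[0.0, 1.0]]))
        for alpha in (0.5, 1.0, 16.0, 100.0):
            out = exp_activation(ch, alpha)
            np.testing.assert_allclose(out.values, [[0.0, 1.0]], atol=1e-14)

    def test_small_alpha_limit_is_identity(self):
        x = np.linspace(0, 1, 11)[None, :]
        out = exp_activation(ChannelMatrix(x), 1e-6)
        assert np.max(np.abs(out.values - x)) < 1e-5

    def test_value_at_half_alpha16(self):
        # (e^8 - 1) / (e^16 - 1), evaluated independently
        expected = (math.exp(8) - 1) / (math.exp(16) - 1)
        out = exp_activation(ChannelMatrix(np.array([[0.5]])), 16.0)
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)
        assert out.values[0, 0] == pytest.approx(3.354e-4, rel=1e-3)

    def test_bijection_roundtrip(self, rng):
        x = ChannelMatrix(rng.random((4, 50)))
        for alpha in (0.1, 2.0, 16.0, 32.0):
            y = exp_activation(x, alpha)
            back = exp_activation_inverse(y, alpha)
            assert np.max(np.abs(back.values - x.values)) < 1e-10

    def test_domain_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            exp_activation(ChannelMatrix(np.array([[1.5, 0.2]])), 2.0)


class TestAddNoise:
    def test_infinite_snr_is_identity(self, rng):
        ch = ChannelMatrix(rng.random((3, 100)))
        out = add_noise(ch, np.inf, seed=0)
        np.testing.assert_array_equal(out.values, ch.values)

    @pytest.mark.parametrize("snr_db,expected_ratio", [(20.0, 0.01), (7.0, 0.1995)])
    def test_noise_power_fraction(self, rng, snr_db, expected_ratio):
        # 20 dB <=> noise power 1% of signal power; 7 dB <=> ~20%
        ch = ChannelMatrix(rng.random((4, 100_000)))
        out = add_noise(ch, snr_db, seed=1)
        noise = out.values - ch.values
        ratio = noise.var(axis=1) / ch.values.var(axis=1)
        np.testing.assert_allclose(ratio, expected_ratio, rtol=0.1)

    def test_empirical_snr_within_half_db(self, rng):
        ch = ChannelMatrix(rng.random((4, 20_000)))
        out = add_noise(ch, 10.0, seed=2)
        noise = out.values - ch.values
        snr_emp = 10 * np.log10(ch.values.var(axis=1) / noise.var(axis=1))
        assert np.all(np.abs(snr_emp - 10.0) < 0.5)


class TestRescaleRandom:
    def test_scale_factors_and_variance(self, rng):
        ch = ChannelMatrix(rng.random((10, 200)))
        out, scales = rescale_random(ch, 1.0, 10.0, seed=3)
        assert np.all((scales >= 1) & (scales <= 10))
        np.testing.assert_allclose(
            out.values.var(axis=1), ch.values.var(axis=1) * scales**2, rtol=1e-10
        )

    def test_same_seed_same_scales(self, rng):
        ch = ChannelMatrix(rng.random((5, 50)))
        _, s1 = rescale_random(ch, 1.0, 10.0, seed=9)
        _, s2 = rescale_random(ch, 1.0, 10.0, seed=9)
        np.testing.assert_array_equal(s1, s2)

    def test_bad_range_rejected(self, rng):
        with pytest.raises(ValueError):
            rescale_random(ChannelMatrix(rng.random((2, 10))), 5.0, 5.0, seed=0)


class TestSimulateDataset:
    def test_noise_free_linear_composition(self):
        ds = simulate_dataset(SimulationConfig(d=6, M=800, N=96, seed=4))
        np.testing.assert_array_equal(ds.observed.values, ds.clean.values)
        centered = ds.clean.values - ds.clean.values.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(centered, compute_uv=False)
        assert np.sum(sv > sv[0] * 1e-8) == 6

    def test_covariance_rank_matches_d(self):
        from manifolddim import eigen_spectrum

        ds = simulate_dataset(SimulationConfig(d=4, M=500, N=30, seed=5))
        ev = eigen_spectrum(ds.clean).eigenvalues
        assert np.sum(ev > 1e-8 * ev[0]) == 4

    def test_nonlinear_output_in_unit_interval(self):
        ds = simulate_dataset(SimulationConfig(d=6, M=500, N=96, alpha=16.0, seed=6))
        assert ds.observed.values.min() >= 0
        assert ds.observed.values.max() <= 1

    def test_determinism(self):
        cfg = SimulationConfig(d=3, M=300, N=20, alpha=4.0, snr_db=10.0,
                               channel_scale_range=(1.0, 10.0), seed=7)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        np.testing.assert_array_equal(a.observed.values, b.observed.values)
        np.testing.assert_array_equal(a.W, b.W)

    def test_stage_error_names_stage(self):
        # d > N fails the config invariant up front
        with pytest.raises(ValueError):
            SimulationConfig(d=10, M=100, N=5, seed=0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(d=2, M=1, N=10)
        with pytest.raises(ValueError):
            SimulationConfig(d=2, M=100, N=10, alpha=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(d=2, M=100, N=10, channel_scale_range=(0.5, 2.0))
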