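"""Generator: parabolic transients, filtered noise, lines, subjects, populations."""

import math

import numpy as np
import pytest
from scipy import signal, stats

import ertwave.synthgen as sg
from ertwave import (
    GeneratorParams,
    generate_line,
    generate_noise_line,
    generate_populations,
    generate_subject,
    lowpass_filter,
    parabolic_transient,
    sample_transient_magnitude,
    transient_support,
)

HALF_NORMAL_MEAN = math.sqrt(2 / math.pi)  # E|z| for z ~ N(0,1)
HALF_NORMAL_SD = math.sqrt(1 - 2 / math.pi)


class TestParabolicTransient:
    @pytest.mark.parametrize(
        "duration,fs,expected_k", [(1.0, 10, 10), (0.5, 10, 5), (1.0, 30, 30)]
    )
    def test_sample_count(self, duration, fs, expected_k):
        assert len(parabolic_transient(duration, fs, 1.0)) == expected_k

    def test_peak_equals_magnitude_and_symmetric(self):
        v = parabolic_transient(1.0, 10, 2.5)
        assert v.max() == pytest.approx(2.5, abs=0)
        np.testing.assert_allclose(v, v[::-1], atol=1e-12)
        assert np.all(v > 0)  # edges are small but strictly positive

    def test_zero_magnitude_gives_zeros(self):
        assert not parabolic_transient(1.0, 10, 0.0).any()

    @pytest.mark.parametrize("duration", [0.0, -1.0, 0.1])
    def test_invalid_duration_rejected(self, duration):
        with pytest.raises(ValueError):
            parabolic_transient(duration, 10, 1.0)


class TestTransientMagnitude:
    def test_half_normal_moments_and_positivity(self, rng):
        draws = np.array([sample_transient_magnitude(rng) for _ in range(100_000)])
        assert np.all(draws >= 0)
        se = HALF_NORMAL_SD / math.sqrt(draws.size)
        assert abs(draws.mean() - HALF_NORMAL_MEAN) < 3 * se

    def test_seed_determinism(self):
        a = sample_transient_magnitude(np.random.default_rng(7))
        b = sample_transient_magnitude(np.random.default_rng(7))
        assert a == b

    def test_scale(self):
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        assert sample_transient_magnitude(r1, 2.0) == 2 * sample_transient_magnitude(r2)


class TestNoiseLine:
    def test_zero_power_gives_zero_trace(self, rng):
        params = GeneratorParams(noise_power=0.0)
        assert not generate_noise_line(params, rng).values.any()

    def test_spectrum_concentrated_below_cutoff(self, rng):
        params = GeneratorParams()
        lines = sg._noise_lines(params, rng, 10_000)
        freqs, psd = signal.periodogram(lines, fs=params.fs, axis=-1)
        mean_psd = psd.mean(axis=0)
        low = mean_psd[freqs < params.lowpass_hz].mean()
        high = mean_psd[freqs > 2 * params.lowpass_hz].mean()
        assert high < 0.05 * low

    def test_pointwise_grand_mean_near_zero(self, rng):
        params = GeneratorParams()
        lines = sg._noise_lines(params, rng, 10_000)
        se = lines.std(axis=0, ddof=1) / math.sqrt(lines.shape[0])
        assert np.all(np.abs(lines.mean(axis=0)) < 4 * se)

    def test_filter_is_zero_phase(self):
        impulse = np.zeros(100)
        impulse[50] = 1.0
        out = lowpass_filter(impulse, fs=10, cutoff=2)
        assert out.argmax() == 50


class TestGenerateLine:
    def test_noiseless_ert_is_parabola_at_halfway(self):
        params = GeneratorParams(noise_power=0.0)
        tr = generate_line("ert", params, np.random.default_rng(0), magnitude=1.0)
        lo, hi = transient_support(params)
        assert (lo, hi) == (50, 60)
        np.testing.assert_array_equal(
            tr.values[lo:hi], parabolic_transient(1.0, 10, 1.0)
        )
        assert not tr.values[:lo].any() and not tr.values[hi:].any()

    def test_null_transient_probability(self, rng):
        params = GeneratorParams(noise_power=0.0)
        hits = sum(
            generate_line("null", params, rng).values.any() for _ in range(10_000)
        )
        se = math.sqrt(0.25 / 10_000)
        assert abs(hits / 10_000 - 0.5) < 3 * se

    def test_null_transients_fit_inside_window(self, rng):
        params = GeneratorParams(noise_power=0.0, null_transient_prob=1.0)
        for _ in range(200):
            v = generate_line("null", params, rng).values
            nz = np.flatnonzero(v)
            assert nz.size == params.transient_samples
            assert nz[-1] - nz[0] == params.transient_samples - 1

    def test_ert_mean_peak_is_half_normal_mean(self, rng):
        params = GeneratorParams(noise_power=0.0)
        n = 10_000
        peaks = np.array(
            [generate_line("ert", params, rng).values[54] for _ in range(n)]
        )
        se = HALF_NORMAL_SD / math.sqrt(n)
        assert abs(peaks.mean() - HALF_NORMAL_MEAN) < 3 * se

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(ValueError, match="condition"):
            generate_line("baseline", GeneratorParams(), rng)

    def test_seed_determinism(self):
        params = GeneratorParams()
        a = generate_line("null", params, np.random.default_rng(11))
        b = generate_line("null", params, np.random.default_rng(11))
        np.testing.assert_array_equal(a.values, b.values)


class TestGenerateSubject:
    def test_single_line_subject_equals_line_draw(self):
        params = GeneratorParams()
        subj = generate_subject("null", params, np.random.default_rng(5), n_lines=1)
        line = generate_line("null", params, np.random.default_rng(5))
        np.testing.assert_array_equal(subj.values, line.values)

    def test_lines_per_subject_uniform(self, monkeypatch, rng):
        params = GeneratorParams(noise_power=0.0, null_transient_prob=0.0)
        counts = []
        real = sg.generate_line

        def counting(condition, p, r, magnitude=None):
            counts[-1] += 1
            return real(condition, p, r, magnitude)

        monkeypatch.setattr(sg, "generate_line", counting)
        n = 10_000
        for _ in range(n):
            counts.append(0)
            generate_subject("null", params, rng)
        observed = np.bincount(counts, minlength=32)[1:32]
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.001

    def test_averaging_reduces_variance(self, rng):
        params = GeneratorParams(null_transient_prob=0.0)
        v1 = np.stack(
            [generate_subject("null", params, rng, n_lines=1).values for _ in range(300)]
        )
        v31 = np.stack(
            [generate_subject("null", params, rng, n_lines=31).values for _ in range(300)]
        )
        assert v31.var(axis=0).mean() < v1.var(axis=0).mean()


class TestGeneratePopulations:
    def test_shapes_and_seed_reproducibility(self, small_params, small_populations):
        null_pop, ert_pop = small_populations
        assert null_pop.n_traces == ert_pop.n_traces == small_params.population_subjects
        assert null_pop.n_points == small_params.n_points
        null2, ert2 = generate_populations(small_params)
        np.testing.assert_array_equal(null_pop.values, null2.values)
        np.testing.assert_array_equal(ert_pop.values, ert2.values)

    def test_ert_bump_confined_to_transient_window(self, small_params, small_populations):
        _, ert_pop = small_populations
        mean = ert_pop.values.mean(axis=0)
        lo, hi = transient_support(small_params)
        margin = int(0.5 * small_params.fs)
        outside = np.r_[mean[: lo - margin], mean[hi + margin :]]
        assert np.abs(outside).max() < np.abs(mean[lo:hi]).max()

    def test_ert_matches_null_outside_support(self, small_params, small_populations):
        """Away from the event-locked transient the two conditions are the
        same zero-mean process (unrelated null transients are sign-symmetric,
        so they add variance but no mean shift)."""
        null_pop, ert_pop = small_populations
        lo, hi = transient_support(small_params)
        outside = np.r_[0:lo, hi : small_params.n_points]
        res = stats.ttest_ind(
            null_pop.values[:, outside], ert_pop.values[:, outside], axis=0
        )
        assert res.pvalue.min() > 0.001 / outside.size
        both = np.r_[null_pop.values[:, outside], ert_pop.values[:, outside]]
        zero = stats.ttest_1samp(both, 0.0, axis=0)
        assert zero.pvalue.min() > 0.001 / outside.size


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fs": 0},
            {"lowpass_hz": 6.0},
            {"transient_duration": 0.1},
            {"null_transient_prob": 1.5},
            {"lines_per_subject_range": (0, 31)},
            {"lines_per_subject_range": (5, 2)},
            {"noise_power": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorParams(**kwargs)
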