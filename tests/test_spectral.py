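"""Sensor-space feature extraction: epoching, modes, AR spectra, stats."""

import numpy as np
import pytest
from scipy import signal as sps

from neurodcm.containers import CHANNELS_1020, Recording
from neurodcm.spectral import (
    EmptyDataError,
    band_power_summary,
    compute_spatial_modes,
    count_data_points,
    group_band_anova,
    mar_cross_spectra,
    preprocess,
)
from neurodcm.containers import CrossSpectra


def _white_recording(rng, duration=60.0, rate=250.0, n_ch=21, scale=5.0):
    n = int(duration * rate)
    return Recording(scale * rng.standard_normal((n_ch, n)), rate)


class TestPreprocess:
    def test_clean_recording_yields_duration_over_five(self, rng):
        rec = _white_recording(rng, duration=60.0)
        es = preprocess(rec)
        assert es.n_epochs == 12
        assert es.n_rejected == 0

    def test_amplitude_step_rejects_exactly_that_epoch(self, rng):
        rec = _white_recording(rng, duration=60.0)
        rec.samples[3, 6 * 1250 + 100] += 500.0  # 500 uV artifact in epoch 6
        es = preprocess(rec)
        assert es.n_epochs == 11
        assert es.n_rejected == 1

    def test_all_rejected_raises(self, rng):
        rec = _white_recording(rng, duration=20.0, scale=200.0)
        with pytest.raises(EmptyDataError):
            preprocess(rec)

    def test_lowpass_attenuates_above_45(self, rng):
        # periodogram oracle: post-filter power above 45 Hz <= 1% of total
        rec = _white_recording(rng, duration=120.0)
        es = preprocess(rec)
        x = es.epochs[:, 0, :].ravel()
        f, p = sps.welch(x, fs=rec.rate, nperseg=1024)
        assert p[f > 45].sum() / p.sum() <= 0.01


class TestSpatialModes:
    def test_orthonormality(self, rng):
        es = preprocess(_white_recording(rng))
        sm = compute_spatial_modes(es, 8)
        np.testing.assert_allclose(sm.matrix.T @ sm.matrix, np.eye(8),
                                   atol=1e-10)

    def test_low_rank_data_has_noise_floor_after_rank(self, rng):
        # constructed fixture: exactly 3 independent sources + tiny noise
        n = 250 * 40
        latents = rng.standard_normal((3, n))
        mix = rng.standard_normal((21, 3))
        data = 2.0 * mix @ latents + 0.002 * rng.standard_normal((21, n))
        es = preprocess(Recording(data, 250.0))
        sm = compute_spatial_modes(es, 8)
        assert sm.singular_values[3] / sm.singular_values[0] < 1e-2

    def test_k_exceeding_channels_raises(self, rng):
        es = preprocess(_white_recording(rng, n_ch=21))
        with pytest.raises(ValueError):
            compute_spatial_modes(es, 22)

    def test_full_rank_projection_preserves_variance(self, rng):
        es = preprocess(_white_recording(rng, duration=20.0))
        sm = compute_spatial_modes(es, 21)
        X = es.epochs.transpose(1, 0, 2).reshape(21, -1)
        X = X - X.mean(axis=1, keepdims=True)
        proj = sm.matrix.T @ X
        assert np.var(proj) == pytest.approx(np.var(X), rel=1e-10)


class TestMarCrossSpectra:
    def test_ar1_matches_closed_form(self, rng):
        """Univariate AR(1) spectrum proportional to 1/|1 - a e^{-iw}|^2."""
        a, sigma, rate = 0.8, 1.0, 250.0
        n = 200000
        x = np.empty(n)
        x[0] = 0.0
        eps = sigma * rng.standard_normal(n)
        for t in range(1, n):
            x[t] = a * x[t - 1] + eps[t]
        es_epochs = x[: (n // 1250) * 1250].reshape(-1, 1, 1250)
        from neurodcm.containers import EpochSet, SpatialModes

        es = EpochSet(es_epochs, rate, ["ch1"])
        sm = SpatialModes(np.ones((1, 1)), np.array([1.0]))
        cs = mar_cross_spectra(es, sm, order=4, band=(1.0, 48.0))
        w = 2 * np.pi * cs.freqs / rate
        expected = sigma**2 / np.abs(1 - a * np.exp(-1j * w)) ** 2 / rate
        got = cs.values[:, 0, 0].real
        rel = np.linalg.norm(got - expected) / np.linalg.norm(expected)
        assert rel <= 0.01

    def test_independent_channels_have_small_cross_terms(self, rng):
        es = preprocess(_white_recording(rng, duration=120.0))
        sm = compute_spatial_modes(es, 4)
        cs = mar_cross_spectra(es, sm, order=2, band=(2.0, 40.0))
        off = np.abs(cs.values - np.einsum(
            "fij,ij->fij", cs.values, np.eye(4)))
        diag = np.abs(np.einsum("fii->fi", cs.values))
        assert off.max() < 0.3 * diag.mean()
        assert np.median(off) < 0.05 * diag.mean()

    def test_output_hermitian(self, rng):
        es = preprocess(_white_recording(rng, duration=30.0))
        sm = compute_spatial_modes(es, 4)
        cs = mar_cross_spectra(es, sm, order=3, band=(2.0, 40.0))
        assert cs.is_hermitian()

    def test_invalid_band_raises(self, rng):
        es = preprocess(_white_recording(rng, duration=10.0))
        sm = compute_spatial_modes(es, 4)
        with pytest.raises(ValueError):
            mar_cross_spectra(es, sm, band=(10.0, 200.0))


class TestCounts:
    @pytest.mark.parametrize("band,df,modes,expected", [
        ((20, 48), 1.0, 8, 1856),
        ((2, 6), 1.0, 8, 320),
        ((10, 10), 1.0, 1, 1),
    ])
    def test_data_point_counts(self, band, df, modes, expected):
        assert count_data_points(band, df, modes) == expected


class TestBandPower:
    def _flat_cs(self, value=3.0):
        freqs = np.arange(1.0, 49.0)
        vals = np.tile(value * np.eye(4)[None], (len(freqs), 1, 1)).astype(complex)
        return CrossSpectra(freqs, vals)

    def test_flat_spectrum_average(self):
        assert band_power_summary(self._flat_cs(3.0), (28, 40), 0) == 3.0

    def test_single_bin(self):
        cs = self._flat_cs(1.0)
        cs.values[9, 2, 2] = 7.0
        assert band_power_summary(cs, (10, 10), 2) == 7.0

    def test_gaussian_bump_quadrature(self):
        freqs = np.arange(1.0, 49.0)
        bump = 2.0 * np.exp(-((freqs - 30) ** 2) / 18.0)
        vals = np.zeros((len(freqs), 2, 2), dtype=complex)
        vals[:, 0, 0] = bump
        cs = CrossSpectra(freqs, vals)
        sel = (freqs >= 28) & (freqs <= 40)
        assert band_power_summary(cs, (28, 40), 0) == pytest.approx(
            bump[sel].mean()
        )

    def test_bad_mode_index(self):
        with pytest.raises(IndexError):
            band_power_summary(self._flat_cs(), (28, 40), 9)


class TestGroupAnova:
    def test_identical_groups_give_zero_f(self):
        res = group_band_anova([1.0] * 6, ["a"] * 2 + ["b"] * 2 + ["c"] * 2)
        assert res["F"] == 0.0

    def test_f_matches_sum_of_squares_oracle(self):
        vals = np.array([3.1, 2.9, 3.4, 5.0, 5.2, 4.6, 1.1, 0.9, 1.3])
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = group_band_anova(vals, groups)
        # from-scratch sum-of-squares decomposition
        gm = vals.mean()
        means = [vals[i:i + 3].mean() for i in (0, 3, 6)]
        ssb = 3 * sum((m - gm) ** 2 for m in means)
        ssw = sum(((vals[i:i + 3] - vals[i:i + 3].mean()) ** 2).sum()
                  for i in (0, 3, 6))
        f_expected = (ssb / 2) / (ssw / 6)
        assert res["F"] == pytest.approx(f_expected, abs=1e-10)

    def test_shifted_group_drives_pairwise_significance(self, rng):
        base = rng.standard_normal(10) * 0.1
        vals = np.concatenate([base, base + 0.02, base + 5.0])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = group_band_anova(vals, groups)
        assert res["pairwise"][("a", "c")] < 0.05
        assert res["pairwise"][("b", "c")] < 0.05
        assert res["pairwise"][("a", "b")] > 0.05
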