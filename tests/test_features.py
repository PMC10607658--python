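"""EEG feature extraction: amplitude statistics, Hurst exponent, Welch
band power and interhemispheric asymmetry."""

import numpy as np
import pytest

from vrphobia import (
    EEGRecording,
    amplitude_features,
    hurst_exponent,
    iha,
    iha_profile,
    welch_band_power,
    welch_psd,
)
from vrphobia.montage import CHANNELS_18
from conftest import fractional_gaussian_noise, oracle_amplitude_stats


def _rec(data, fs=500.0, channels=None):
    data = np.atleast_2d(data)
    channels = channels or [f"C{i}" for i in range(len(data))]
    return EEGRecording(data=data, sampling_rate=fs, channels=channels)


class TestAmplitudeFeatures:
    def test_constant_channel(self):
        per, agg = amplitude_features(_rec(np.full((1, 100), 7.5)))
        assert per.iloc[0]["amp_max"] == 7.5
        assert per.iloc[0]["amp_mean"] == 7.5
        assert per.iloc[0]["amp_std"] == 0.0

    def test_alternating_channel_hand_computed(self):
        # [1,-1,1,-1]: max 1, mean 0, std sqrt(4/3) with the n-1 denominator
        per, _ = amplitude_features(_rec(np.array([[1.0, -1.0, 1.0, -1.0]])))
        assert per.iloc[0]["amp_max"] == 1.0
        assert per.iloc[0]["amp_mean"] == 0.0
        assert per.iloc[0]["amp_std"] == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_matches_literal_oracle_on_random_signals(self, rng):
        data = rng.normal(0, 20, size=(6, 1000))
        _, agg = amplitude_features(_rec(data))
        omax, omean, ostd = oracle_amplitude_stats(data)
        assert agg["amp_max"] == pytest.approx(omax)
        assert agg["amp_mean"] == pytest.approx(omean)
        assert agg["amp_std"] == pytest.approx(ostd)

    def test_aggregates_are_channel_means(self, rng):
        data = rng.normal(0, 5, size=(4, 500))
        per, agg = amplitude_features(_rec(data))
        assert np.allclose(agg.to_numpy(), per.mean(axis=0).to_numpy())

    def test_too_short_channel_raises(self):
        with pytest.raises(ValueError):
            amplitude_features(_rec(np.ones((1, 1))))


class TestHurstExponent:
    def test_trending_series_near_unity(self, rng):
        t = np.linspace(0.0, 1.0, 8192)
        ramp = t + 0.001 * rng.standard_normal(8192)
        assert hurst_exponent(ramp) > 0.9

    def test_fractional_gaussian_noise_recovered(self, rng):
        estimates = [hurst_exponent(fractional_gaussian_noise(0.8, 8192, rng))
                     for _ in range(10)]
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.1)

    def test_antipersistent_series_below_half(self, rng):
        estimates = [hurst_exponent(np.diff(rng.standard_normal(4097)))
                     for _ in range(10)]
        assert np.mean(estimates) < 0.5

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            hurst_exponent(np.random.default_rng(0).standard_normal(100))

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            hurst_exponent(np.ones(1024))


class TestWelchBandPower:
    def test_pure_alpha_tone_dominates_other_bands(self, rng):
        fs, n = 500.0, 30000
        t = np.arange(n) / fs
        x = 20.0 * np.sin(2 * np.pi * 10.0 * t) + 0.5 * rng.standard_normal(n)
        rec = _rec(x, fs)
        _, alpha = welch_band_power(rec, "alpha")
        _, beta = welch_band_power(rec, "beta")
        _, theta = welch_band_power(rec, "theta")
        assert alpha > 10 * beta
        assert alpha > 10 * theta

    def test_white_noise_band_means_roughly_flat(self, rng):
        fs, n = 500.0, 30000
        rates = []
        for _ in range(5):
            rec = _rec(rng.standard_normal(n), fs)
            _, lo = welch_band_power(rec, (10.0, 20.0))
            _, hi = welch_band_power(rec, (30.0, 40.0))
            rates.append(lo / hi)
        assert np.mean(rates) == pytest.approx(1.0, abs=0.2)

    def test_parseval_total_power_matches_variance(self, rng):
        fs, n = 500.0, 30000
        x = rng.standard_normal(n) * 12.0
        freqs, psd = welch_psd(_rec(x, fs))
        total = np.trapezoid(psd[0], freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_dc_offset_invariance(self, rng):
        fs, n = 500.0, 10000
        x = rng.standard_normal(n)
        rec0 = _rec(x, fs)
        rec1 = _rec(x + 250.0, fs)
        _, p0 = welch_band_power(rec0, "alpha")
        _, p1 = welch_band_power(rec1, "alpha")
        assert p0 == pytest.approx(p1, rel=1e-9)

    def test_band_outside_device_range_rejected(self, synthetic_record):
        with pytest.raises(ValueError, match="device"):
            welch_band_power(synthetic_record, (0.01, 0.3))
        with pytest.raises(ValueError, match="device"):
            welch_band_power(synthetic_record, (60.0, 90.0))

    def test_record_too_short_for_two_windows(self):
        rec = _rec(np.random.default_rng(0).standard_normal(600), 500.0)
        with pytest.raises(ValueError, match="short"):
            welch_band_power(rec, "alpha")


class TestIHA:
    @pytest.mark.parametrize("right, left, expected", [
        (2.0, 2.0, 0.0),
        (5.0, 0.0, 100.0),
        (1.0, 3.0, -50.0),
        (0.0, 5.0, -100.0),
    ])
    def test_direct_values(self, right, left, expected):
        assert iha(right, left) == pytest.approx(expected)

    def test_zero_total_power_raises(self):
        with pytest.raises(ValueError):
            iha(0.0, 0.0)

    def test_antisymmetric_and_bounded(self, rng):
        for _ in range(200):
            r, l = rng.uniform(0.0, 100.0, 2)
            if r + l == 0:
                continue
            v = iha(r, l)
            assert -100.0 <= v <= 100.0
            assert v == pytest.approx(-iha(l, r))

    def test_profile_shape_and_asymmetric_record(self, rng):
        fs, n = 500.0, 10000
        t = np.arange(n) / fs
        data = []
        for ch in CHANNELS_18:
            # plant alpha only on the left hemisphere electrodes
            amp = 15.0 if ch in ("O1", "P3", "T3", "T5", "C3", "F3", "F7", "FP1") else 2.0
            data.append(amp * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
                        + rng.standard_normal(n))
        rec = EEGRecording(np.array(data), fs, CHANNELS_18)
        prof = iha_profile(rec)
        assert prof.shape == (8, 3)
        assert (prof["alpha"] < 0).all()   # right minus left is negative
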