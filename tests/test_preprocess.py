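"""Denoising stages: frequency response, baseline removal, comb, invariants."""

import numpy as np
import pytest

from hemoppg import (
    NoiseConfig,
    NoPulseError,
    PreprocessConfig,
    Signal1D,
    TooShortError,
    comb_filter,
    estimate_period,
    generate_ppg,
    lowpass_filter,
    modulation_depth,
    preprocess_channel,
    remove_baseline,
)

FS = 100.0


def _sig(x):
    return Signal1D(np.asarray(x, dtype=float), FS)


def _tone(freq, duration=60.0, amp=1.0, phase=0.0):
    t = np.arange(int(duration * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        y = lowpass_filter(_sig(np.full(2000, 2.0))).samples
        np.testing.assert_allclose(y[300:-300], 2.0, atol=1e-6)

    def test_stopband_kills_25hz(self):
        x = _tone(25.0)
        y = lowpass_filter(_sig(x)).samples
        assert np.std(y[300:-300]) < 0.01 * np.std(x)

    def test_passband_preserves_1hz_amplitude(self):
        y = lowpass_filter(_sig(_tone(1.0))).samples
        assert np.max(np.abs(y[300:-300])) == pytest.approx(1.0, rel=0.01)

    def test_too_short_signal_rejected(self):
        with pytest.raises(TooShortError):
            lowpass_filter(_sig(np.zeros(100)))


class TestBaselineRemoval:
    def test_zero_in_zero_out(self):
        y = remove_baseline(_sig(np.zeros(3000))).samples
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_restores_drift_contaminated_ppg(self, state_normal, optics):
        """Clean pulse + 0.05 Hz drift at 5x the AC amplitude: corr >= 0.99."""
        ppg = generate_ppg(state_normal, optics, NoiseConfig.noiseless(),
                           duration=60, seed=0)
        clean = ppg.channels[:, 0]
        ac_amp = clean.max() - clean.min()
        drift = _tone(0.05, duration=60, amp=5 * ac_amp)
        out = remove_baseline(_sig(clean + drift)).samples
        corr = np.corrcoef(out, clean)[0, 1]
        assert corr >= 0.99

    def test_pure_drift_mostly_removed(self):
        x = _tone(0.05, duration=60)
        y = remove_baseline(_sig(x)).samples
        assert np.sqrt(np.mean(y**2)) <= 0.10 * np.sqrt(np.mean(x**2))

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(_sig(np.zeros(3000)),
                            PreprocessConfig(wavelet_name="nosuchwavelet"))

    def test_approximately_idempotent(self):
        rng = np.random.default_rng(0)
        x = _tone(1.2, 30) + 0.5 * _tone(0.1, 30) + 0.05 * rng.normal(size=3000)
        once = remove_baseline(_sig(x)).samples
        twice = remove_baseline(_sig(once)).samples
        rms = np.sqrt(np.mean(once**2))
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * rms


class TestPeriodEstimation:
    def test_pure_tone(self):
        period, f0 = estimate_period(_sig(_tone(1.2, 60)))
        assert f0 == pytest.approx(1.2, abs=0.02)
        assert period == round(FS / f0)

    def test_synthetic_ppg_at_72_bpm(self, state_normal, optics):
        ppg = generate_ppg(state_normal, optics, NoiseConfig.noiseless(),
                           duration=60, seed=0)
        x = remove_baseline(lowpass_filter(_sig(ppg.channels[:, 0])))
        _, f0 = estimate_period(x)
        assert f0 == pytest.approx(1.2, abs=0.05)

    def test_out_of_band_tone_rejected(self):
        x = _tone(1.2, 60) + 3.0 * _tone(0.3, 60)
        _, f0 = estimate_period(_sig(x))
        assert f0 == pytest.approx(1.2, abs=0.02)

    def test_white_noise_raises_no_pulse(self):
        rng = np.random.default_rng(1)
        with pytest.raises(NoPulseError):
            estimate_period(_sig(rng.normal(size=6000)))


class TestCombFilter:
    def test_exactly_periodic_passes_unchanged(self):
        t = np.arange(4000)
        x = np.sin(2 * np.pi * t / 80) + 0.3 * np.sin(4 * np.pi * t / 80)
        y = comb_filter(_sig(x), period=80).samples
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_white_noise_sd_halved_with_four_taps(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=40_000)
        y = comb_filter(_sig(noise), period=100, n_taps=4).samples
        interior = y[300:]
        assert np.std(interior) == pytest.approx(0.5, rel=0.05)

    def test_single_spike_attenuated_fourfold(self):
        x = np.zeros(2000)
        x[900] = 1.0
        y = comb_filter(_sig(x), period=100, n_taps=4).samples
        assert y[900] == pytest.approx(0.25, abs=1e-12)

    def test_period_too_long_rejected(self):
        with pytest.raises(TooShortError):
            comb_filter(_sig(np.zeros(200)), period=100)


class TestChainAndInvariants:
    def test_clean_channel_nearly_unchanged(self, clean_record):
        x = _sig(clean_record.ppg.channels[:, 3])
        y = preprocess_channel(x)
        assert np.corrcoef(y.samples, x.samples)[0, 1] >= 0.999

    def test_noisy_ac_dc_within_5pct_of_truth(self, state_normal, optics):
        """Full noise model: per-channel AC/DC within 5% of the generator's."""
        from hemoppg.features import record_perfusions

        ppg = generate_ppg(state_normal, optics, NoiseConfig(), duration=120, seed=5)
        r_hat = record_perfusions(ppg)
        r_true = modulation_depth(state_normal, optics)
        np.testing.assert_allclose(r_hat, r_true, rtol=0.05)

    def test_every_stage_preserves_length(self):
        rng = np.random.default_rng(3)
        for n in (2000, 3157, 6000):
            x = _sig(rng.normal(size=n) + _tone(1.1, n / FS)[:n])
            assert len(lowpass_filter(x)) == n
            assert len(remove_baseline(x)) == n
            assert len(comb_filter(x, period=83)) == n

    @pytest.mark.parametrize("op", [lowpass_filter, remove_baseline])
    def test_linearity(self, op):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 3000))
        a, b = 2.5, -1.3
        lhs = op(_sig(a * x + b * y)).samples
        rhs = a * op(_sig(x)).samples + b * op(_sig(y)).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_chain_deterministic(self, clean_record):
        x = _sig(clean_record.ppg.channels[:, 0])
        np.testing.assert_array_equal(preprocess_channel(x).samples,
                                      preprocess_channel(x).samples)
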