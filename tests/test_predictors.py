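"""Auditory-periphery predictor models: ERB scale, gammatone, IHC, adaptation."""

import numpy as np
import pytest
from scipy import signal

from subtrf.predictors import (
    adaptation_loops,
    best_circular_shift,
    erb_bandwidth,
    erb_center_frequencies,
    erb_number,
    gammatone_filterbank,
    ihc_transduction,
    make_predictor_pair,
)
from subtrf.stimulus import AudioStimulus, PolarityStimulusPair


class TestErbScale:
    def test_standard_filterbank_has_31_filters(self):
        spec = erb_center_frequencies(80.0, 8000.0, 1.0)
        assert len(spec.center_freqs) == 31
        assert spec.center_freqs[0] == 80.0
        assert spec.center_freqs[-1] <= 8000.0

    def test_degenerate_range_gives_single_frequency(self):
        spec = erb_center_frequencies(440.0, 440.0, 1.0)
        assert list(spec.center_freqs) == [440.0]

    def test_erb_number_at_1khz(self):
        # 21.4 * log10(0.00437 * 1000 + 1)
        assert erb_number(1000.0) == pytest.approx(15.62, abs=0.005)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            erb_center_frequencies(8000.0, 80.0, 1.0)

    def test_spacing_is_one_erb_number(self):
        spec = erb_center_frequencies(80.0, 8000.0, 1.0)
        steps = np.diff(erb_number(spec.center_freqs))
        np.testing.assert_allclose(steps, 1.0, atol=1e-6)


class TestGammatoneFilterbank:
    def test_band_count_matches_spec(self, short_stimulus):
        spec = erb_center_frequencies(80.0, 8000.0, 1.0)
        bands = gammatone_filterbank(short_stimulus, spec)
        assert bands.shape == (short_stimulus.samples.size, 31)

    def test_cf_tone_passes_at_unity_gain(self):
        fs, cf = 16384.0, 1000.0
        t = np.arange(int(fs)) / fs
        tone = AudioStimulus(np.sin(2 * np.pi * cf * t), fs)
        spec = erb_center_frequencies(cf, cf, 1.0)
        band = gammatone_filterbank(tone, spec)[:, 0]
        steady = band[int(0.5 * fs) :]
        gain_db = 20 * np.log10(np.sqrt(2 * np.mean(steady**2)))
        assert abs(gain_db) < 1.0

    def test_impulse_envelope_peak_near_analytic_delay(self):
        fs, cf = 16384.0, 500.0
        x = np.zeros(int(fs // 2))
        x[0] = 1.0
        band = gammatone_filterbank(
            AudioStimulus(x, fs), erb_center_frequencies(cf, cf, 1.0)
        )[:, 0]
        env = np.abs(signal.hilbert(band))
        peak_s = np.argmax(env) / fs
        expected = 3.0 / (2 * np.pi * float(erb_bandwidth(cf)))
        assert peak_s == pytest.approx(expected, rel=0.3)

    def test_low_rate_rejected(self):
        stim = AudioStimulus(np.ones(100), 4096.0)
        with pytest.raises(ValueError):
            gammatone_filterbank(stim, erb_center_frequencies(80.0, 8000.0, 1.0))


class TestIhcTransduction:
    def test_all_negative_band_zeroed(self):
        out = ihc_transduction(-np.ones((100, 2)), 16384.0)
        np.testing.assert_allclose(out, 0.0)

    def test_constant_positive_band_preserved(self):
        out = ihc_transduction(np.full((5000, 1), 0.3), 16384.0)
        assert out[-1, 0] == pytest.approx(0.3, rel=1e-3)  # unit DC gain

    def test_ripple_attenuation_matches_lowpass_response(self):
        fs, f_tone = 16384.0, 2000.0
        t = np.arange(int(fs)) / fs
        tone = np.sin(2 * np.pi * f_tone * t)[:, None]
        out = ihc_transduction(tone, fs)[int(fs / 2) :, 0]
        b, a = signal.butter(1, 1000.0, btype="lowpass", fs=fs)
        # rectified tone: DC = 1/pi, fundamental ripple amplitude = 1/2
        expected_ripple = 0.5 * abs(signal.freqz(b, a, worN=[f_tone], fs=fs)[1][0])
        spec = np.fft.rfft(out) / out.size * 2
        freqs = np.fft.rfftfreq(out.size, 1 / fs)
        ripple = abs(spec[np.argmin(abs(freqs - f_tone))])
        assert ripple == pytest.approx(expected_ripple, rel=0.05)
        assert np.mean(out) == pytest.approx(1 / np.pi, rel=0.05)


class TestAdaptationLoops:
    def test_steady_state_ratio_follows_32nd_root(self):
        fs = 8192.0
        n = int(12 * fs)
        x = np.column_stack([np.full(n, 1.0), np.full(n, 2.0**-10)])
        out = adaptation_loops(x, fs)
        ratio = out[-int(fs) :, 0].mean() / out[-int(fs) :, 1].mean()
        assert ratio == pytest.approx(1024 ** (1 / 32), rel=0.01)

    def test_zero_input_sits_at_lower_bound(self):
        out = adaptation_loops(np.zeros((2000, 1)), 8192.0, minlvl=1e-5)
        np.testing.assert_allclose(out, (1e-5) ** (1 / 32), rtol=1e-6)

    def test_onset_overshoot_is_limited(self):
        fs = 8192.0
        x = np.concatenate([np.zeros(int(fs)), np.ones(int(2 * fs))])[:, None]
        limited = adaptation_loops(x, fs, limit=10.0)
        unlimited = adaptation_loops(x, fs, limit=1.0)
        steady = limited[-100:, 0].mean()
        # soft limiter asymptote is limit + 1 relative to full-scale steady state
        assert limited.max() <= 11.0 * steady * 1.05
        assert unlimited.max() > limited.max()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            adaptation_loops(np.array([[-0.1]]), 8192.0)


class TestMakePredictorPair:
    def test_rs_is_half_wave_rectification(self):
        stim = AudioStimulus(np.array([1.0, -1.0, 2.0, -0.5] * 64), 4096.0)
        pair = make_predictor_pair(
            PolarityStimulusPair(positive=stim), "RS", 4096.0
        )
        rect = np.maximum(stim.samples, 0)
        np.testing.assert_allclose(
            pair.positive.samples, (rect) / rect.std(), rtol=1e-12
        )

    def test_rs_pair_reconstructs_magnitude(self, rng):
        x = AudioStimulus(rng.standard_normal(4096), 4096.0)
        pair = PolarityStimulusPair(positive=x)
        pos = np.maximum(pair.positive.samples, 0)
        neg = np.maximum(pair.negative.samples, 0)
        np.testing.assert_allclose(pos + neg, np.abs(x.samples))

    @pytest.mark.parametrize("kind", ["GT", "OSS", "OSSA"])
    def test_band_models_give_single_aligned_series(self, short_stimulus, kind):
        pair = make_predictor_pair(
            PolarityStimulusPair(positive=short_stimulus), kind, 4096.0
        )
        n_expected = int(round(short_stimulus.samples.size * 4096.0 / 16384.0))
        assert pair.positive.samples.shape == (n_expected,)
        assert pair.positive.samples.std() == pytest.approx(1.0, abs=1e-9)
        assert pair.negative.samples.std() == pytest.approx(1.0, abs=1e-9)
        assert pair.positive.alignment_shift == pair.negative.alignment_shift

    def test_gt_polarity_invariance(self, short_stimulus):
        pair = make_predictor_pair(
            PolarityStimulusPair(positive=short_stimulus), "GT", 4096.0
        )
        r = np.corrcoef(pair.positive.samples, pair.negative.samples)[0, 1]
        assert r > 0.99

    def test_ossa_compresses_level(self, short_stimulus):
        loud = AudioStimulus(2 * short_stimulus.samples, short_stimulus.rate_hz)
        from subtrf.predictors import _model_series

        quiet_out = _model_series(short_stimulus, "OSSA", None)
        loud_out = _model_series(loud, "OSSA", None)
        tail = slice(short_stimulus.samples.size // 2, None)
        growth = np.mean(loud_out[tail]) / np.mean(quiet_out[tail])
        assert 1.0 < growth < 2.0

    def test_alignment_recovers_artificial_delay(self, rng):
        ref = np.abs(rng.standard_normal(2048)) + 0.1 * rng.standard_normal(2048)
        delayed = np.roll(ref, 12)
        shift = best_circular_shift(delayed, ref)
        assert shift == -12
        # brute-force oracle over all circular lags
        scores = [
            np.corrcoef(np.roll(delayed, s), ref)[0, 1] for s in range(-30, 31)
        ]
        assert np.argmax(scores) - 30 == -12

    def test_unknown_kind_rejected(self, short_stimulus):
        with pytest.raises(ValueError):
            make_predictor_pair(
                PolarityStimulusPair(positive=short_stimulus), "ZIL", 4096.0
            )
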