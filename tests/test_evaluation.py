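"""Prediction scoring, LOO evaluation and wave V metrics."""

import numpy as np
import pytest

from subtrf._util import fft_filter
from subtrf.eeg import EEGSession, EEGTrial
from subtrf.evaluation import (
    SessionEvaluator,
    loo_evaluate,
    null_model_score,
    predict_and_score,
    wave_v_metrics,
)
from subtrf.predictors import Predictor, PredictorPair
from subtrf.trf import TRFWaveform, lag_axis_ms

RATE = 4096.0


def make_wave_v_trf(peak_ms=7.0, s_over_n=2.0, rate=RATE):
    """TRF covering [-500, 35] ms: unit-power noise floor, a peak window
    whose mean square is ``s_over_n``, zeros elsewhere."""
    lag = np.arange(int(-0.5 * rate), int(0.035 * rate) + 1) / rate * 1000.0
    c = np.zeros(lag.size)
    noise = (lag >= -500.0) & (lag < -20.0)
    c[noise] = 1.0
    i_peak = int(np.argmin(np.abs(lag - peak_ms)))
    win = (lag >= lag[i_peak] - 2.5 - 1e-9) & (lag < lag[i_peak] + 2.5 - 1e-9)
    c[win] = np.sqrt(s_over_n)
    c[i_peak] += 1e-9  # pin the argmax
    return TRFWaveform(c, rate, lag, stage="smoothed")


def tiny_pair(x, rate=RATE, kind="RS"):
    sd = x.std()
    return PredictorPair(
        Predictor(x / sd, rate, kind, +1), Predictor(x / sd, rate, kind, -1)
    )


class TestWaveVMetrics:
    def test_twice_noise_power_is_3db_and_detected(self):
        wv = wave_v_metrics(make_wave_v_trf(s_over_n=2.0))
        assert wv.snr_db == pytest.approx(10 * np.log10(2), abs=0.02)
        assert wv.detected
        assert 5.0 <= wv.latency_ms <= 10.0

    def test_equal_power_floors_at_zero(self):
        wv = wave_v_metrics(make_wave_v_trf(s_over_n=1.0))
        assert wv.snr_db == pytest.approx(0.0, abs=1e-6)
        assert not wv.detected
        below = wave_v_metrics(make_wave_v_trf(s_over_n=0.999))
        assert below.snr_db == 0.0  # negative raw SNR floored

    def test_ten_times_noise_is_10db(self):
        wv = wave_v_metrics(make_wave_v_trf(s_over_n=10.0))
        assert wv.snr_db == pytest.approx(10.0, abs=0.02)

    def test_scale_invariance(self):
        trf = make_wave_v_trf(s_over_n=5.0)
        a = wave_v_metrics(trf)
        scaled = TRFWaveform(123.4 * trf.coefficients, trf.rate_hz, trf.lag_ms, "smoothed")
        b = wave_v_metrics(scaled)
        assert a.snr_db == pytest.approx(b.snr_db, abs=1e-9)
        assert a.latency_ms == b.latency_ms

    def test_peak_latency_detected_within_search_window(self):
        for peak in (5.5, 7.0, 9.5):
            wv = wave_v_metrics(make_wave_v_trf(peak_ms=peak, s_over_n=8.0))
            assert wv.latency_ms == pytest.approx(peak, abs=0.25)

    def test_zero_noise_rejected(self):
        trf = make_wave_v_trf()
        trf.coefficients[trf.lag_ms < 0] = 0.0
        with pytest.raises(ValueError):
            wave_v_metrics(trf)

    def test_short_lag_axis_rejected(self):
        lag = np.arange(-100, 50) / RATE * 1000.0
        with pytest.raises(ValueError):
            wave_v_metrics(TRFWaveform(np.ones(lag.size), RATE, lag))


class TestPredictAndScore:
    def _extracted_trf(self, rng):
        lag = np.arange(int(-0.010 * RATE), int(0.030 * RATE) + 1) / RATE * 1000.0
        return TRFWaveform(rng.standard_normal(lag.size), RATE, lag, "baselined")

    def test_perfect_prediction_scores_one(self, rng):
        trf = self._extracted_trf(rng)
        x = rng.standard_normal(4 * 4096)
        pair = tiny_pair(x)
        lags = np.round(trf.lag_ms * RATE / 1000).astype(int)
        full = np.convolve(pair.mean_samples, trf.coefficients)
        t = np.arange(x.size)
        y = np.zeros(x.size)
        valid = (t >= lags[-1]) & (t <= x.size - 1 + lags[0])
        y[valid] = full[t[valid] - lags[0]]
        assert predict_and_score(trf, pair, y) == pytest.approx(1.0, abs=1e-9)
        assert predict_and_score(trf, pair, -y) == pytest.approx(-1.0, abs=1e-9)

    def test_constant_test_trial_rejected(self, rng):
        trf = self._extracted_trf(rng)
        pair = tiny_pair(rng.standard_normal(4096))
        with pytest.raises(ValueError):
            predict_and_score(trf, pair, np.ones(4096))


def _band_limited_kernel(width_ms=4.0):
    """Ground-truth kernel confined to the 30-1000 Hz analysis band, so a
    noiseless session is perfectly predictable by the post-processed TRF."""
    from scipy.signal import firwin

    from subtrf.synthetic import gen_kernel
    from subtrf.trf import smoothing_window

    k = gen_kernel(7.0, 1.0, width_ms, RATE)
    fir = firwin(4097, (30.0, 1000.0), pass_zero=False, fs=RATE)
    w = smoothing_window(RATE)
    full = np.convolve(np.convolve(k, fir), w)
    delay = 2048 + (w.size - 1) // 2
    return full[delay : delay + k.size]


def _tiny_session(rng, n_trials=4, dur_s=8.0, noise=0.05):
    """Small coherent session: y = pair_mean * kernel + noise, at 4096 Hz."""
    kernel = _band_limited_kernel()
    trials, pairs = [], []
    n = int(dur_s * RATE)
    for i in range(n_trials):
        x = np.abs(rng.standard_normal(n)) + 0.2 * rng.standard_normal(n)
        pair = tiny_pair(x)
        y = fft_filter(pair.mean_samples, kernel)[:n] + noise * rng.standard_normal(n)
        trials.append(EEGTrial(y, RATE, i))
        pairs.append(pair)
    return EEGSession(trials, "tiny", RATE), pairs


class TestLooEvaluate:
    def test_fold_count_and_minutes(self, rng):
        session, pairs = _tiny_session(rng)
        res = loo_evaluate(session, pairs, n_trials=4)
        assert res.n_trials == 4
        assert res.minutes_of_data == pytest.approx(4 * 8.0 / 60.0)
        assert -1 <= res.prediction_r <= 1

    def test_near_noiseless_session_predicts_almost_perfectly(self, rng):
        session, pairs = _tiny_session(rng, noise=1e-4)
        res = loo_evaluate(session, pairs, n_trials=3)
        assert res.prediction_r > 0.99

    def test_too_few_trials_rejected(self, rng):
        session, pairs = _tiny_session(rng, n_trials=2)
        ev = SessionEvaluator(session, pairs)
        with pytest.raises(ValueError):
            ev.loo(1)

    def test_null_model_destroys_prediction(self, rng):
        session, pairs = _tiny_session(rng, noise=0.5)
        ev = SessionEvaluator(session, pairs)
        true_r = ev.loo(4)[0]
        null_r = null_model_score(session, pairs, 4, shifts_s=(2.0, 3.0, 4.0), evaluator=ev)
        assert true_r > 0.5
        assert abs(null_r) < 0.2

    def test_excessive_shift_rejected(self, rng):
        session, pairs = _tiny_session(rng)
        ev = SessionEvaluator(session, pairs)
        with pytest.raises(ValueError):
            ev.loo(3, shift_s=100.0)


class TestRecoveryOnStudyConditions:
    """Checks on the 20-seed full-pipeline simulation records."""

    def test_latency_recovered_within_half_ms(self, recovery_study):
        errs = [
            abs(rec["latency_by_n"][8] - rec["true_peak_ms"])
            for rec in recovery_study
            if rec["snr_by_n"][8] >= 3.0
        ]
        assert np.median(errs) < 0.5

    def test_full_session_is_32_minutes(self, recovery_study):
        assert recovery_study[0]["minutes_by_n"][8] == pytest.approx(32.0)

    def test_snr_grows_with_data_length(self, recovery_study):
        from scipy.stats import spearmanr

        lengths = sorted(recovery_study[0]["snr_by_n"])
        mean_snr = [
            np.mean([rec["snr_by_n"][n] for rec in recovery_study]) for n in lengths
        ]
        rho = spearmanr(lengths, mean_snr).statistic
        assert rho > 0
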