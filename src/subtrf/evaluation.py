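"""Model evaluation: prediction correlation, null models, wave V metrics.

Model fit is quantified by leave-one-out cross-validation over trials taken
in presentation order: for each fold the TRF is fit on the training trials,
post-processed, and used to predict the held-out trial's EEG by convolution
with the polarity-averaged predictor; the Pearson correlation between
prediction and measurement, averaged over folds, is the model fit.  A noise
floor is estimated by repeating the procedure with circularly shifted
predictors (30/60/90 s), which preserves predictor statistics while
destroying stimulus-EEG alignment.

The wave V peak — the dominant brainstem component at 5-10 ms lag — is
scored on the fold-averaged TRF: signal power S is the mean square in a
5 ms window around the detected peak, noise power N the average mean-square
over contiguous 5 ms windows tiling -500 to -20 ms, and
SNR = 10 log10(S/N), floored at 0 dB, with a 3 dB detection threshold
(signal power twice the noise power).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._util import fft_filter
from .eeg import EEGSession
from .predictors import PredictorPair
from .trf import (
    TRFWaveform,
    TrialWeights,
    circular_to_lags,
    extract_and_baseline,
    smoothing_window,
)

NULL_SHIFTS_S = (30.0, 60.0, 90.0)
WAVE_V_SEARCH_MS = (5.0, 10.0)
WAVE_V_WINDOW_MS = 5.0
NOISE_RANGE_MS = (-500.0, -20.0)
DETECTION_THRESHOLD_DB = 3.0


@dataclass
class WaveVResult:
    latency_ms: float
    amplitude: float
    snr_db: float
    detected: bool


@dataclass
class EvalResult:
    predictor_kind: str
    n_trials: int
    minutes_of_data: float
    prediction_r: float
    null_r: float | None
    wave_v: WaveVResult | None


def wave_v_metrics(
    trf: TRFWaveform,
    search_ms: tuple = WAVE_V_SEARCH_MS,
    window_ms: float = WAVE_V_WINDOW_MS,
    noise_range_ms: tuple = NOISE_RANGE_MS,
    threshold_db: float = DETECTION_THRESHOLD_DB,
) -> WaveVResult:
    """Detect the wave V peak and compute its SNR on a pre-extraction TRF.

    The input must cover lags from ``noise_range_ms[0]`` to
    ``search_ms[1]`` (use the filtered/smoothed full-length TRF, not the
    extracted segment).  Ties in the peak search resolve to the earliest lag.
    """
    lag, c = trf.lag_ms, trf.coefficients
    if lag[0] > noise_range_ms[0] + 1e-9 or lag[-1] < search_ms[1] - 1e-9:
        raise ValueError("TRF lag axis does not cover the noise and search ranges")
    search = trf.window(*search_ms)
    i_rel = int(np.argmax(c[search]))
    i_peak = np.flatnonzero(search)[i_rel]
    latency = float(lag[i_peak])

    half = window_ms / 2.0
    sig = (lag >= latency - half - 1e-9) & (lag < latency + half - 1e-9)
    s_power = float(np.mean(c[sig] ** 2))

    edges = np.arange(noise_range_ms[0], noise_range_ms[1] - 1e-6 + window_ms, window_ms)
    powers = []
    for lo in edges[:-1]:
        win = (lag >= lo - 1e-9) & (lag < lo + window_ms - 1e-9)
        if np.any(win):
            powers.append(np.mean(c[win] ** 2))
    n_power = float(np.mean(powers))
    if n_power == 0:
        raise ValueError("zero noise power; degenerate TRF")

    snr_raw = 10.0 * np.log10(s_power / n_power)
    snr_db = max(0.0, float(snr_raw))

    base = trf.window(-10.0, 0.0, include_hi=False)
    baseline = float(c[base].mean()) if np.any(base) else 0.0
    return WaveVResult(
        latency_ms=latency,
        amplitude=float(c[i_peak] - baseline),
        snr_db=snr_db,
        detected=snr_db >= threshold_db,
    )


def predict_and_score(trf: TRFWaveform, pair: PredictorPair, test) -> float:
    """Pearson correlation between TRF-predicted and measured held-out EEG.

    The extracted TRF is convolved with the mean of the polarity pair;
    edge samples without full kernel support are dropped.
    """
    x = pair.mean_samples
    y = np.asarray(test.samples if hasattr(test, "samples") else test, dtype=float)
    if x.size != y.size:
        raise ValueError("predictor and test trial lengths differ")
    h = trf.coefficients
    lags = np.round(trf.lag_ms * trf.rate_hz / 1000.0).astype(int)
    l0, l1 = int(lags[0]), int(lags[-1])
    full = fft_filter(x, h)
    # prediction at time t is full[t - l0]; keep t with full kernel support
    t_lo, t_hi = max(l1, 0), y.size - 1 + min(l0, 0)
    pred = full[t_lo - l0 : t_hi - l0 + 1]
    obs = y[t_lo : t_hi + 1]
    if np.std(obs) == 0:
        raise ValueError("constant test trial; correlation undefined")
    return float(stats.pearsonr(pred, obs)[0])


def _postprocess_spectrum(n: int, rate_hz: float, band_hz, numtaps, smooth_ms):
    """rfft of the zero-phase bandpass+smoothing kernel, circularly centered."""
    fir = signal.firwin(numtaps, band_hz, pass_zero=False, fs=rate_hz)
    ker = np.convolve(fir, smoothing_window(rate_hz, smooth_ms))
    half = (ker.size - 1) // 2
    buf = np.zeros(n)
    buf[: half + 1] = ker[half:]
    buf[-half:] = ker[:half]
    return np.fft.rfft(buf)


class SessionEvaluator:
    """Cached-spectra leave-one-out evaluation of one session.

    Per-trial predictor/EEG cross- and auto-spectra are computed once;
    circular predictor shifts for null models become phase ramps, and the
    TRF post-processing (zero-phase 30-1000 Hz FIR + 2 ms Hamming) is
    applied as a spectral gain, which matches the delay-compensated
    time-domain filters everywhere away from the +/-T/2 lag edges.
    """

    def __init__(
        self,
        session: EEGSession,
        pairs: list,
        band_hz: tuple = (30.0, 1000.0),
        numtaps: int = 4097,
        smooth_ms: float = 2.0,
    ):
        if len(pairs) != len(session.trials):
            raise ValueError("need one predictor pair per trial")
        self.rate = session.rate_hz
        self.trials = session.trials
        self.pairs = pairs
        self.n = session.trials[0].samples.size
        for t, p in zip(session.trials, pairs):
            if t.samples.size != self.n or p.positive.samples.size != self.n:
                raise ValueError("trials and predictors must share one length")
        self.variances = np.array([t.variance for t in session.trials])
        self.cross = []  # per trial: {+1, -1} -> conj(X) * Y
        self.auto = []  # per trial: {+1, -1} -> |X|^2
        for t, p in zip(session.trials, pairs):
            Y = np.fft.rfft(t.samples)
            cr, au = {}, {}
            for pol, pred in ((+1, p.positive), (-1, p.negative)):
                X = np.fft.rfft(pred.samples)
                cr[pol] = np.conj(X) * Y
                au[pol] = (np.conj(X) * X).real
            self.cross.append(cr)
            self.auto.append(au)
        self.k_bins = np.arange(self.n // 2 + 1)
        self.post = _postprocess_spectrum(self.n, self.rate, band_hz, numtaps, smooth_ms)

    def _ramp(self, shift_samples: int):
        if shift_samples == 0:
            return 1.0
        return np.exp(2j * np.pi * self.k_bins * shift_samples / self.n)

    def _fold_spectrum(self, train: list, shift_samples: int):
        """Polarity-averaged post-processed TRF spectrum for one fold."""
        w = 1.0 / self.variances[train]
        w = w / w.sum()
        ramp = self._ramp(shift_samples)
        spec = np.zeros(self.n // 2 + 1, dtype=complex)
        for pol in (+1, -1):
            num = np.zeros(self.n // 2 + 1, dtype=complex)
            den = np.zeros(self.n // 2 + 1)
            for wi, i in zip(w, train):
                num += wi * self.cross[i][pol]
                den += self.auto[i][pol]
            den /= len(train)
            den += 1e-10 * den.mean()
            spec += (num * ramp) / den
        return 0.5 * spec * self.post

    def loo(
        self,
        n_trials: int,
        shift_s: float = 0.0,
        extract_ms: tuple = (-10.0, 30.0),
    ) -> tuple:
        """LOO fit over the first ``n_trials`` trials (presentation order).

        Returns ``(mean_prediction_r, fold_averaged_smoothed_trf)``.
        """
        if n_trials < 2 or n_trials > len(self.trials):
            raise ValueError("need 2 <= n_trials <= available trials")
        m = int(round(shift_s * self.rate))
        if m >= self.n:
            raise ValueError("shift must be shorter than the trial")
        rs = []
        spec_sum = np.zeros(self.n // 2 + 1, dtype=complex)
        for test in range(n_trials):
            train = [i for i in range(n_trials) if i != test]
            spec = self._fold_spectrum(train, m)
            spec_sum += spec
            trf = circular_to_lags(np.fft.irfft(spec, self.n), self.rate, "smoothed")
            extracted = extract_and_baseline(trf, window_ms=extract_ms)
            pair = self.pairs[test]
            if m:
                from dataclasses import replace

                pair = PredictorPair(
                    replace(pair.positive, samples=np.roll(pair.positive.samples, m)),
                    replace(pair.negative, samples=np.roll(pair.negative.samples, m)),
                )
            rs.append(predict_and_score(extracted, pair, self.trials[test]))
        mean_trf = circular_to_lags(
            np.fft.irfft(spec_sum / n_trials, self.n), self.rate, "smoothed"
        )
        return float(np.mean(rs)), mean_trf


def loo_evaluate(
    session: EEGSession,
    pairs: list,
    n_trials: int,
    evaluator: SessionEvaluator | None = None,
) -> EvalResult:
    """Leave-one-out evaluation at one data length, with wave V metrics."""
    ev = evaluator or SessionEvaluator(session, pairs)
    r, mean_trf = ev.loo(n_trials)
    return EvalResult(
        predictor_kind=pairs[0].positive.kind,
        n_trials=n_trials,
        minutes_of_data=n_trials * ev.n / ev.rate / 60.0,
        prediction_r=r,
        null_r=None,
        wave_v=wave_v_metrics(mean_trf),
    )


def null_model_score(
    session: EEGSession,
    pairs: list,
    n_trials: int,
    shifts_s: tuple = NULL_SHIFTS_S,
    evaluator: SessionEvaluator | None = None,
) -> float:
    """Mean LOO prediction correlation over circularly shifted predictors."""
    ev = evaluator or SessionEvaluator(session, pairs)
    rs = [ev.loo(n_trials, shift_s=s)[0] for s in shifts_s]
    return float(np.mean(rs))


def trial_weights_for(session: EEGSession, n_trials: int | None = None) -> TrialWeights:
    """Inverse-variance weights over the first ``n_trials`` trials."""
    trials = session.trials[: n_trials or len(session.trials)]
    from .trf import compute_trial_weights

    return compute_trial_weights(trials)
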