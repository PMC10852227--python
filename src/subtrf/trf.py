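"""Temporal response function estimation by frequency-domain deconvolution.

The TRF is the least-squares kernel relating a stimulus-derived predictor
``x_i`` to the EEG ``y_i`` over trials ``i``.  It is computed in closed form
in the frequency domain as

    TRF = IFFT( sum_i w_i X_i* Y_i  /  (1/N) sum_i X_i* X_i )

where ``X_i`` and ``Y_i`` are Fourier transforms, ``*`` is complex
conjugation and ``w_i`` are inverse-variance trial weights normalised to sum
to one.  The approach is unregularised apart from a tiny numerical floor on
the denominator; the resulting circular kernel is laid out on a lag axis
from -T/2 to T/2.  Post-processing bandpasses the TRF to 30-1000 Hz with a
delay-compensated linear-phase FIR, smooths with a unit-sum 2 ms Hamming
window, extracts the [-10, 30] ms segment and subtracts the mean of the
[-10, 0) ms baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from ._util import fft_filter

DENOMINATOR_FLOOR = 1e-10


@dataclass
class TRFWaveform:
    """A TRF on an ascending lag axis (milliseconds)."""

    coefficients: np.ndarray
    rate_hz: float
    lag_ms: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.lag_ms = np.asarray(self.lag_ms, dtype=float)
        if self.coefficients.shape != self.lag_ms.shape:
            raise ValueError("coefficients and lag axis differ in length")

    def window(self, lo_ms: float, hi_ms: float, include_hi: bool = True):
        """Boolean mask selecting lags in [lo_ms, hi_ms] (or [lo, hi))."""
        eps = 1e-9
        m = self.lag_ms >= lo_ms - eps
        m &= (self.lag_ms <= hi_ms + eps) if include_hi else (self.lag_ms < hi_ms - eps)
        return m

    @property
    def peak_lag_ms(self) -> float:
        return float(self.lag_ms[int(np.argmax(self.coefficients))])


@dataclass
class TrialWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def compute_trial_weights(trials) -> TrialWeights:
    """Inverse-variance weights, normalised to sum to one across trials.

    ``trials`` may be :class:`~subtrf.eeg.EEGTrial` objects or plain arrays.
    """
    variances = np.array(
        [t.variance if hasattr(t, "variance") else np.var(np.asarray(t)) for t in trials]
    )
    if np.any(variances <= 0):
        raise ValueError("every trial must have positive variance")
    inv = 1.0 / variances
    return TrialWeights(inv / inv.sum())


def _as_array(obj) -> np.ndarray:
    return np.asarray(obj.samples if hasattr(obj, "samples") else obj, dtype=float)


def lag_axis_ms(n: int, rate_hz: float) -> np.ndarray:
    """Ascending lag axis for an n-point circular TRF: -T/2..T/2 (ms)."""
    n_neg = (n - 1) // 2
    return (np.arange(n) - n_neg) * 1000.0 / rate_hz


def circular_to_lags(h: np.ndarray, rate_hz: float, stage: str = "raw") -> TRFWaveform:
    """Reorder an inverse-FFT kernel (index k = lag k mod T) onto -T/2..T/2."""
    n = h.size
    n_neg = (n - 1) // 2
    return TRFWaveform(np.roll(h, n_neg), rate_hz, lag_axis_ms(n, rate_hz), stage)


def estimate_trf_spectrum(
    num: np.ndarray, den: np.ndarray, n: int, rate_hz: float
) -> TRFWaveform:
    """Invert accumulated cross-/auto-spectra into a lag-domain TRF."""
    den = den + DENOMINATOR_FLOOR * float(np.mean(den))
    h = np.fft.irfft(num / den, n)
    return circular_to_lags(h, rate_hz)


def estimate_trf(predictors, trials, weights: TrialWeights) -> TRFWaveform:
    """Closed-form weighted frequency-domain TRF over a set of trials."""
    xs = [_as_array(p) for p in predictors]
    ys = [_as_array(t) for t in trials]
    if len(xs) != len(ys) or len(xs) == 0:
        raise ValueError("need equal, non-zero numbers of predictors and trials")
    n = xs[0].size
    for x, y in zip(xs, ys):
        if x.size != n or y.size != n:
            raise ValueError("all trials and predictors must share one length")
    if any(not np.any(x) for x in xs):
        raise ValueError("all-zero predictor")
    w = weights.w
    if w.size != len(xs):
        raise ValueError("one weight per trial required")
    rate = getattr(predictors[0], "rate_hz", getattr(trials[0], "rate_hz", 1.0))
    num = np.zeros(n // 2 + 1, dtype=complex)
    den = np.zeros(n // 2 + 1)
    for x, y, wi in zip(xs, ys, w):
        X = np.fft.rfft(x)
        num += wi * np.conj(X) * np.fft.rfft(y)
        den += (np.conj(X) * X).real
    den /= len(xs)
    return estimate_trf_spectrum(num, den, n, rate)


def combine_polarity_trfs(trf_pos: TRFWaveform, trf_neg: TRFWaveform) -> TRFWaveform:
    """Average the TRFs fit to the positive- and negative-polarity predictors."""
    if trf_pos.lag_ms.shape != trf_neg.lag_ms.shape or not np.allclose(
        trf_pos.lag_ms, trf_neg.lag_ms
    ):
        raise ValueError("lag axes do not match")
    return replace(
        trf_pos, coefficients=0.5 * (trf_pos.coefficients + trf_neg.coefficients)
    )


def average_trfs(trfs) -> TRFWaveform:
    """Mean of several TRFs on identical axes (e.g. across CV folds)."""
    first = trfs[0]
    for t in trfs[1:]:
        if not np.allclose(t.lag_ms, first.lag_ms):
            raise ValueError("lag axes do not match")
    return replace(
        first, coefficients=np.mean([t.coefficients for t in trfs], axis=0)
    )


def smoothing_window(rate_hz: float, width_ms: float = 2.0) -> np.ndarray:
    """Unit-sum Hamming window of ~width_ms, odd length for zero phase."""
    n = int(round(width_ms * rate_hz / 1000.0))
    n += 1 - n % 2  # nearest odd
    n = max(n, 3)
    w = np.hamming(n)
    return w / w.sum()


def bandpass_smooth(
    trf: TRFWaveform,
    band_hz: tuple = (30.0, 1000.0),
    numtaps: int = 4097,
    smooth_width_ms: float = 2.0,
) -> TRFWaveform:
    """30-1000 Hz linear-phase FIR bandpass + 2 ms Hamming smoothing.

    Both operations are delay compensated, so lags are preserved.
    """
    h = signal.firwin(numtaps, band_hz, pass_zero=False, fs=trf.rate_hz)
    x = trf.coefficients
    y = fft_filter(x, h, delay=(numtaps - 1) // 2)
    w = smoothing_window(trf.rate_hz, smooth_width_ms)
    y = fft_filter(y, w, delay=(w.size - 1) // 2)
    return replace(trf, coefficients=y, stage="smoothed")


def extract_and_baseline(
    trf: TRFWaveform,
    window_ms: tuple = (-10.0, 30.0),
    baseline_ms: tuple = (-10.0, 0.0),
) -> TRFWaveform:
    """Extract [-10, 30] ms and subtract the mean of the [-10, 0) ms baseline."""
    keep = trf.window(*window_ms)
    if not np.any(keep):
        raise ValueError("extraction window not covered by the lag axis")
    base = trf.window(baseline_ms[0], baseline_ms[1], include_hi=False)
    baseline = float(trf.coefficients[base].mean()) if np.any(base) else 0.0
    return TRFWaveform(
        trf.coefficients[keep] - baseline,
        trf.rate_hz,
        trf.lag_ms[keep],
        stage="baselined",
    )


def postprocess_trf(trf: TRFWaveform, **kwargs) -> TRFWaveform:
    """Full post-processing: bandpass, smooth, extract, baseline-subtract."""
    span_ms = trf.lag_ms[-1] - trf.lag_ms[0]
    if span_ms < 80.0:
        raise ValueError(f"TRF spans only {span_ms:.1f} ms; need >= 80 ms")
    return extract_and_baseline(bandpass_smooth(trf, **kwargs))
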