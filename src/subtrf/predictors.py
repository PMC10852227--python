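"""Stimulus-derived predictors for subcortical TRF estimation.

Four predictor families of increasing peripheral realism are supported, each
computed for both members of a polarity pair and resampled to the EEG rate:

``RS``
    half-wave rectified speech waveform — the coarsest model of cochlear
    rectification;
``GT``
    mean across bands of the absolute output of a gammatone filterbank
    (31 filters, 80-8000 Hz, spaced 1 ERB apart);
``OSS``
    gammatone filterbank followed by an inner-hair-cell stage (half-wave
    rectification + lowpass), band-averaged;
``OSSA``
    as OSS, with five cascaded divisive adaptation loops per band before
    band averaging — the adaptation stage compresses steady-state level to
    roughly the 1/32 power of the input.

Model-inherent lags are removed by circularly shifting each predictor to the
lag that maximises its correlation with the rectified-speech predictor, and
each predictor is scaled to unit variance so TRF amplitudes are comparable
across models.  An ``EXTERNAL`` kind wraps precomputed predictor series
(e.g. mean auditory-nerve firing rates from a complex periphery model).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import signal

from .stimulus import AudioStimulus, PolarityStimulusPair

KINDS = ("RS", "GT", "OSS", "OSSA", "EXTERNAL")

#: adaptation-loop time constants, seconds (5 divisive feedback loops)
ADAPTATION_TAUS_S = (0.005, 0.050, 0.129, 0.253, 0.500)
ADAPTATION_LIMIT = 10.0
ADAPTATION_MINLVL = 1e-5


@dataclass
class Predictor:
    """A single-polarity predictor series at the EEG sampling rate."""

    samples: np.ndarray
    rate_hz: float
    kind: str
    polarity: int  # +1 or -1
    alignment_shift: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("predictor contains non-finite samples")
        if self.kind not in KINDS:
            raise ValueError(f"unknown predictor kind {self.kind!r}")


@dataclass
class PredictorPair:
    positive: Predictor
    negative: Predictor

    def __post_init__(self) -> None:
        if self.positive.kind != self.negative.kind:
            raise ValueError("polarity pair must share a model kind")
        if self.positive.samples.size != self.negative.samples.size:
            raise ValueError("polarity pair must share a length")

    @property
    def mean_samples(self) -> np.ndarray:
        return 0.5 * (self.positive.samples + self.negative.samples)


@dataclass
class FilterbankSpec:
    f_lo: float
    f_hi: float
    spacing_erb: float
    center_freqs: np.ndarray

    def __post_init__(self) -> None:
        cf = np.asarray(self.center_freqs, dtype=float)
        if np.any(np.diff(cf) <= 0):
            raise ValueError("center frequencies must be strictly increasing")
        self.center_freqs = cf


def erb_number(f_hz):
    """ERB-number (Cam) scale: 21.4 * log10(0.00437 f + 1)."""
    return 21.4 * np.log10(0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


def erb_number_to_hz(e):
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth of the auditory filter at ``f_hz``."""
    return 24.7 * (0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


def erb_center_frequencies(
    f_lo: float, f_hi: float, spacing: float = 1.0
) -> FilterbankSpec:
    """Center frequencies from ``f_lo`` up to ``f_hi``, stepped on the ERB scale."""
    if not (0 < f_lo <= f_hi):
        raise ValueError("need 0 < f_lo <= f_hi")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    e_lo, e_hi = erb_number(f_lo), erb_number(f_hi)
    # tiny tolerance so f_hi itself is kept when it falls on the grid
    numbers = np.arange(e_lo, e_hi + 1e-9, spacing)
    cfs = erb_number_to_hz(numbers)
    cfs[0] = f_lo
    cfs = np.minimum(cfs, f_hi)
    return FilterbankSpec(f_lo=f_lo, f_hi=f_hi, spacing_erb=spacing, center_freqs=cfs)


DEFAULT_FILTERBANK = (80.0, 8000.0, 1.0)


def gammatone_filterbank(x: AudioStimulus, spec: FilterbankSpec) -> np.ndarray:
    """Apply a 4th-order gammatone filterbank; returns (n_samples, n_bands).

    Each band has unity gain at its center frequency.
    """
    if x.rate_hz < 2 * spec.center_freqs[-1]:
        raise ValueError(
            f"rate {x.rate_hz} Hz too low for highest band "
            f"{spec.center_freqs[-1]:.0f} Hz"
        )
    out = np.empty((x.samples.size, spec.center_freqs.size))
    for j, cf in enumerate(spec.center_freqs):
        b, a = signal.gammatone(cf, "iir", fs=x.rate_hz)
        out[:, j] = signal.lfilter(b, a, x.samples)
    return out


def ihc_transduction(
    bands: np.ndarray, rate_hz: float, lp_hz: float = 1000.0
) -> np.ndarray:
    """Inner-hair-cell stage: half-wave rectification then 1st-order lowpass."""
    bands = np.asarray(bands, dtype=float)
    if not np.all(np.isfinite(bands)):
        raise ValueError("non-finite band input")
    rect = np.maximum(bands, 0.0)
    b, a = signal.butter(1, lp_hz, btype="lowpass", fs=rate_hz)
    return signal.lfilter(b, a, rect, axis=0)


def _adapt_numpy(x, coef, state, limit):
    factor = limit * 2.0
    expfac = -2.0 / (limit - 1.0) if limit > 1.0 else 0.0
    offset = limit - 1.0
    out = np.empty_like(x)
    for t in range(x.shape[0]):
        tmp = x[t].copy()
        for i in range(state.shape[0]):
            tmp = tmp / state[i]
            if limit > 1.0:
                hot = tmp > 1.0
                if np.any(hot):
                    tmp[hot] = factor / (1.0 + np.exp(expfac * (tmp[hot] - 1.0))) - offset
            state[i] += (1.0 - coef[i]) * (tmp - state[i])
        out[t] = tmp
    return out


@lru_cache(maxsize=1)
def _adapt_kernel():
    """Compiled per-sample adaptation recursion (falls back to numpy)."""
    try:
        from numba import njit
    except Exception:  # pragma: no cover - numba present in normal installs
        return _adapt_numpy

    @njit(cache=True)
    def core(x, coef, state, limit):
        nloops = state.shape[0]
        factor = limit * 2.0
        expfac = -2.0 / (limit - 1.0) if limit > 1.0 else 0.0
        offset = limit - 1.0
        out = np.empty_like(x)
        for t in range(x.shape[0]):
            for b in range(x.shape[1]):
                tmp = x[t, b]
                for i in range(nloops):
                    tmp = tmp / state[i, b]
                    if limit > 1.0 and tmp > 1.0:
                        tmp = factor / (1.0 + np.exp(expfac * (tmp - 1.0))) - offset
                    state[i, b] += (1.0 - coef[i]) * (tmp - state[i, b])
                out[t, b] = tmp
        return out

    return core


def adaptation_loops(
    bands: np.ndarray,
    rate_hz: float,
    taus_s: tuple = ADAPTATION_TAUS_S,
    limit: float = ADAPTATION_LIMIT,
    minlvl: float = ADAPTATION_MINLVL,
) -> np.ndarray:
    """Five cascaded divisive adaptation loops per band.

    Each loop divides its input by a lowpass-filtered copy of its own output
    (time constants ``taus_s``), with a soft overshoot limiter that caps
    onset transients at roughly ``limit`` times the full-scale steady state.
    For a constant input *I* (relative to full scale 1.0, floored at
    ``minlvl``), the steady-state output is proportional to ``I**(1/32)``.
    """
    bands = np.asarray(bands, dtype=float)
    squeeze = bands.ndim == 1
    if squeeze:
        bands = bands[:, None]
    if np.any(bands < 0):
        raise ValueError("adaptation input must be non-negative (post-IHC)")
    x = np.maximum(bands, minlvl)
    nloops = len(taus_s)
    coef = np.exp(-1.0 / (np.asarray(taus_s) * rate_hz))
    # start each loop in the steady state reached for the minimum input
    state = np.empty((nloops, x.shape[1]))
    for i in range(nloops):
        state[i] = minlvl ** (1.0 / 2 ** (i + 1))
    out = _adapt_kernel()(x, coef, state, float(limit))
    return out[:, 0] if squeeze else out


def _model_series(x: AudioStimulus, kind: str, fb: FilterbankSpec | None) -> np.ndarray:
    if kind == "RS":
        return np.maximum(x.samples, 0.0)
    if fb is None:
        fb = erb_center_frequencies(*DEFAULT_FILTERBANK)
    bands = gammatone_filterbank(x, fb)
    if kind == "GT":
        return np.abs(bands).mean(axis=1)
    ihc = ihc_transduction(bands, x.rate_hz)
    if kind == "OSS":
        return ihc.mean(axis=1)
    if kind == "OSSA":
        return adaptation_loops(ihc, x.rate_hz).mean(axis=1)
    raise ValueError(f"unknown predictor kind {kind!r}")


def resample_to_rate(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Anti-aliased rational resampling; output length round(n*rate_out/rate_in)."""
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator)
    target = int(round(x.shape[0] * rate_out / rate_in))
    if y.shape[0] > target:
        y = y[:target]
    elif y.shape[0] < target:
        y = np.pad(y, (0, target - y.shape[0]))
    return y


def best_circular_shift(x: np.ndarray, reference: np.ndarray) -> int:
    """Signed circular shift of ``x`` maximising correlation with ``reference``."""
    if x.size != reference.size:
        raise ValueError("length mismatch")
    n = x.size
    xf = np.fft.rfft(x - x.mean())
    rf = np.fft.rfft(reference - reference.mean())
    cc = np.fft.irfft(rf * np.conj(xf), n)
    s = int(np.argmax(cc))
    return s - n if s > n // 2 else s


def make_predictor_pair(
    pair: PolarityStimulusPair,
    kind: str,
    eeg_rate: float,
    rs_reference: Predictor | None = None,
    filterbank: FilterbankSpec | None = None,
) -> PredictorPair:
    """Compute a predictor pair at the EEG rate, aligned and variance-normalised.

    Non-RS predictors are circularly shifted by the integer lag (at the EEG
    rate) that maximises their correlation with the rectified-speech
    predictor of the same stimulus, removing model-inherent delays.
    """
    kind = kind.upper()
    if kind not in ("RS", "GT", "OSS", "OSSA"):
        raise ValueError(f"unknown predictor kind {kind!r}")

    series = {}
    for pol, stim in ((+1, pair.positive), (-1, pair.negative)):
        raw = _model_series(stim, kind, filterbank)
        series[pol] = resample_to_rate(raw, stim.rate_hz, eeg_rate)

    shift = 0
    if kind != "RS":
        if rs_reference is not None:
            ref = rs_reference.samples
        else:
            ref = resample_to_rate(
                np.maximum(pair.positive.samples, 0.0), pair.positive.rate_hz, eeg_rate
            )
        shift = best_circular_shift(series[+1], ref)

    preds = {}
    for pol in (+1, -1):
        s = np.roll(series[pol], shift) if shift else series[pol]
        sd = s.std()
        if sd == 0:
            raise ValueError("predictor is constant; cannot normalise")
        preds[pol] = Predictor(
            samples=(s - 0.0) / sd,
            rate_hz=eeg_rate,
            kind=kind,
            polarity=pol,
            alignment_shift=shift,
        )
    return PredictorPair(positive=preds[+1], negative=preds[-1])


def external_predictor_pair(
    positive: np.ndarray,
    negative: np.ndarray,
    rate_in: float,
    eeg_rate: float,
    rs_reference: Predictor | None = None,
) -> PredictorPair:
    """Adapter for predictors computed outside this package.

    Accepts a precomputed series per polarity (e.g. band-averaged mean firing
    rates from an auditory-nerve model), resamples to the EEG rate, aligns to
    the rectified-speech reference when given, and variance-normalises —
    exactly the treatment the built-in kinds receive.
    """
    pos = resample_to_rate(np.asarray(positive, float), rate_in, eeg_rate)
    neg = resample_to_rate(np.asarray(negative, float), rate_in, eeg_rate)
    if pos.size != neg.size:
        raise ValueError("polarity series must have equal length")
    shift = 0
    if rs_reference is not None:
        shift = best_circular_shift(pos, rs_reference.samples)
        pos, neg = np.roll(pos, shift), np.roll(neg, shift)
    out = []
    for pol, s in ((+1, pos), (-1, neg)):
        sd = s.std()
        if sd == 0:
            raise ValueError("predictor is constant; cannot normalise")
        out.append(
            Predictor(s / sd, eeg_rate, "EXTERNAL", pol, alignment_shift=shift)
        )
    return PredictorPair(positive=out[0], negative=out[1])
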