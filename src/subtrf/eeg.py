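"""Single-channel EEG preprocessing for subcortical TRF analysis.

The chain mirrors standard ABR-style preprocessing of continuous EEG:
a causal first-order 1 Hz Butterworth highpass, linear-phase FIR notch
filters at all multiples of 50 Hz up to 1000 Hz (5 Hz wide, delay
compensated), anti-aliased downsampling to 4096 Hz, zeroing of 1 s windows
around high-amplitude artifacts, and trimming each trial to its central
2-242 s so every trial contributes the same 240 s of data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from ._util import fft_filter
from .predictors import resample_to_rate

ANALYSIS_RATE_HZ = 4096.0


@dataclass
class EEGTrial:
    """One preprocessed EEG trial (microvolts) with its quality metadata."""

    samples: np.ndarray
    rate_hz: float
    trial_index: int = 0
    weight: float | None = None
    zeroed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG trial contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def variance(self) -> float:
        return float(np.var(self.samples))


@dataclass
class EEGSession:
    """Ordered trials from one participant at a common rate."""

    trials: list
    participant_id: str = ""
    rate_hz: float = ANALYSIS_RATE_HZ

    def __post_init__(self) -> None:
        for t in self.trials:
            if t.rate_hz != self.rate_hz:
                raise ValueError("all trials must share the session rate")

    def __len__(self) -> int:
        return len(self.trials)


@lru_cache(maxsize=8)
def _notch_comb_fir(
    rate_hz: float, f_max: float = 1000.0, f_step: float = 50.0, width_hz: float = 5.0
) -> np.ndarray:
    """Linear-phase FIR combining all 50 Hz-harmonic notches up to ``f_max``.

    Designed by frequency sampling (firwin2) with each notch reaching -6 dB
    at +/- width/2 from its center.  One long symmetric filter covers every
    harmonic, so a single delay-compensated convolution applies the cascade.
    """
    numtaps = int(round(1.8 * rate_hz))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    half = width_hz / 2.0
    # desired gain ramps 1 -> 0 between f0 +/- 0.8*width and f0 +/- 0.2*width,
    # crossing 0.5 (-6 dB) at f0 +/- width/2
    plateau, ramp = 0.2 * width_hz, 0.8 * width_hz
    freqs = [0.0]
    gains = [1.0]
    for f0 in np.arange(f_step, f_max + 1e-6, f_step):
        freqs += [f0 - ramp, f0 - plateau, f0 + plateau, f0 + ramp]
        gains += [1.0, 0.0, 0.0, 1.0]
    freqs += [rate_hz / 2.0]
    gains += [1.0]
    return signal.firwin2(
        numtaps, freqs, gains, nfreqs=1 << 17, fs=rate_hz, window="hamming"
    )


def notch_filter(x: np.ndarray, rate_hz: float, f_max: float = 1000.0,
                 width_hz: float = 5.0) -> np.ndarray:
    """Apply the 50 Hz-harmonic notch comb with group-delay compensation."""
    h = _notch_comb_fir(float(rate_hz), float(f_max), width_hz=float(width_hz))
    return fft_filter(x, h, delay=(h.size - 1) // 2)


def preprocess_eeg(
    raw: np.ndarray,
    rate_in: float,
    out_rate: float = ANALYSIS_RATE_HZ,
    hp_hz: float = 1.0,
    notch_max_hz: float = 1000.0,
    trial_index: int = 0,
    zero_phase_hp: bool = False,
) -> EEGTrial:
    """Highpass, notch and downsample one raw EEG trial.

    ``rate_in`` must be at least twice the analysis rate; the highpass is a
    causal first-order Butterworth at 1 Hz (set ``zero_phase_hp`` for
    filtfilt), followed by the notch comb and anti-aliased resampling.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw EEG must be a non-empty 1-D series")
    if rate_in < 2 * out_rate:
        raise ValueError(
            f"input rate {rate_in} Hz must be >= {2 * out_rate:.0f} Hz"
        )
    b, a = signal.butter(1, hp_hz, btype="highpass", fs=rate_in)
    x = signal.filtfilt(b, a, raw) if zero_phase_hp else signal.lfilter(b, a, raw)
    x = notch_filter(x, rate_in, f_max=notch_max_hz)
    x = resample_to_rate(x, rate_in, out_rate)
    return EEGTrial(x, out_rate, trial_index=trial_index)


def suppress_artifacts(
    trial: EEGTrial,
    n_sd: float = 5.0,
    window_s: float = 1.0,
    two_sided: bool = True,
) -> EEGTrial:
    """Zero 1 s windows centered on samples beyond ``n_sd`` SDs from the mean.

    Mean and SD are computed once over the whole trial before any zeroing.
    A zero-variance trial is returned unchanged.
    """
    x = trial.samples
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return EEGTrial(x.copy(), trial.rate_hz, trial.trial_index,
                        zeroed_mask=np.zeros(x.size, dtype=bool))
    dev = x - mu
    flags = np.abs(dev) > n_sd * sd if two_sided else dev > n_sd * sd
    mask = np.zeros(x.size, dtype=bool)
    idx = np.flatnonzero(flags)
    if idx.size:
        half = int(round(window_s * trial.rate_hz / 2))
        # union of windows via an event-count sweep
        delta = np.zeros(x.size + 1, dtype=int)
        starts = np.clip(idx - half, 0, x.size)
        ends = np.clip(idx + half + 1, 0, x.size)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        mask = np.cumsum(delta[:-1]) > 0
    out = x.copy()
    out[mask] = 0.0
    return EEGTrial(out, trial.rate_hz, trial.trial_index, zeroed_mask=mask)


def trim_trial(trial: EEGTrial, start_s: float = 2.0, end_s: float = 242.0) -> EEGTrial:
    """Keep the ``[start_s, end_s)`` span of a trial (default 240 s)."""
    n_start = int(round(start_s * trial.rate_hz))
    n_end = int(round(end_s * trial.rate_hz))
    if trial.samples.size < n_end:
        raise ValueError(
            f"trial is {trial.duration_s:.1f} s, shorter than end={end_s} s"
        )
    mask = trial.zeroed_mask[n_start:n_end] if trial.zeroed_mask is not None else None
    return EEGTrial(
        trial.samples[n_start:n_end].copy(),
        trial.rate_hz,
        trial.trial_index,
        weight=trial.weight,
        zeroed_mask=mask,
    )


def read_bdf_channel(path, channel: str = "Cz", refs=("M1", "M2")):
    """Read one referenced channel from a BioSemi BDF file.

    Returns ``(samples_uV, rate_hz)`` for ``channel`` minus the mean of the
    reference channels.  Requires :mod:`mne`.
    """
    import mne

    raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    picks = [channel, *refs]
    missing = [ch for ch in picks if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"channels not found in BDF: {missing}")
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    referenced = data[0] - data[1:].mean(axis=0)
    return referenced, float(raw.info["sfreq"])


def read_text_eeg(path):
    """Read a one-column EEG text file with a ``# rate_hz: <value>`` header."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# rate_hz:"):
            raise ValueError("missing '# rate_hz:' header line")
        rate = float(first.split(":", 1)[1])
        data = np.loadtxt(fh)
    return np.atleast_1d(data).astype(float), rate


def write_text_eeg(path, samples: np.ndarray, rate_hz: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rate_hz: {rate_hz}\n")
        np.savetxt(fh, np.asarray(samples, dtype=float), fmt="%.8g")
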