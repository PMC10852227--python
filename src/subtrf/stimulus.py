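"""Speech stimulus loading and preconditioning.

The audio chain mirrors a typical subcortical-TRF experiment: the (possibly
stereo) speech recording is mixed down to mono, gently highpass filtered at
1 kHz with a first-order Butterworth filter to emphasise the frequencies
that drive the brainstem most strongly, and calibrated to a target r.m.s.
level against speech-shaped noise.  Finally a polarity pair (original and
sign-inverted waveform) is formed, the continuous-speech analogue of
alternating-polarity click presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclass
class AudioStimulus:
    """A single-channel pressure waveform in arbitrary digital units."""

    samples: np.ndarray
    rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("stimulus must be a non-empty 1-D waveform")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class PolarityStimulusPair:
    """Original (+) and sign-inverted (-) copies of one stimulus."""

    positive: AudioStimulus
    negative: AudioStimulus = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.negative is None:
            self.negative = AudioStimulus(
                -self.positive.samples,
                self.positive.rate_hz,
                label=self.positive.label + "-inv",
            )


def preprocess_stimulus(
    raw: np.ndarray, rate_hz: float, hp_hz: float = 1000.0, label: str = ""
) -> AudioStimulus:
    """Mix to mono and apply the first-order 1 kHz Butterworth highpass.

    ``raw`` may be 1-D (mono) or 2-D with channels along the second axis.
    The filter is applied causally (forward only), as during presentation.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty audio input")
    if raw.ndim == 2:
        mono = raw.mean(axis=1)
    elif raw.ndim == 1:
        mono = raw
    else:
        raise ValueError("audio must be 1-D or 2-D (samples x channels)")
    if rate_hz <= 2 * hp_hz:
        raise ValueError(
            f"sampling rate {rate_hz} Hz too low for a {hp_hz} Hz highpass"
        )
    b, a = signal.butter(1, hp_hz, btype="highpass", fs=rate_hz)
    out = signal.lfilter(b, a, mono)
    return AudioStimulus(out, rate_hz, label=label)


def speech_shaped_noise(reference: AudioStimulus, seed: int) -> AudioStimulus:
    """White noise re-shaped to the long-term magnitude spectrum of ``reference``.

    The full-length Fourier magnitudes of the reference are imposed on the
    phases of a seeded white-noise realisation, so the output has exactly the
    reference's long-term spectrum.
    """
    x = reference.samples
    if not np.any(x):
        raise ValueError("reference stimulus is silent")
    n = x.size
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    wf = np.fft.rfft(w)
    mag = np.abs(np.fft.rfft(x))
    wmag = np.abs(wf)
    phase = np.where(wmag > 0, wf / np.where(wmag > 0, wmag, 1.0), 1.0)
    out = np.fft.irfft(mag * phase, n)
    return AudioStimulus(out, reference.rate_hz, label="speech-shaped noise")


def calibrate_rms(x: AudioStimulus, target_rms: float) -> AudioStimulus:
    """Scale the waveform to the requested r.m.s. value (shape unchanged)."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    current = x.rms
    if current == 0:
        raise ValueError("cannot calibrate a silent stimulus")
    return AudioStimulus(x.samples * (target_rms / current), x.rate_hz, x.label)


def make_polarity_pair(x: AudioStimulus) -> PolarityStimulusPair:
    """Pair the stimulus with its sign-inverted copy."""
    return PolarityStimulusPair(positive=x)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file, returning float samples and the sampling rate.

    Integer PCM is rescaled to [-1, 1); float data is passed through.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(float)
    return data, float(rate)


def write_wav(path, x: AudioStimulus) -> None:
    """Write a stimulus as 32-bit float WAV."""
    wavfile.write(path, int(round(x.rate_hz)), x.samples.astype(np.float32))
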