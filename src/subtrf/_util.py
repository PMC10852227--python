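"""Internal numerical helpers."""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len


def fft_filter(x: np.ndarray, h: np.ndarray, delay: int | None = None) -> np.ndarray:
    """Linear convolution via padded real FFTs, optionally delay-compensated.

    Equivalent to ``np.convolve(x, h)`` (mode full) but padded to an
    FFT-friendly length; with ``delay`` given, returns the length-``len(x)``
    slice starting at ``delay`` (group-delay compensation for symmetric h).
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    m = x.size + h.size - 1
    nfft = next_fast_len(m)
    y = np.fft.irfft(np.fft.rfft(x, nfft) * np.fft.rfft(h, nfft), nfft)[:m]
    if delay is None:
        return y
    return y[delay : delay + x.size]


def seeded_noise_fft(n: int, shaper, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with spectral shaping applied at an FFT-friendly length.

    ``shaper(freqs_cycles_per_sample, spectrum)`` modifies the rfft in place.
    The result is truncated to ``n`` samples and has unit r.m.s.
    """
    nfft = next_fast_len(n)
    spec = np.fft.rfft(rng.standard_normal(nfft))
    f = np.fft.rfftfreq(nfft)
    shaper(f, spec)
    x = np.fft.irfft(spec, nfft)[:n]
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("spectral shaper removed all signal")
    return x / rms
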