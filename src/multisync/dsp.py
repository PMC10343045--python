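"""Shared zero-phase filtering and resampling helpers."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal


def bandpass_zero_phase(x: np.ndarray, rate: float, low: float, high: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, SOS)."""
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def lowpass_zero_phase(x: np.ndarray, rate: float, cutoff: float,
                       order: int = 6) -> np.ndarray:
    nyq = rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({nyq} Hz)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def notch_zero_phase(x: np.ndarray, rate: float, freq: float = 50.0,
                     q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``freq`` Hz."""
    if freq >= rate / 2.0:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist")
    b, a = signal.iirnotch(freq, q, fs=rate)
    return signal.filtfilt(b, a, x)


def resample_to(x: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    """Anti-aliased polyphase resampling to ``target_rate``."""
    frac = Fraction(target_rate / rate).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)
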