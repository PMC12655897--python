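"""Shared zero-lag low-pass filtering."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt


def lowpass(x: np.ndarray, sample_rate: float, cutoff_hz: float,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq:
        return np.asarray(x, dtype=float).copy()
    sos = butter(order, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))
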