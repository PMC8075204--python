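"""Zero-phase Butterworth helpers shared across modules.

All temporal filtering in the package is zero-phase (forward-backward,
``sosfiltfilt``) so that filtering never shifts spike times.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["butter_highpass", "butter_lowpass"]


def _apply(
    sos: np.ndarray, x: np.ndarray, axis: int, cutoff: float, fs: float
) -> np.ndarray:
    # pad by at least one cutoff period: the default (a few dozen samples)
    # is far shorter than a low-cutoff filter's response and leaves edge
    # transients large enough to masquerade as spikes
    min_padlen = 3 * (2 * sos.shape[0] + 1)
    padlen = min(x.shape[axis] - 2, max(min_padlen, int(round(fs / cutoff))))
    if x.shape[axis] <= min_padlen:
        raise ValueError(
            f"trace too short for zero-phase filtering: need more than "
            f"{min_padlen} samples along the time axis, got {x.shape[axis]}"
        )
    return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def butter_highpass(
    x: np.ndarray, cutoff: float, fs: float, order: int, axis: int = 0
) -> np.ndarray:
    """Zero-phase Butterworth high-pass along ``axis``."""
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return _apply(sos, np.asarray(x), axis, cutoff, fs)


def butter_lowpass(
    x: np.ndarray, cutoff: float, fs: float, order: int, axis: int = 0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along ``axis``."""
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _apply(sos, np.asarray(x), axis, cutoff, fs)
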