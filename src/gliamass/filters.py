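"""Zero-phase Butterworth filters shared by the analysis modules.

Both filters are 4th-order designs applied forward-backward
(``sosfiltfilt``), so they add no phase lag - a prerequisite for phase
locking and envelope statistics.  One second per end should be discarded
downstream to remove filter and Hilbert edge transients.
"""

from __future__ import annotations

import numpy as np
import scipy.signal
from numpy.typing import NDArray

__all__ = ["ALPHA_BAND", "SLOW_CUTOFF", "bandpass_alpha", "lowpass_slow"]

ALPHA_BAND = (8.0, 13.0)   # Hz
SLOW_CUTOFF = 0.5          # Hz


def bandpass_alpha(x: NDArray, fs: float,
                   band: tuple[float, float] = ALPHA_BAND) -> NDArray:
    """Zero-phase band-pass in the electrophysiological alpha band."""
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band} Hz band")
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def lowpass_slow(x: NDArray, fs: float, cutoff: float = SLOW_CUTOFF) -> NDArray:
    """Zero-phase low-pass isolating sub-0.5 Hz modulation."""
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff} Hz cutoff")
    sos = scipy.signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)
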