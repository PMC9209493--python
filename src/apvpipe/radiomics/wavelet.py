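"""One-level separable 3D stationary (undecimated) wavelet filter bank.

Each of the 8 sub-band channels is obtained by convolving the volume with the
low-pass (L) or high-pass (H) decomposition filter of the chosen wavelet
family along each axis in turn, without downsampling, using symmetric
boundary padding.  Channel labels read "LHL" = (axis0 filter, axis1 filter,
axis2 filter).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .catalogue import WAVELET_CHANNELS


class SizeError(ValueError):
    """Volume smaller than the filter support along some axis."""


def wavelet_filters(wavelet: str = "coif1") -> tuple[np.ndarray, np.ndarray]:
    """(low-pass, high-pass) decomposition filter taps."""
    w = pywt.Wavelet(wavelet)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(w.dec_hi, dtype=np.float64)


def wavelet_bank(
    grid: np.ndarray, wavelet: str = "coif1", channels: tuple[str, ...] = WAVELET_CHANNELS
) -> dict[str, np.ndarray]:
    """Compute the requested sub-band channels of a 3D array.

    Returns a dict channel-label -> array of the same shape as ``grid``.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 3:
        raise ValueError("wavelet_bank expects a 3D array")
    lo, hi = wavelet_filters(wavelet)
    if min(grid.shape) < len(lo):
        raise SizeError(
            f"volume shape {grid.shape} smaller than the {wavelet} filter length {len(lo)}"
        )

    # cache per-axis single-filter passes: 'L' and 'H' along each axis
    def convolve(arr: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
        return ndimage.convolve1d(arr, taps, axis=axis, mode="reflect")

    out: dict[str, np.ndarray] = {}
    # group channels by leading letters to share partial convolutions
    partial0: dict[str, np.ndarray] = {}
    for letter, taps in (("L", lo), ("H", hi)):
        if any(ch[0] == letter for ch in channels):
            partial0[letter] = convolve(grid, taps, axis=0)
    partial01: dict[str, np.ndarray] = {}
    for ch0, arr in partial0.items():
        for letter, taps in (("L", lo), ("H", hi)):
            if any(ch[0] == ch0 and ch[1] == letter for ch in channels):
                partial01[ch0 + letter] = convolve(arr, taps, axis=1)
    for ch in channels:
        taps = lo if ch[2] == "L" else hi
        out[ch] = convolve(partial01[ch[:2]], taps, axis=2)
    return out
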