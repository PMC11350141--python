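"""Canonical hemodynamic response function.

A single double-gamma kernel (response peak 6 s, undershoot peak 16 s,
undershoot ratio 1/6) is shared by the forward simulator and the GLM design
builder, so simulation and analysis use the same impulse response by
construction.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma

__all__ = ["double_gamma_hrf", "convolve_boxcar"]


def double_gamma_hrf(
    fs_hz: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sampled double-gamma HRF, peak-normalized to 1."""
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    # shape/scale chosen so each gamma peaks at the requested time (scale 1 s)
    h = gamma.pdf(t, peak_s) - ratio * gamma.pdf(t, undershoot_s)
    return h / h.max()


def convolve_boxcar(
    onsets_s, durations_s, n_time: int, fs_hz: float, hrf: np.ndarray | None = None
) -> np.ndarray:
    """Boxcar(s) convolved with the HRF, sampled on the recording grid.

    With ``hrf=None`` the canonical kernel is used; ``hrf=np.array([1.0])``
    gives the raw boxcar (identity kernel).
    """
    box = np.zeros(n_time)
    for onset, dur in zip(np.atleast_1d(onsets_s), np.atleast_1d(durations_s)):
        i0 = int(round(onset * fs_hz))
        i1 = int(round((onset + dur) * fs_hz))
        box[max(i0, 0):min(i1, n_time)] = 1.0
    if hrf is None:
        hrf = double_gamma_hrf(fs_hz)
    reg = np.convolve(box, hrf)[:n_time]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg
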