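"""Hemodynamic response modelling shared by the simulator and the GLMs."""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.stats import gamma

__all__ = ["double_gamma_hrf", "convolve_columns", "DEFAULT_LAG_TRS"]

#: fixed hemodynamic lag used when labels/epochs are shifted instead of convolved
DEFAULT_LAG_TRS = 10


def double_gamma_hrf(tr_seconds: float, duration_s: float = 30.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma HRF sampled at the TR, normalized to unit peak.

    The response is the difference of two gamma densities, peaking at
    ``peak_s`` with an undershoot peaking at ``undershoot_s``.
    """
    t = np.arange(0.0, duration_s, tr_seconds)
    h = gamma.pdf(t, peak_s + 1.0) - undershoot_ratio * gamma.pdf(t, undershoot_s + 1.0)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF")
    return h / peak


def convolve_columns(X: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each column of ``X`` with ``kernel``, truncated to len(X)."""
    X = np.asarray(X, dtype=float)
    full = signal.fftconvolve(X, kernel[:, None], axes=0)
    return full[: X.shape[0]]
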