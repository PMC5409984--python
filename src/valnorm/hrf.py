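"""Double-gamma hemodynamic response function with adjustable peak delay."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["double_gamma_hrf", "hrf_kernel", "DEFAULT_PEAK_GRID"]

# candidate peak delays (s) searched when adapting the HRF to a channel
DEFAULT_PEAK_GRID = np.arange(3.0, 8.01, 0.5)

UNDERSHOOT_DELAY_S = 16.0
UNDERSHOOT_RATIO = 1.0 / 6.0
KERNEL_DURATION_S = 30.0


def double_gamma_hrf(t: np.ndarray, peak_s: float = 5.5) -> np.ndarray:
    """Canonical-style double-gamma HRF, peak-normalized to 1.

    The positive lobe is a gamma density with unit scale peaking at
    ``peak_s``; the undershoot peaks at 16 s with 1/6 relative amplitude.
    ``peak_s`` is the single adapted temporal parameter.
    """
    t = np.asarray(t, float)
    pos = gamma_dist.pdf(t, a=peak_s + 1.0, scale=1.0)
    under = gamma_dist.pdf(t, a=UNDERSHOOT_DELAY_S + 1.0, scale=1.0)
    h = pos - UNDERSHOOT_RATIO * under
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def hrf_kernel(fs_hz: float, peak_s: float = 5.5) -> np.ndarray:
    """HRF sampled at ``fs_hz`` over 30 s, peak-normalized to 1."""
    n = int(round(KERNEL_DURATION_S * fs_hz))
    t = np.arange(n) / fs_hz
    return double_gamma_hrf(t, peak_s)
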