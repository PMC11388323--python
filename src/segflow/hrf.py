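"""Canonical haemodynamic response function (HRF) models.

The BOLD signal is a delayed, dispersed echo of neural events.  The standard
model is a difference of two gamma densities: a positive lobe peaking ~5-6 s
after the event and a slow undershoot centred ~15-16 s.  All analyses here
sample the HRF on the scan grid (one value per TR).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["double_gamma_hrf", "identity_hrf"]


def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    oversample: int = 1,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF at TR resolution.

    Parameters
    ----------
    tr : repetition time in seconds (sampling interval of the output).
    duration : total extent of the kernel in seconds.
    peak_delay, undershoot_delay : gamma shape parameters (scale fixed at
        1 s), placing the positive peak near ``peak_delay`` seconds and the
        undershoot near ``undershoot_delay`` seconds.
    undershoot_ratio : relative amplitude of the undershoot lobe.
    oversample : internal oversampling factor; the kernel is computed on a
        finer grid and decimated, which stabilises coarse TRs.

    Returns
    -------
    1-D array normalised to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversample
    t = np.arange(0, duration + dt / 2, dt)
    h = stats.gamma.pdf(t, peak_delay) - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay
    )
    h = h[::oversample]
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF parameters produced a zero kernel")
    return h / peak


def identity_hrf() -> np.ndarray:
    """A unit-impulse kernel: convolution with it is the identity map."""
    return np.array([1.0])
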