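"""Error-related temporal features: first-derivative-of-Gaussian convolution.

A kernel shaped like the first derivative of a Gaussian is an edge/transient
detector: convolved with EEG it responds to rapid amplitude excursions such
as the positive error-locked deflection that follows an observed trajectory
error, and rejects constant and slowly varying activity (the kernel sums to
zero).  With the default scale l = 30 samples (300 ms at 100 Hz) the window
matches the latency scale of that deflection; sliding by one sample over a
trial of n samples yields ``n - l + 1`` feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trial import EEGTrial, EegCursorError, FeatureSequence

__all__ = ["WaveletSpec", "gauss_deriv_kernel", "temporal_feature_sequence"]


@dataclass(frozen=True)
class WaveletSpec:
    """Scale and shape of the Gaussian-derivative kernel.

    ``gauss_sigma`` defaults to l/6 so that +-3 sigma spans the window; the
    kernel is rescaled to unit peak absolute value.
    """

    scale_l: int = 30
    gauss_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.scale_l < 2:
            raise EegCursorError("scale_l must be >= 2")
        if self.gauss_sigma is not None and self.gauss_sigma <= 0:
            raise EegCursorError("gauss_sigma must be positive")

    @property
    def sigma(self) -> float:
        return self.gauss_sigma if self.gauss_sigma is not None else self.scale_l / 6.0


def gauss_deriv_kernel(spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Kernel ``k(u), u = 1..l``: derivative of a Gaussian centred mid-window.

    Antisymmetric about its centre (sums to zero) and normalized to unit
    peak absolute value.
    """
    l = spec.scale_l
    sigma = spec.sigma
    u = np.arange(1, l + 1, dtype=float)
    centre = (l + 1) / 2.0
    k = -(u - centre) / sigma ** 2 * np.exp(-((u - centre) ** 2) / (2.0 * sigma ** 2))
    return k / np.max(np.abs(k))


def temporal_feature_sequence(trial: EEGTrial,
                              spec: WaveletSpec = WaveletSpec()) -> FeatureSequence:
    """Convolve each channel with the Gaussian-derivative kernel.

    ``X_T[t, j] = (1/l) * sum_{i=0}^{l-1} k(l - i) * signal[t - i, j]`` for
    t running over full windows only (no padding), i.e. the kernel's indices
    1..l meet the window's oldest..newest samples; rows = ``n - l + 1``.
    """
    l = spec.scale_l
    n, m = trial.signal.shape
    if n < l:
        raise EegCursorError(f"trial has {n} samples; need at least {l}")
    kernel = gauss_deriv_kernel(spec)
    # In the window ending at t, sample t-i meets kernel index l-i; running
    # j = l-i turns the sum into a plain sliding correlation of the signal
    # with k(1..l), oldest sample first.
    values = np.empty((n - l + 1, m))
    for j in range(m):
        values[:, j] = sps.correlate(trial.signal[:, j], kernel, mode="valid") / l
    return FeatureSequence(values=values, start_offset=l - 1,
                           step_samples=1, kind="temporal")
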