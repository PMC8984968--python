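"""Sliding-window Burg autoregressive mu-band power features.

Each 400 ms window of each channel is fit with a 16th-order autoregressive
model by the Burg (maximum-entropy) recursion; the model's power spectral
density is evaluated on a fixed mu-band grid (8-13 Hz in 0.5 Hz steps) and
summed (area under the PSD) to one band-power value.  Sliding the window by
10 ms (one sample at 100 Hz) over a trial of n samples yields the spectral
feature sequence of shape ``(n - 39, m)`` at the defaults.

The AR coefficients are stored in the convention where the PSD denominator
is ``|1 + sum_k a_k e^{-i omega k}|^2``, and the PSD is evaluated literally
as ``sigma^2`` over that squared magnitude (no sampling-rate factor), so a
white-noise model with unit innovation variance has a flat unit spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trial import EEGTrial, EegCursorError, FeatureSequence

__all__ = [
    "ARModel",
    "SpectralSpec",
    "burg_ar",
    "ar_psd",
    "mu_band_power",
    "spectral_feature_sequence",
    "DegenerateWindowError",
]


class DegenerateWindowError(EegCursorError):
    """Raised when a window is too short or has (near-)zero variance."""


@dataclass
class ARModel:
    """An all-pole model: coefficients ``a_1..a_p`` and innovation variance."""

    order: int
    coeffs: np.ndarray
    noise_var: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.order,):
            raise EegCursorError("coeffs must have length equal to the order")
        if self.noise_var < 0:
            raise EegCursorError("noise_var must be >= 0")


@dataclass(frozen=True)
class SpectralSpec:
    """Windowing and band parameters of the spectral feature extractor."""

    window_ms: float = 400.0
    step_ms: float = 10.0
    order: int = 16
    band: tuple[float, float] = (8.0, 13.0)
    freq_step: float = 0.5

    def band_grid(self) -> np.ndarray:
        lo, hi = self.band
        n = int(round((hi - lo) / self.freq_step))
        return lo + self.freq_step * np.arange(n + 1)

    def window_samples(self, sample_rate: float) -> int:
        w = self.window_ms * sample_rate / 1000.0
        if abs(w - round(w)) > 1e-9:
            raise EegCursorError("window_ms must be an integral number of samples")
        return int(round(w))

    def step_samples(self, sample_rate: float) -> int:
        s = self.step_ms * sample_rate / 1000.0
        if abs(s - round(s)) > 1e-9 or round(s) < 1:
            raise EegCursorError("step_ms must be a positive integral number of samples")
        return int(round(s))


def _burg_batch(windows: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg recursion over a batch of windows.

    Parameters
    ----------
    windows
        ``(n_windows, window_len)`` array.
    order
        AR order p; ``window_len`` must exceed ``2 * order``.

    Returns
    -------
    coeffs : ``(n_windows, p)`` in the ``1 + sum a_k z^-k`` convention.
    noise_var : ``(n_windows,)`` final prediction-error power.

    Windows with zero variance (or a vanishing error denominator mid-way)
    get all-zero coefficients and zero variance rather than NaNs; callers
    decide whether that is an error.
    """
    windows = np.asarray(windows, dtype=float)
    n_w, n = windows.shape
    if n <= 2 * order:
        raise DegenerateWindowError(
            f"window length {n} too short for order {order} (need > {2 * order})")
    f = windows.copy()
    b = windows.copy()
    a = np.zeros((n_w, order))
    e = np.mean(windows * windows, axis=1)
    dead = e <= 0.0
    for m in range(order):
        ff = f[:, 1:]
        bb = b[:, :-1]
        num = -2.0 * np.einsum("ij,ij->i", ff, bb)
        den = np.einsum("ij,ij->i", ff, ff) + np.einsum("ij,ij->i", bb, bb)
        dead |= den <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(dead, 0.0, num / np.where(den > 0, den, 1.0))
        if m > 0:
            a[:, :m] += k[:, None] * a[:, m - 1::-1]
        a[:, m] = k
        e = e * (1.0 - k * k)
        f = ff + k[:, None] * bb
        b = bb + k[:, None] * ff
    a[dead] = 0.0
    e[dead] = 0.0
    return a, np.maximum(e, 0.0)


def burg_ar(window: np.ndarray, order: int = 16) -> ARModel:
    """Fit one AR model to a window by the Burg algorithm.

    Raises :class:`DegenerateWindowError` for windows that are too short or
    identically constant.
    """
    window = np.asarray(window, dtype=float).ravel()
    if np.ptp(window) == 0.0:
        raise DegenerateWindowError("window is constant; AR fit undefined")
    coeffs, noise_var = _burg_batch(window[None, :], order)
    return ARModel(order=order, coeffs=coeffs[0], noise_var=float(noise_var[0]))


def ar_psd(model: ARModel, freqs: np.ndarray, sample_rate: float) -> np.ndarray:
    """Evaluate the AR power spectral density at the given frequencies (Hz).

    ``P(f) = sigma^2 / |1 + sum_k a_k exp(-i 2 pi f k / fs)|^2``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > sample_rate / 2):
        raise EegCursorError("frequencies must lie within [0, Nyquist]")
    omega = 2.0 * np.pi * freqs / sample_rate
    k = np.arange(1, model.order + 1)
    denom = 1.0 + np.exp(-1j * np.outer(omega, k)) @ model.coeffs
    return model.noise_var / np.abs(denom) ** 2


def mu_band_power(psd: np.ndarray, freqs: np.ndarray,
                  band: tuple[float, float] = (8.0, 13.0),
                  freq_step: float | None = None) -> float:
    """Area under the PSD inside the band: ``sum_f P(f) * delta_f``."""
    psd = np.asarray(psd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if freqs[0] > band[0] or freqs[-1] < band[1]:
        raise EegCursorError(f"frequency grid does not cover the band {band}")
    if freq_step is None:
        freq_step = float(np.mean(np.diff(freqs)))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sum(psd[mask]) * freq_step)


def spectral_feature_sequence(trial: EEGTrial,
                              spec: SpectralSpec = SpectralSpec()) -> FeatureSequence:
    """Sliding-window mu-band power, one value per channel per window position.

    At the defaults (100 Hz, 400 ms window, 10 ms step) a trial of n samples
    yields ``n - 39`` rows; row t summarizes raw samples ``[t, t + 39]``.
    Degenerate (flat) windows yield 0 power with a warning rather than
    aborting the trial.
    """
    win = spec.window_samples(trial.sample_rate)
    step = spec.step_samples(trial.sample_rate)
    n, m = trial.signal.shape
    if n < win:
        raise EegCursorError(f"trial has {n} samples; need at least {win}")

    rows = (n - win) // step + 1
    # (rows, win) view per channel, stacked over channels into one batch.
    sw = np.lib.stride_tricks.sliding_window_view(trial.signal, win, axis=0)
    sw = sw[::step]                         # (rows, m, win)
    batch = sw.transpose(1, 0, 2).reshape(m * rows, win)

    variances = batch.var(axis=1)
    coeffs, noise_var = _burg_batch(batch, spec.order)
    if np.any(variances == 0.0):
        warnings.warn("degenerate (constant) windows encountered; "
                      "their mu power is set to 0", RuntimeWarning)

    grid = spec.band_grid()
    omega = 2.0 * np.pi * grid / trial.sample_rate
    k = np.arange(1, spec.order + 1)
    basis = np.exp(-1j * np.outer(k, omega))        # (p, n_freqs)
    denom = 1.0 + coeffs @ basis                    # (batch, n_freqs)
    psd = noise_var[:, None] / np.abs(denom) ** 2
    power = psd.sum(axis=1) * spec.freq_step
    power[variances == 0.0] = 0.0

    values = power.reshape(m, rows).T
    return FeatureSequence(values=values, start_offset=win - 1,
                           step_samples=step, kind="spectral")
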