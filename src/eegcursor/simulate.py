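"""Synthetic EEG generator for cursor-control decoding experiments.

Emulates the statistical structure the decoder relies on, without claiming
biophysical realism:

* a mu-band (default 10 Hz) sensorimotor rhythm with a slowly varying
  log-normal (Ornstein-Uhlenbeck) amplitude envelope per channel;
* class-dependent event-related desynchronization (ERD): imagining the left
  hand attenuates the mu amplitude over the *right* hemisphere, the right
  hand over the left hemisphere, both hands over both; the relax class
  instead boosts mu amplitude (ERS).  ERD depth scales with imagery
  intensity, mirroring the finding that corticospinal excitability during
  motor imagery grows with imagery intensity;
* error-locked positive deflections: each simulated trajectory error elicits
  a positive unimodal (Gaussian) pulse peaking ~300 ms after the event on
  fronto-central channels, a P300-like passive error signal;
* 1/f^alpha pink + white background noise;
* a ground-truth cursor velocity trace that is constant along the class axis
  (left/right -> horizontal, up/down -> vertical) and zero on the other axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trial import (
    CLASS_AXIS_SIGN,
    CLASSES,
    ERROR_CHANNELS_FULL,
    ERROR_CHANNELS_HALF,
    LEFT_CHANNELS,
    MONTAGE_10,
    RIGHT_CHANNELS,
    EEGTrial,
    EegCursorError,
    _check_class_label,
)

__all__ = [
    "SimConfig",
    "simulate_trial",
    "inject_error_potential",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in microvolt-like signal units; the velocity unit is
    "pixels per feature step" (one step = one decoded segment).
    """

    channel_names: tuple[str, ...] = MONTAGE_10
    sample_rate: float = 100.0          #: Hz
    trial_duration: float = 10.0        #: seconds
    mu_freq: float = 10.0               #: Hz, centre of the mu rhythm
    mu_base_amp: float = 4.0            #: resting mu amplitude per channel
    erd_depth: float = 0.5              #: fraction of mu removed at intensity 1
    intensity: float = 1.0              #: imagery intensity (scales ERD + speed)
    noise_sd: float = 1.5               #: total background noise SD
    pink_noise_exponent: float = 1.0    #: alpha of the 1/f^alpha component
    p300_amp: float = 5.0               #: peak of the error-locked deflection
    p300_latency: float = 0.3           #: seconds from error onset to peak
    p300_width: float = 0.1             #: Gaussian sigma of the deflection, s
    error_rate: float = 0.1             #: error events per second (Poisson)
    speed_gain: float = 25.0            #: velocity units per unit intensity
    envelope_tau: float = 0.5           #: OU time constant of the mu envelope, s
    envelope_sd: float = 0.25           #: stationary SD of the log-envelope

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.trial_duration <= 0:
            raise EegCursorError("sample_rate and trial_duration must be positive")
        if self.p300_latency <= 0 or self.p300_width <= 0:
            raise EegCursorError("p300_latency and p300_width must be positive")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise EegCursorError("erd_depth must lie in [0, 1]")
        if self.intensity < 0 or self.error_rate < 0 or self.noise_sd < 0:
            raise EegCursorError("intensity, error_rate and noise_sd must be >= 0")
        if len(self.channel_names) != len(set(self.channel_names)):
            raise EegCursorError("channel_names must be unique")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))

    @property
    def effective_erd(self) -> float:
        """ERD fraction actually applied: clipped so mu never goes negative."""
        return min(self.erd_depth * self.intensity, 1.0)


def _ou_log_envelope(rng: np.random.Generator, n: int, dt: float,
                     tau: float, sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, exponentiated to a positive envelope."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    steps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + steps[i - 1]
    return np.exp(x)


def _pink_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-SD 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _erd_factors(config: SimConfig, class_label: str) -> np.ndarray:
    """Per-channel multiplicative mu-amplitude factor for a class."""
    d = config.effective_erd
    factors = np.ones(len(config.channel_names))
    if class_label == "L":
        attenuated: Sequence[str] = RIGHT_CHANNELS
    elif class_label == "R":
        attenuated = LEFT_CHANNELS
    elif class_label == "U":
        attenuated = LEFT_CHANNELS + RIGHT_CHANNELS
    else:  # relax -> ERS: mu amplitude boosted everywhere
        for i in range(len(factors)):
            factors[i] = 1.0 + d
        return factors
    for i, name in enumerate(config.channel_names):
        if name in attenuated:
            factors[i] = 1.0 - d
    return factors


def _true_velocity(config: SimConfig, class_label: str, n: int) -> np.ndarray:
    axis, sign = CLASS_AXIS_SIGN[class_label]
    v = np.zeros((n, 2))
    v[:, axis] = sign * config.speed_gain * config.intensity
    return v


def simulate_trial(config: SimConfig, class_label: str, seed: int) -> EEGTrial:
    """Generate one synthetic trial for a motor-imagery class.

    The signal is mu rhythm (class-dependent amplitude per hemisphere)
    + pink + white noise + error-locked positive deflections; bit-identical
    for identical ``(config, class_label, seed)``.
    """
    _check_class_label(class_label)
    rng = np.random.default_rng(seed)
    n = config.n_samples
    fs = config.sample_rate
    t = np.arange(n) / fs
    m = len(config.channel_names)

    factors = _erd_factors(config, class_label)
    signal = np.empty((n, m))
    for j in range(m):
        env = _ou_log_envelope(rng, n, 1.0 / fs, config.envelope_tau,
                               config.envelope_sd)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        mu = config.mu_base_amp * factors[j] * env * np.sin(
            2.0 * np.pi * config.mu_freq * t + phase)
        pink = _pink_noise(rng, n, config.pink_noise_exponent)
        white = rng.normal(size=n)
        noise = config.noise_sd * (pink + white) / np.sqrt(2.0)
        signal[:, j] = mu + noise

    trial = EEGTrial(
        signal=signal,
        sample_rate=fs,
        channel_names=config.channel_names,
        class_label=class_label,
        true_velocity=_true_velocity(config, class_label, n),
        error_events=[],
        trial_id=f"sim-{class_label}-{seed}",
    )

    # Error events are drawn last so that error_rate=0 leaves the base
    # construction (and the consumed random stream) untouched.
    if config.error_rate > 0:
        n_events = rng.poisson(config.error_rate * config.trial_duration)
        if n_events > 0:
            onsets = np.sort(rng.uniform(0.0, config.trial_duration, size=n_events))
            trial = inject_error_potential(
                trial, onsets.tolist(), amp=config.p300_amp,
                latency=config.p300_latency, width=config.p300_width)
    return trial


def inject_error_potential(trial: EEGTrial, onsets: Sequence[float], amp: float,
                           latency: float = 0.3, width: float = 0.1) -> EEGTrial:
    """Add a P300-like positive pulse after each error onset.

    Each onset contributes a Gaussian bump of peak ``amp`` centred at
    ``onset + latency`` on FC3/FC4 and half that on C1/C2 (when present).
    Addition is exact and linear; the returned copy's ``error_events`` is
    extended with the onsets.
    """
    if width <= 0:
        raise EegCursorError("width must be positive")
    duration = trial.duration
    for onset in onsets:
        if not 0.0 <= onset < duration:
            raise EegCursorError(
                f"error onset {onset:.3f}s outside trial [0, {duration:.3f}s)")
    out = trial.copy()
    t = trial.times
    bump = np.zeros(trial.n_samples)
    for onset in onsets:
        centre = onset + latency
        bump += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    for name, scale in [(c, 1.0) for c in ERROR_CHANNELS_FULL] + \
                       [(c, 0.5) for c in ERROR_CHANNELS_HALF]:
        if name in out.channel_names:
            out.signal[:, out.channel_index(name)] += scale * bump
    out.error_events = sorted((out.error_events or []) + [float(o) for o in onsets])
    return out


def simulate_dataset(config: SimConfig, trials_per_class: int,
                     seed: int) -> tuple[list[EEGTrial], pd.DataFrame]:
    """Generate a class-balanced set of trials plus a manifest table.

    Per-trial seeds are derived deterministically from the master seed via
    ``numpy.random.SeedSequence``; the manifest records trial_id, class,
    seed and intensity.
    """
    if trials_per_class < 1:
        raise EegCursorError("trials_per_class must be >= 1")
    n_trials = 4 * trials_per_class
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2 ** 31)
    trials: list[EEGTrial] = []
    rows = []
    k = 0
    for rep in range(trials_per_class):
        for cls in CLASSES:
            s = int(child_seeds[k])
            trial = simulate_trial(config, cls, seed=s)
            trial.trial_id = f"trial-{k:03d}-{cls}"
            trials.append(trial)
            rows.append({"trial_id": trial.trial_id, "class_label": cls,
                         "seed": s, "intensity": config.intensity})
            k += 1
    manifest = pd.DataFrame(rows)
    return trials, manifest
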