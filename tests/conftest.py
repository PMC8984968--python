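"""Shared fixtures: simulated trials and small decodable datasets."""

from __future__ import annotations

import numpy as np
import pytest

from eegcursor import SimConfig, simulate_trial
from eegcursor.fusion import FusedDataset


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def trial_r(sim_config):
    """One right-hand-imagery trial (10 s, 100 Hz, 10 channels)."""
    return simulate_trial(sim_config, "R", seed=42)


def band_power_periodogram(trial, channel: str, band=(8.0, 13.0)) -> float:
    """Independent band-power oracle: periodogram integral over the band."""
    from scipy.signal import periodogram

    f, p = periodogram(trial.channel(channel), fs=trial.sample_rate)
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[mask], f[mask]))


def toy_dataset(n_samples: int = 128, seq_len: int = 8, n_features: int = 6,
                seed: int = 0, noise: float = 0.1) -> FusedDataset:
    """A small learnable dataset: labels linearly encoded in the features.

    Class axis structure mirrors the velocity-label convention (up/down
    samples have zero horizontal label and vice versa) so the VC loss is
    well defined on it.
    """
    rng = np.random.default_rng(seed)
    classes = np.tile(np.array(["L", "R", "U", "D"]), n_samples // 4 + 1)[:n_samples]
    speeds = rng.uniform(1.0, 3.0, size=n_samples)
    labels = np.zeros((n_samples, 2))
    for i, cls in enumerate(classes):
        axis = 0 if cls in "LR" else 1
        sign = 1 if cls in "RU" else -1
        labels[i, axis] = sign * speeds[i]
    x = rng.normal(scale=noise, size=(n_samples, seq_len, n_features))
    x[:, :, 0] += labels[:, 0][:, None]
    x[:, :, 1] += labels[:, 1][:, None]
    n_trials = max(1, n_samples // 8)
    trial_ids = np.array([f"t{i % n_trials}" for i in range(n_samples)])
    seg = np.arange(n_samples)
    return FusedDataset(x, labels, classes, trial_ids, seg)
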