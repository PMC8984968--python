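"""Reading, writing and preprocessing of EEG trials.

Supported formats: EDF (read, through :mod:`mne`), delimited text (CSV,
read/write) and an HDF5 trial container (read/write) used to move whole
datasets between pipeline stages.  Preprocessing follows common
sensorimotor-decoding practice: pick the 10-channel montage, optionally
notch mains interference, down-sample to 100 Hz with polyphase
anti-aliasing, then band-pass 0.1-30 Hz with a zero-phase 4th-order
Butterworth filter (zero-phase so the latency of transient error signals
is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .trial import MONTAGE_10, EEGTrial, EegCursorError

__all__ = [
    "PreprocessSpec",
    "read_trial",
    "write_trial_csv",
    "write_trials",
    "read_trials",
    "resample",
    "bandpass",
    "notch",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing parameters (rates/frequencies in Hz)."""

    target_rate: float = 100.0
    bandpass_low: float = 0.1
    bandpass_high: float = 30.0
    notch_freq: Optional[float] = None
    channel_subset: tuple[str, ...] = MONTAGE_10

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high < self.target_rate / 2:
            raise EegCursorError(
                "require 0 < bandpass_low < bandpass_high < target_rate/2")
        if not self.channel_subset:
            raise EegCursorError("channel_subset must be nonempty")
        if len(self.channel_subset) != len(set(self.channel_subset)):
            raise EegCursorError("channel_subset contains duplicates")


def _select_channels(names: Sequence[str], data: np.ndarray,
                     requested: Sequence[str]) -> np.ndarray:
    idx = []
    for ch in requested:
        if ch not in names:
            raise EegCursorError(f"channel {ch!r} not found in file (has {list(names)})")
        idx.append(list(names).index(ch))
    return data[:, idx]


def read_trial(path, fmt: Optional[str] = None, *, class_label: str,
               sample_rate: Optional[float] = None,
               channels: Optional[Sequence[str]] = None,
               true_velocity: Optional[np.ndarray] = None,
               trial_id: Optional[str] = None) -> EEGTrial:
    """Read a single trial from an EDF or delimited (CSV) file.

    For EDF the sampling rate comes from the file header; for CSV it must be
    supplied.  ``channels``, when given, selects and orders the columns;
    a missing channel raises an error naming it.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        import mne  # mne's pure-python EDF reader; no pyedflib needed

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = raw.ch_names
        data = raw.get_data().T * 1e6  # volts -> microvolt-like units
        rate = float(raw.info["sfreq"])
    elif fmt == "delimited":
        if sample_rate is None:
            raise EegCursorError("sample_rate is required for delimited files")
        frame = pd.read_csv(path)
        names = list(frame.columns)
        data = frame.to_numpy(dtype=float)
        rate = float(sample_rate)
    else:
        raise EegCursorError(f"unknown format {fmt!r}; expected 'edf' or 'delimited'")

    if channels is not None:
        data = _select_channels(names, data, channels)
        names = list(channels)
    return EEGTrial(signal=data, sample_rate=rate, channel_names=names,
                    class_label=class_label, true_velocity=true_velocity,
                    trial_id=trial_id or path.stem)


def write_trial_csv(trial: EEGTrial, path) -> None:
    """Write one trial's signal as CSV with a channel-name header row."""
    frame = pd.DataFrame(trial.signal, columns=list(trial.channel_names))
    frame.to_csv(path, index=False)


def write_trials(trials: Sequence[EEGTrial], path) -> None:
    """Write a list of trials into one HDF5 container.

    Layout: group ``trials/<trial_id>`` per trial with dataset ``signal``
    (and optional ``true_velocity``, ``error_events``) plus attributes
    ``class_label`` and ``sample_rate``; the shared channel list is a root
    attribute.  All trials must share channel names.
    """
    names = None
    for trial in trials:
        if names is None:
            names = list(trial.channel_names)
        elif list(trial.channel_names) != names:
            raise EegCursorError("all trials must share identical channel names")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "eegcursor-trials-v1"
        if names is not None:
            f.attrs["channel_names"] = [str(n) for n in names]
        grp = f.create_group("trials")
        for i, trial in enumerate(trials):
            g = grp.create_group(f"{i:05d}")
            g.create_dataset("signal", data=trial.signal)
            g.attrs["trial_id"] = trial.trial_id
            g.attrs["class_label"] = trial.class_label
            g.attrs["sample_rate"] = trial.sample_rate
            if trial.true_velocity is not None:
                g.create_dataset("true_velocity", data=trial.true_velocity)
            if trial.error_events is not None:
                g.create_dataset("error_events", data=np.asarray(trial.error_events))


def read_trials(path) -> list[EEGTrial]:
    """Inverse of :func:`write_trials`."""
    out: list[EEGTrial] = []
    with h5py.File(path, "r") as f:
        names = [str(n) for n in f.attrs.get("channel_names", [])]
        for key in sorted(f["trials"].keys()):
            g = f["trials"][key]
            out.append(EEGTrial(
                signal=g["signal"][()],
                sample_rate=float(g.attrs["sample_rate"]),
                channel_names=names,
                class_label=str(g.attrs["class_label"]),
                true_velocity=g["true_velocity"][()] if "true_velocity" in g else None,
                error_events=list(g["error_events"][()]) if "error_events" in g else None,
                trial_id=str(g.attrs["trial_id"]),
            ))
    return out


def resample(trial: EEGTrial, target_rate: float) -> EEGTrial:
    """Down-sample a trial with polyphase anti-alias filtering.

    Output length is ``floor(n * target_rate / input_rate)``.  The
    ground-truth velocity trace is carried over by nearest-sample index
    mapping (it is piecewise constant; low-pass resampling would smear its
    steps).  Upsampling is not supported.
    """
    if target_rate > trial.sample_rate:
        raise EegCursorError(
            f"target rate {target_rate} Hz exceeds input rate {trial.sample_rate} Hz")
    if target_rate == trial.sample_rate:
        return trial.copy()
    frac = Fraction(target_rate / trial.sample_rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    n_out = int(np.floor(trial.n_samples * target_rate / trial.sample_rate))
    data = sps.resample_poly(trial.signal, up, down, axis=0)[:n_out]
    velocity = None
    if trial.true_velocity is not None:
        src_idx = np.minimum(
            (np.arange(n_out) * trial.sample_rate / target_rate).astype(int),
            trial.n_samples - 1)
        velocity = trial.true_velocity[src_idx]
    return trial.copy(signal=data, sample_rate=float(target_rate),
                      true_velocity=velocity)


def bandpass(trial: EEGTrial, low: float, high: float, order: int = 4) -> EEGTrial:
    """Zero-phase Butterworth band-pass; length preserved."""
    nyq = trial.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise EegCursorError(f"band ({low}, {high}) Hz must lie within (0, {nyq}) Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trial.sample_rate,
                     output="sos")
    # Reflect-pad on the scale of the low corner's impulse response, else its
    # settling transient contaminates the trial edges.
    padlen = int(min(trial.n_samples - 1, 3 * trial.sample_rate / low))
    data = sps.sosfiltfilt(sos, trial.signal, axis=0, padlen=padlen)
    return trial.copy(signal=data)


def notch(trial: EEGTrial, freq: float, quality: float = 30.0) -> EEGTrial:
    """Zero-phase IIR notch at ``freq`` Hz (mains interference)."""
    if not 0 < freq < trial.sample_rate / 2:
        raise EegCursorError("notch frequency must lie within (0, Nyquist)")
    b, a = sps.iirnotch(freq, quality, fs=trial.sample_rate)
    data = sps.filtfilt(b, a, trial.signal, axis=0)
    return trial.copy(signal=data)


def preprocess(trial: EEGTrial, spec: PreprocessSpec = PreprocessSpec()) -> EEGTrial:
    """Full preprocessing chain: channel select -> notch -> resample -> band-pass.

    The band-pass runs at the target rate, after the polyphase stage has
    already applied its own anti-alias filter; the output rate always equals
    ``spec.target_rate``.
    """
    data = _select_channels(trial.channel_names, trial.signal, spec.channel_subset)
    out = trial.copy(signal=data, channel_names=list(spec.channel_subset))
    if spec.notch_freq is not None:
        out = notch(out, spec.notch_freq)
    if out.sample_rate != spec.target_rate:
        out = resample(out, spec.target_rate)
    out = bandpass(out, spec.bandpass_low, spec.bandpass_high)
    return out
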