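"""Core containers for EEG cursor-control decoding.

An :class:`EEGTrial` holds one trial of multichannel EEG together with its
motor-imagery class label and, when known, the ground-truth cursor velocity
trace and the onset times of observed trajectory errors.  A
:class:`FeatureSequence` is a time-indexed feature matrix derived from a trial
(sliding-window band power, wavelet output, or their fusion) together with the
alignment bookkeeping needed to map feature rows back onto raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

#: The 10-channel sensorimotor montage used for cursor control: channels
#: around C3/C4 over left/right motor cortex plus fronto-central channels
#: that carry most of the error-related signal.
MONTAGE_10: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "C5", "C6", "FC3", "FC4", "CP3", "CP4",
)

#: Hemisphere groups by the 10-20 convention: odd digit = left, even = right.
LEFT_CHANNELS: tuple[str, ...] = ("C1", "C3", "C5", "FC3", "CP3")
RIGHT_CHANNELS: tuple[str, ...] = ("C2", "C4", "C6", "FC4", "CP4")

#: Channels that carry the error-locked positive deflection at full amplitude,
#: and the central neighbours that receive it at half amplitude.
ERROR_CHANNELS_FULL: tuple[str, ...] = ("FC3", "FC4")
ERROR_CHANNELS_HALF: tuple[str, ...] = ("C1", "C2")

#: Motor-imagery classes: left hand, right hand, both hands, relax -> the
#: cursor moves left, right, up, down respectively.
CLASSES: tuple[str, ...] = ("L", "R", "U", "D")

#: Velocity-label convention per class: (axis index, sign) with axis 0 =
#: horizontal, axis 1 = vertical; screen convention L=-x, R=+x, U=+y, D=-y.
CLASS_AXIS_SIGN: dict[str, tuple[int, int]] = {
    "L": (0, -1),
    "R": (0, +1),
    "U": (1, +1),
    "D": (1, -1),
}


class EegCursorError(ValueError):
    """Base class for labelled errors raised by this package."""


def _check_class_label(label: str) -> str:
    if label not in CLASSES:
        raise EegCursorError(
            f"unknown class label {label!r}; expected one of {CLASSES}"
        )
    return label


@dataclass
class EEGTrial:
    """One trial of multichannel EEG with its decoding metadata.

    Parameters
    ----------
    signal
        ``(n_samples, n_channels)`` array in microvolt-like units.
    sample_rate
        Sampling rate in Hz.
    channel_names
        Ordered channel identifiers, one per signal column.
    class_label
        Motor-imagery class, one of ``L R U D``.
    true_velocity
        Optional ``(n_samples, 2)`` ground-truth (horizontal, vertical)
        cursor velocity trace.
    error_events
        Optional onset times (seconds) of observed trajectory errors.
    """

    signal: np.ndarray
    sample_rate: float
    channel_names: Sequence[str]
    class_label: str
    true_velocity: Optional[np.ndarray] = None
    error_events: Optional[list[float]] = None
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise EegCursorError("signal must be a (n_samples, n_channels) array with n >= 1")
        self.channel_names = list(self.channel_names)
        if self.signal.shape[1] != len(self.channel_names):
            raise EegCursorError(
                f"signal has {self.signal.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        if self.sample_rate <= 0:
            raise EegCursorError("sample_rate must be positive")
        _check_class_label(self.class_label)
        if self.true_velocity is not None:
            self.true_velocity = np.asarray(self.true_velocity, dtype=float)
            if self.true_velocity.shape != (self.signal.shape[0], 2):
                raise EegCursorError(
                    "true_velocity must have shape (n_samples, 2) matching the signal"
                )
        if self.error_events is not None:
            self.error_events = sorted(float(t) for t in self.error_events)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise EegCursorError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples as a 1-D array."""
        return self.signal[:, self.channel_index(name)]

    def copy(self, **changes) -> "EEGTrial":
        """Return a deep copy, optionally with fields replaced."""
        out = replace(self, **changes)
        if "signal" not in changes:
            out.signal = self.signal.copy()
        if "true_velocity" not in changes and self.true_velocity is not None:
            out.true_velocity = self.true_velocity.copy()
        if "error_events" not in changes and self.error_events is not None:
            out.error_events = list(self.error_events)
        return out


@dataclass
class FeatureSequence:
    """A time-indexed feature matrix with raw-sample alignment metadata.

    ``values[t]`` summarizes the raw-sample window that *ends* at raw index
    ``start_offset + t * step_samples``; ``kind`` records which extractor
    produced it.
    """

    values: np.ndarray
    start_offset: int
    step_samples: int = 1
    kind: str = "spectral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EegCursorError("feature values must be a 2-D (steps, features) array")
        if self.step_samples < 1 or self.start_offset < 0:
            raise EegCursorError("step_samples must be >= 1 and start_offset >= 0")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
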