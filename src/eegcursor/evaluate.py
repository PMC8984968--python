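"""Trajectory construction and evaluation metrics for 2D cursor control.

Decoded velocities are integrated (forward Euler) into a cursor trajectory.
Performance is summarized by

* per-axis RMSE of predicted vs labelled velocity;
* ACC, the percentage of decoded samples whose dominant signed velocity
  component matches the intended direction (ties count as incorrect);
* MAR = RMSE / (eps + ACC), the RMSE-accuracy ratio on the non-imaginary
  axis, with ACC entered on the percent scale and eps = 1e-8 (lower is
  better);
* the gate test: a trial succeeds if its trajectory first crosses the
  perpendicular plane through the start-target midpoint within a
  400-pixel-wide gate centred on the ideal line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .decoder import DecoderModel, predict_velocities
from .fusion import FusedDataset
from .trial import CLASSES, EegCursorError

__all__ = [
    "Trajectory",
    "EvalReport",
    "integrate_velocity",
    "axis_rmse",
    "direction_accuracy",
    "mar",
    "gate_success",
    "evaluate",
]

_AXIS_INDEX = {"horizontal": 0, "vertical": 1}


@dataclass
class Trajectory:
    """An integrated cursor path: ``positions[0]`` is the start point."""

    positions: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise EegCursorError("positions must be a (steps, 2) array")

    @property
    def start(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end(self) -> np.ndarray:
        return self.positions[-1]


def integrate_velocity(velocities: np.ndarray, start=(0.0, 0.0),
                       dt: float = 1.0) -> Trajectory:
    """Forward-Euler integration: ``p[k+1] = p[k] + v[k] * dt``."""
    velocities = np.asarray(velocities, dtype=float)
    if velocities.ndim != 2 or velocities.shape[1] != 2:
        raise EegCursorError("velocities must be a (steps, 2) array")
    if not np.all(np.isfinite(velocities)):
        raise EegCursorError("velocities contain non-finite values")
    positions = np.vstack([np.zeros((1, 2)),
                           np.cumsum(velocities * dt, axis=0)]) + np.asarray(start, dtype=float)
    return Trajectory(positions=positions, dt=dt)


def axis_rmse(y: np.ndarray, yhat: np.ndarray, axis: str | int) -> float:
    """Root mean square error of one velocity component."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise EegCursorError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if len(y) == 0:
        raise EegCursorError("empty input")
    a = _AXIS_INDEX.get(axis, axis) if isinstance(axis, str) else axis
    return float(np.sqrt(np.mean((y[:, a] - yhat[:, a]) ** 2)))


def _decoded_direction(yhat: np.ndarray) -> np.ndarray:
    """Signed dominant direction per sample; '?' for exact |h| = |v| ties."""
    h, v = yhat[:, 0], yhat[:, 1]
    out = np.full(len(yhat), "?", dtype="<U1")
    horiz = np.abs(h) > np.abs(v)
    vert = np.abs(v) > np.abs(h)
    out[horiz & (h > 0)] = "R"
    out[horiz & (h < 0)] = "L"
    out[vert & (v > 0)] = "U"
    out[vert & (v < 0)] = "D"
    return out


def direction_accuracy(yhat: np.ndarray, intended: Sequence[str]) -> float:
    """ACC in percent: decoded dominant signed direction vs intended class.

    The decoded direction of a sample is the axis of the larger absolute
    velocity component, signed (positive horizontal = right, positive
    vertical = up); exact ties count as incorrect.
    """
    yhat = np.asarray(yhat, dtype=float)
    intended = np.asarray(intended)
    if len(yhat) == 0:
        raise EegCursorError("empty input")
    unknown = ~np.isin(intended, CLASSES)
    if unknown.any():
        raise EegCursorError(f"unknown class label(s): {sorted(set(intended[unknown]))}")
    return float(100.0 * np.mean(_decoded_direction(yhat) == intended))


def mar(rmse_nonimaginary: float, acc: float, eps: float = 1e-8) -> float:
    """RMSE-accuracy ratio ``RMSE / (eps + ACC)`` with ACC in percent."""
    if rmse_nonimaginary < 0 or acc < 0:
        raise EegCursorError("rmse and acc must be >= 0")
    return rmse_nonimaginary / (eps + acc)


def gate_success(traj: Trajectory, start, target,
                 gate_width: float = 400.0) -> bool:
    """Did the trajectory pass through the midpoint gate?

    The gate is a segment of width ``gate_width`` centred on the
    start-target midpoint, perpendicular to the start-target line.  The
    trial succeeds iff, at the trajectory's *first* crossing of the
    midpoint plane, the perpendicular offset from the ideal line is at most
    half the gate width.  A trajectory that never reaches the plane fails.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    span = target - start
    dist = np.linalg.norm(span)
    if dist == 0:
        raise EegCursorError("start and target coincide; gate undefined")
    d = span / dist
    perp = np.array([-d[1], d[0]])
    mid = (start + target) / 2.0
    s = (traj.positions - mid) @ d
    crossings = np.nonzero((s[:-1] < 0) & (s[1:] >= 0) |
                           (s[:-1] > 0) & (s[1:] <= 0))[0]
    if s[0] == 0.0:
        offset = abs((traj.positions[0] - mid) @ perp)
        return bool(offset <= gate_width / 2.0)
    if len(crossings) == 0:
        return False
    k = crossings[0]
    frac = s[k] / (s[k] - s[k + 1])
    p_cross = traj.positions[k] + frac * (traj.positions[k + 1] - traj.positions[k])
    offset = abs((p_cross - mid) @ perp)
    return bool(offset <= gate_width / 2.0)


@dataclass
class EvalReport:
    """Machine-readable evaluation summary; absent views stay ``None``."""

    rmse: dict = field(default_factory=dict)       # view -> {horizontal, vertical}
    acc: dict = field(default_factory=dict)        # view -> percent
    mar: dict = field(default_factory=dict)        # view -> MAR (non-imaginary axis)
    gate_successes: int = 0
    gate_trials: int = 0
    eps: float = 1e-8
    acc_scale: str = "percent"
    gate_width: float = 400.0

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse, "acc": self.acc, "mar": self.mar,
            "gate_successes": self.gate_successes, "gate_trials": self.gate_trials,
            "eps": self.eps, "acc_scale": self.acc_scale,
            "gate_width": self.gate_width,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True, **kw)


#: Which axis is the non-imaginary (ideally zero) one per test view.
_NON_IMAGINARY_AXIS = {"TESTUD": "horizontal", "TESTLR": "vertical"}


def evaluate(model: DecoderModel, testset: FusedDataset,
             gate_width: float = 400.0, dt: float = 1.0) -> tuple[EvalReport, dict]:
    """Evaluate a trained model on a test split.

    Returns the report plus a dict of per-trial predicted trajectories
    (trial_id -> Trajectory).  RMSE is reported per axis on the TEST,
    TESTUD and TESTLR views; ACC over each view; MAR on the non-imaginary
    axis of TESTUD/TESTLR.  The gate test integrates each trial's predicted
    velocities and uses the trial's ideal (label-integrated) endpoint as
    the target.
    """
    if len(testset) == 0:
        raise EegCursorError("test set is empty")
    yhat = predict_velocities(model, testset)
    report = EvalReport(gate_width=gate_width)
    views = {
        "TEST": np.ones(len(testset), dtype=bool),
        "TESTUD": np.isin(testset.class_labels, ["U", "D"]),
        "TESTLR": np.isin(testset.class_labels, ["L", "R"]),
    }
    for name, mask in views.items():
        if not mask.any():
            report.rmse[name] = None
            report.acc[name] = None
            if name in _NON_IMAGINARY_AXIS:
                report.mar[name] = None
            continue
        y_v, yhat_v = testset.labels[mask], yhat[mask]
        report.rmse[name] = {
            "horizontal": axis_rmse(y_v, yhat_v, "horizontal"),
            "vertical": axis_rmse(y_v, yhat_v, "vertical"),
        }
        report.acc[name] = direction_accuracy(yhat_v, testset.class_labels[mask])
        if name in _NON_IMAGINARY_AXIS:
            ax = _NON_IMAGINARY_AXIS[name]
            report.mar[name] = mar(report.rmse[name][ax], report.acc[name],
                                   report.eps)

    trajectories: dict[str, Trajectory] = {}
    for trial_id in np.unique(testset.trial_ids):
        mask = testset.trial_ids == trial_id
        order = np.argsort(testset.segment_index[mask])
        pred_traj = integrate_velocity(yhat[mask][order], dt=dt)
        ideal_end = integrate_velocity(testset.labels[mask][order], dt=dt).end
        trajectories[str(trial_id)] = pred_traj
        if np.linalg.norm(ideal_end) > 0:
            report.gate_trials += 1
            if gate_success(pred_traj, (0.0, 0.0), ideal_end, gate_width):
                report.gate_successes += 1
    return report, trajectories
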