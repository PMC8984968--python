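"""Trajectory integration and the RMSE / ACC / MAR / gate metrics."""

import numpy as np
import pytest

from eegcursor import (
    EegCursorError,
    Trajectory,
    axis_rmse,
    direction_accuracy,
    evaluate,
    gate_success,
    integrate_velocity,
    mar,
)

from conftest import toy_dataset


class TestIntegrateVelocity:
    def test_constant_velocity_endpoint(self):
        traj = integrate_velocity(np.tile([1.0, 0.0], (100, 1)), start=(0, 0), dt=1.0)
        assert traj.positions.shape == (101, 2)
        assert traj.end == pytest.approx([100.0, 0.0])

    def test_zero_velocity_stays_at_start(self):
        traj = integrate_velocity(np.zeros((50, 2)), start=(3.0, -2.0))
        assert np.all(traj.positions == [3.0, -2.0])

    def test_reversed_velocities_return_to_start(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(40, 2))
        path = np.vstack([v, -v[::-1]])
        traj = integrate_velocity(path, start=(5.0, 5.0))
        assert traj.end == pytest.approx([5.0, 5.0], abs=1e-9)

    def test_integration_linearity(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(30, 2))
        end1 = integrate_velocity(v).end
        end3 = integrate_velocity(3.0 * v).end
        assert end3 == pytest.approx(3.0 * end1)

    def test_nonfinite_rejected(self):
        v = np.zeros((5, 2))
        v[2, 0] = np.nan
        with pytest.raises(EegCursorError, match="finite"):
            integrate_velocity(v)


class TestAxisRmse:
    def test_perfect_and_constant_error(self):
        y = np.zeros((10, 2))
        assert axis_rmse(y, y, "horizontal") == 0.0
        yhat = y.copy()
        yhat[:, 1] = 2.0
        assert axis_rmse(y, yhat, "vertical") == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(100, 2))
        yhat = rng.normal(size=(100, 2))
        want = np.sqrt(np.mean((y[:, 0] - yhat[:, 0]) ** 2))
        assert axis_rmse(y, yhat, "horizontal") == pytest.approx(want, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EegCursorError, match="empty"):
            axis_rmse(np.zeros((0, 2)), np.zeros((0, 2)), 0)


class TestDirectionAccuracy:
    def test_stated_example(self):
        preds = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 0.0]])
        assert direction_accuracy(preds, ["U", "U", "U"]) == pytest.approx(200 / 3)

    def test_perfect_alignment(self):
        preds = np.array([[-3.0, 0.0], [4.0, 0.0], [0.0, 2.0], [0.0, -1.0]])
        assert direction_accuracy(preds, ["L", "R", "U", "D"]) == 100.0

    def test_tie_counts_incorrect(self):
        assert direction_accuracy(np.array([[1.0, 1.0]]), ["R"]) == 0.0

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(4)
        preds = rng.normal(size=(50, 2))
        intended = rng.choice(list("LRUD"), size=50)
        assert direction_accuracy(preds, intended) == \
            direction_accuracy(17.3 * preds, intended)

    def test_unknown_class_rejected(self):
        with pytest.raises(EegCursorError, match="unknown"):
            direction_accuracy(np.array([[1.0, 0.0]]), ["Z"])


class TestMar:
    def test_zero_rmse(self):
        assert mar(0.0, 90.0) == 0.0

    def test_zero_acc_smoothing(self):
        assert mar(1.0, 0.0) == pytest.approx(1e8)

    def test_published_worked_cell(self):
        # RMSE 5.62 at ACC 61.40% -> 0.09 at two decimals
        assert round(mar(5.62, 61.40), 2) == 0.09

    def test_monotonicity(self):
        assert mar(6.0, 60.0) > mar(5.0, 60.0)
        assert mar(5.0, 70.0) < mar(5.0, 60.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(EegCursorError):
            mar(-1.0, 50.0)
        with pytest.raises(EegCursorError):
            mar(1.0, -50.0)


class TestGateSuccess:
    START, TARGET = (0.0, 0.0), (1000.0, 0.0)

    def _line(self, points):
        return Trajectory(positions=np.asarray(points, dtype=float))

    def test_straight_line_succeeds(self):
        traj = self._line([[0, 0], [500, 0], [1000, 0]])
        assert gate_success(traj, self.START, self.TARGET)

    def test_wide_offset_fails(self):
        # crosses the midpoint plane at perpendicular offset 250 > 200
        traj = self._line([[0, 250], [1000, 250]])
        assert not gate_success(traj, self.START, self.TARGET)

    def test_offset_within_gate_succeeds(self):
        traj = self._line([[0, 150], [1000, 150]])
        assert gate_success(traj, self.START, self.TARGET)

    def test_stopping_short_fails(self):
        traj = self._line([[0, 0], [400, 0]])
        assert not gate_success(traj, self.START, self.TARGET)

    def test_first_crossing_decides(self):
        # first crossing misses the gate; a later recross inside must not count
        traj = self._line([[0, 300], [600, 300], [400, 0], [1000, 0]])
        assert not gate_success(traj, self.START, self.TARGET)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        wiggle = np.cumsum(rng.normal(scale=20.0, size=(40, 2)), axis=0)
        wiggle[:, 0] += np.linspace(0, 1000, 40)
        traj = self._line(np.vstack([[0.0, 0.0], wiggle]))
        base = gate_success(traj, self.START, self.TARGET)
        for angle in (np.pi / 2, 0.37, 2.1):
            c, s = np.cos(angle), np.sin(angle)
            rot = np.array([[c, -s], [s, c]])
            assert gate_success(
                Trajectory(traj.positions @ rot.T),
                self.START, rot @ np.asarray(self.TARGET)) == base

    def test_degenerate_rejected(self):
        with pytest.raises(EegCursorError, match="coincide"):
            gate_success(self._line([[0, 0], [1, 1]]), (2, 2), (2, 2))


class _OracleModel:
    """Duck-typed stand-in that predicts the labels exactly."""

    standardizer = None

    def __init__(self, labels):
        self._labels = np.asarray(labels, dtype=float)

    def forward(self, x):
        return self._labels


class TestEvaluate:
    def test_perfect_predictor(self):
        ds = toy_dataset(64, seed=9)
        report, trajectories = evaluate(_OracleModel(ds.labels), ds)
        assert report.rmse["TESTUD"]["horizontal"] == 0.0
        assert report.mar["TESTUD"] == 0.0
        assert report.acc["TEST"] == 100.0
        assert report.gate_successes == report.gate_trials

    def test_one_gate_outcome_per_trial(self):
        ds = toy_dataset(64, seed=9)
        report, trajectories = evaluate(_OracleModel(ds.labels), ds)
        assert report.gate_trials == len(np.unique(ds.trial_ids))
        assert set(trajectories) == set(np.unique(ds.trial_ids))

    def test_rmse_fields_match_direct_calls(self):
        ds = toy_dataset(48, seed=11)
        rng = np.random.default_rng(0)
        noisy = ds.labels + rng.normal(size=ds.labels.shape)
        report, _ = evaluate(_OracleModel(noisy), ds)
        assert report.rmse["TEST"]["horizontal"] == \
            pytest.approx(axis_rmse(ds.labels, noisy, "horizontal"))
        ud = np.isin(ds.class_labels, ["U", "D"])
        assert report.rmse["TESTUD"]["vertical"] == \
            pytest.approx(axis_rmse(ds.labels[ud], noisy[ud], "vertical"))

    def test_empty_view_reported_absent(self):
        ds = toy_dataset(64, seed=9).view(["U", "D"], "TESTUD")
        report, _ = evaluate(_OracleModel(ds.labels), ds)
        assert report.rmse["TESTLR"] is None
        assert report.mar["TESTLR"] is None

    def test_empty_testset_rejected(self):
        ds = toy_dataset(8).view([], "none")
        with pytest.raises(EegCursorError, match="empty"):
            evaluate(_OracleModel(np.zeros((0, 2))), ds)
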