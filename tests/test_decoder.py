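"""Losses, gradients and training behavior of the two-branch decoder."""

import numpy as np
import pytest

from eegcursor import (
    DecoderModel,
    EegCursorError,
    ModelConfig,
    TrainConfig,
    loss_mse,
    loss_total,
    loss_vc,
    predict_velocities,
    select_lambda,
    train,
)
from eegcursor.decoder import default_lambda_grid, loss_grad_yhat

from conftest import toy_dataset

TINY = ModelConfig(input_size=6, hidden_units=12, seq_len=8, init_seed=3)


class TestModelBasics:
    def test_forward_shape(self):
        model = DecoderModel(TINY)
        out = model.forward(np.zeros((5, 8, 6)))
        assert out.shape == (5, 2)

    def test_init_reproducible(self):
        a, b = DecoderModel(TINY), DecoderModel(TINY)
        for name in ("horizontal", "vertical"):
            for pa, pb in zip(a._params(name), b._params(name)):
                assert np.array_equal(pa, pb)

    def test_wrong_feature_count_rejected(self):
        model = DecoderModel(TINY)
        with pytest.raises(EegCursorError, match="features"):
            model.forward(np.zeros((5, 8, 7)))

    def test_untrained_predictions_finite(self):
        ds = toy_dataset(16)
        preds = predict_velocities(DecoderModel(TINY), ds)
        assert preds.shape == (16, 2)
        assert np.all(np.isfinite(preds))


class TestLossArithmetic:
    def test_mse_cases(self):
        assert loss_mse([[0.0, 0.0]], [[3.0, 4.0]]) == pytest.approx(25.0)
        assert loss_mse([[1.0, 2.0]], [[1.0, 2.0]]) == 0.0
        assert loss_mse([[0, 0], [0, 0]], [[1, 0], [0, 2]]) == pytest.approx(2.5)

    def test_mse_shape_mismatch(self):
        with pytest.raises(EegCursorError, match="mismatch"):
            loss_mse(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_vc_cases(self):
        assert loss_vc(["R"], [[3.0, 4.0]]) == pytest.approx(7.0)    # 16 - 9
        assert loss_vc(["U"], [[3.0, 4.0]]) == pytest.approx(-7.0)   # 9 - 16
        assert loss_vc(["L"], [[0.0, 0.0]]) == 0.0

    def test_vc_unknown_class(self):
        with pytest.raises(EegCursorError, match="unknown class"):
            loss_vc(["Q"], [[1.0, 1.0]])

    def test_total_composition(self):
        lv = loss_total([[5.0, 0.0]], [[3.0, 4.0]], ["R"], lambda_=0.01)
        assert lv.mse == pytest.approx(20.0)
        assert lv.vc == pytest.approx(7.0)
        assert lv.total == pytest.approx(20.07)
        assert loss_total([[5.0, 0.0]], [[3.0, 4.0]], ["R"], 0.0).total == \
            pytest.approx(20.0)
        # mse=20, vc=-7 at lambda=1 -> 13
        assert loss_total([[1.0, 0.0]], [[3.0, 4.0]], ["U"],
                          1.0).total == pytest.approx(20.0 - 7.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(EegCursorError, match="lambda"):
            loss_total([[0.0, 0.0]], [[1.0, 1.0]], ["R"], -0.1)

    def test_total_identity_on_random_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.normal(size=(16, 2))
            yhat = rng.normal(size=(16, 2))
            classes = rng.choice(list("LRUD"), size=16)
            lam = float(rng.uniform(0, 0.2))
            lv = loss_total(y, yhat, classes, lam)
            assert lv.total == pytest.approx(lv.mse + lam * lv.vc, rel=1e-9)

    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(6, 2))
        yhat = rng.normal(size=(6, 2))
        classes = np.array(["L", "R", "U", "D", "R", "U"])
        lam = 0.05
        grad = loss_grad_yhat(y, yhat, classes, lam)
        for i in range(6):
            for j in range(2):
                h = 1e-6
                up, dn = yhat.copy(), yhat.copy()
                up[i, j] += h
                dn[i, j] -= h
                fd = (loss_total(y, up, classes, lam).total
                      - loss_total(y, dn, classes, lam).total) / (2 * h)
                assert grad[i, j] == pytest.approx(fd, abs=1e-4)


class TestNetworkGradients:
    @pytest.mark.parametrize("n_layers", [1, 2])
    def test_bptt_matches_finite_differences(self, n_layers):
        rng = np.random.default_rng(0)
        cfg = ModelConfig(input_size=3, hidden_units=5, seq_len=6,
                          init_seed=1, n_layers=n_layers)
        model = DecoderModel(cfg)
        x = rng.normal(size=(4, 6, 3))
        y = rng.normal(size=(4, 2))
        classes = np.array(["L", "U", "R", "D"])
        lam = 0.01

        names = ("horizontal", "vertical")
        yhat_cols, caches, h_last = {}, {}, {}
        for n in names:
            yhat_cols[n], caches[n], h_last[n] = model._forward_branch(n, x)
        yhat = np.stack([yhat_cols[n] for n in names], axis=1)
        dy = loss_grad_yhat(y, yhat, classes, lam)

        def total():
            return loss_total(y, model.forward(x), classes, lam).total

        for col, n in enumerate(names):
            grads = model._backward_branch(n, caches[n], h_last[n], dy[:, col])
            for p, g in zip(model._params(n), grads):
                it = np.nditer(p, flags=["multi_index"])
                for _ in range(min(p.size, 8)):
                    idx = it.multi_index
                    h, orig = 1e-6, p[idx]
                    p[idx] = orig + h
                    lp = total()
                    p[idx] = orig - h
                    lm = total()
                    p[idx] = orig
                    fd = (lp - lm) / (2 * h)
                    denom = max(1e-8, abs(fd) + abs(g[idx]))
                    assert abs(fd - g[idx]) / denom < 1e-4
                    it.iternext()


class TestTraining:
    def test_loss_decreases(self):
        ds = toy_dataset(128)
        model = train(DecoderModel(TINY), ds, TrainConfig(epochs=100))
        assert model.history[-1].total < model.history[0].total

    def test_training_deterministic(self):
        ds = toy_dataset(64)
        cfg = TrainConfig(epochs=20, lambda_=0.01)
        a = train(DecoderModel(TINY), ds, cfg)
        b = train(DecoderModel(TINY), ds, cfg)
        for name in ("horizontal", "vertical"):
            for pa, pb in zip(a._params(name), b._params(name)):
                assert np.array_equal(pa, pb)

    def test_lambda_zero_is_pure_mse_training(self):
        ds = toy_dataset(64)
        a = train(DecoderModel(TINY), ds, TrainConfig(epochs=15, lambda_=0.0))
        for h in a.history:
            assert h.total == pytest.approx(h.mse)

    def test_empty_trainset_rejected(self):
        ds = toy_dataset(8)
        empty = ds.view([], "none")
        with pytest.raises(EegCursorError, match="empty"):
            train(DecoderModel(TINY), empty, TrainConfig(epochs=1))

    def test_history_records_components(self):
        ds = toy_dataset(32)
        model = train(DecoderModel(TINY), ds,
                      TrainConfig(epochs=6, lambda_=0.02, lambda_warmup=0.5))
        assert len(model.history) == 6
        for h in model.history:
            assert h.total == pytest.approx(h.mse + h.lambda_ * h.vc, rel=1e-6)
        # the VC weight is 0 during warm-up, 0.02 afterwards
        assert [h.lambda_ for h in model.history] == [0, 0, 0, 0.02, 0.02, 0.02]


class TestSelectLambda:
    def test_single_candidate(self):
        ds = toy_dataset(48)
        _, lam, table = select_lambda(ds, ds, TINY, TrainConfig(epochs=5),
                                      lambda_grid=[0.003])
        assert lam == 0.003
        assert len(table) == 1

    def test_huge_lambda_loses_to_zero(self):
        ds = toy_dataset(96, seed=2)
        model, lam, table = select_lambda(
            ds, toy_dataset(32, seed=3), TINY,
            TrainConfig(epochs=40), lambda_grid=[0.0, 1e6])
        assert lam == 0.0
        assert len(table) == 2
        assert table.set_index("lambda").loc[1e6, "test_mse"] > \
            table.set_index("lambda").loc[0.0, "test_mse"]

    def test_default_grid_contents(self):
        grid = default_lambda_grid()
        assert grid[0] == 0.0001
        assert 0.005 in grid and 0.05 in grid and grid[-1] == 0.1
        assert len(grid) == 20

    def test_empty_grid_rejected(self):
        ds = toy_dataset(16)
        with pytest.raises(EegCursorError, match="grid"):
            select_lambda(ds, ds, TINY, TrainConfig(epochs=1), lambda_grid=[])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        ds = toy_dataset(64)
        model = train(DecoderModel(TINY), ds, TrainConfig(epochs=10, lambda_=0.01))
        path = tmp_path / "model.npz"
        model.save(path)
        back = DecoderModel.load(path)
        assert back.lambda_ == model.lambda_
        assert np.array_equal(predict_velocities(back, ds),
                              predict_velocities(model, ds))

    def test_prediction_deterministic(self):
        ds = toy_dataset(32)
        model = train(DecoderModel(TINY), ds, TrainConfig(epochs=5))
        assert np.array_equal(predict_velocities(model, ds),
                              predict_velocities(model, ds))
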