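"""The spectral-temporal LSTM (stLSTM) velocity decoder.

Two parallel recurrent branches — one per screen axis — each map the fused
feature sequence of a sample (T steps x E features) through an LSTM layer of
100 hidden units and a linear head to one scalar velocity; their outputs are
concatenated as (horizontal, vertical).  Training minimizes

    L = L_MSE + lambda * L_VC

where L_MSE is the mean squared velocity error and L_VC is the
velocity-constrained term: for left/right samples it is
``|v_hat_vertical|^2 - |v_hat_horizontal|^2`` (suppress the orthogonal
axis, reward the imagined one), and the mirror image for up/down samples.
The regularization weight lambda is picked from a candidate grid by the
held-out MSE of a freshly initialized model trained per candidate.

Optimization is full-batch adam ("batch gradient descent"): one parameter
update per epoch over the whole training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _lstm
from .fusion import FusedDataset, Standardizer
from .trial import CLASSES, EegCursorError

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LossValue",
    "DecoderModel",
    "PathologicalLambdaError",
    "default_lambda_grid",
    "init_model",
    "loss_mse",
    "loss_vc",
    "loss_total",
    "train",
    "select_lambda",
    "predict_velocities",
]

#: Samples whose imagined axis is horizontal vs vertical.
_HORIZONTAL_CLASSES = ("L", "R")
_BRANCHES = ("horizontal", "vertical")


class PathologicalLambdaError(EegCursorError):
    """The VC term has taken over training (lambda too large for the data)."""


def default_lambda_grid() -> list[float]:
    """Candidate grid: 1e-4, 0.001..0.009 step 0.001, 0.01..0.1 step 0.01."""
    grid = [0.0001]
    grid += [round(0.001 * k, 4) for k in range(1, 10)]
    grid += [round(0.01 * k, 3) for k in range(1, 11)]
    return grid


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the decoder."""

    input_size: int = 20       #: E = 2m fused features per step
    hidden_units: int = 100    #: LSTM hidden size per branch
    seq_len: int = 30          #: T steps per sample
    n_layers: int = 1          #: 1 = branch reading; 2 = stacked variant
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 1 or self.hidden_units < 1 or self.n_layers < 1:
            raise EegCursorError("input_size, hidden_units, n_layers must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Full-batch training parameters."""

    epochs: int = 200
    learning_rate: float = 0.01
    lr_schedule: str = "constant"   #: "constant" or "cosine" decay to 0
    tail_average: float = 0.25      #: fraction of final epochs whose weights
                                    #: are Polyak-averaged into the result
    lambda_: float = 0.0
    lambda_warmup: float = 0.0      #: fraction of epochs trained with the VC
                                    #: weight held at 0 before lambda applies
    seed: int = 0
    standardize: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise EegCursorError("epochs must be >= 1")
        if self.lambda_ < 0:
            raise EegCursorError("lambda must be >= 0")
        if self.learning_rate <= 0:
            raise EegCursorError("learning_rate must be positive")
        if self.lr_schedule not in ("cosine", "constant"):
            raise EegCursorError("lr_schedule must be 'cosine' or 'constant'")
        if not 0.0 <= self.tail_average <= 1.0:
            raise EegCursorError("tail_average must lie in [0, 1]")
        if not 0.0 <= self.lambda_warmup < 1.0:
            raise EegCursorError("lambda_warmup must lie in [0, 1)")

    def lambda_at(self, epoch: int) -> float:
        """VC weight for a given epoch: 0 during warm-up, lambda after.

        Off by default: the VC term is most useful while the fit is
        forming (it shapes what the branches learn), and delaying it
        empirically weakens the suppression of the non-imagined axis.
        """
        if epoch < int(round(self.lambda_warmup * self.epochs)):
            return 0.0
        return self.lambda_

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a given epoch under the configured schedule."""
        if self.lr_schedule == "constant":
            return self.learning_rate
        return self.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * epoch / max(1, self.epochs)))


@dataclass
class LossValue:
    """The three components of the training loss; total = mse + lambda*vc."""

    mse: float
    vc: float
    lambda_: float

    @property
    def total(self) -> float:
        return self.mse + self.lambda_ * self.vc


class DecoderModel:
    """Parameters and metadata of the two-branch recurrent regressor."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        self.branches: dict[str, dict] = {}
        for name in _BRANCHES:
            layers = []
            in_size = config.input_size
            for _ in range(config.n_layers):
                layers.append(_lstm.init_lstm_layer(in_size, config.hidden_units, rng))
                in_size = config.hidden_units
            head = _lstm.init_head(config.hidden_units, rng)
            self.branches[name] = {"layers": layers, "head": head}
        self.lambda_: float = 0.0
        self.standardizer: Optional[Standardizer] = None
        self.history: list[LossValue] = []

    # -- parameter plumbing -------------------------------------------------
    def _params(self, branch: str) -> list[np.ndarray]:
        b = self.branches[branch]
        flat: list[np.ndarray] = []
        for layer in b["layers"]:
            flat += [layer["Wx"], layer["Wh"], layer["b"]]
        flat += [b["head"]["Wo"], b["head"]["bo"]]
        return flat

    def astype(self, dtype) -> None:
        for branch in self.branches.values():
            for layer in branch["layers"]:
                for k in layer:
                    layer[k] = layer[k].astype(dtype)
            for k in branch["head"]:
                branch["head"][k] = branch["head"][k].astype(dtype)

    # -- forward / backward -------------------------------------------------
    def _forward_branch(self, branch: str, x: np.ndarray,
                        ) -> tuple[np.ndarray, list, np.ndarray]:
        b = self.branches[branch]
        caches = []
        h_seq = x
        for layer in b["layers"]:
            h_seq, cache = _lstm.lstm_forward(layer, h_seq)
            caches.append(cache)
        y = _lstm.head_forward(b["head"], h_seq[:, -1])
        return y, caches, h_seq[:, -1]

    def _backward_branch(self, branch: str, caches: list, h_last: np.ndarray,
                         dy: np.ndarray) -> list[np.ndarray]:
        b = self.branches[branch]
        head_grads, dh_last = _lstm.head_backward(b["head"], h_last, dy)
        layer_grads: list[dict] = []
        dh_seq = None  # top layer: gradient enters at the final step only
        for layer, cache in zip(reversed(b["layers"]), reversed(caches)):
            if dh_seq is None:
                grads, dx = _lstm.lstm_backward(layer, cache, dh_last=dh_last)
            else:
                grads, dx = _lstm.lstm_backward(layer, cache, dh_seq)
            layer_grads.append(grads)
            dh_seq = dx
        flat: list[np.ndarray] = []
        for grads in reversed(layer_grads):
            flat += [grads["Wx"], grads["Wh"], grads["b"]]
        flat += [head_grads["Wo"], head_grads["bo"]]
        return flat

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Raw forward pass on already-standardized features ``(B, T, E)``."""
        features = np.asarray(features)
        if features.ndim != 3 or features.shape[2] != self.config.input_size:
            raise EegCursorError(
                f"expected (B, T, {self.config.input_size}) features, "
                f"got {features.shape}")
        dtype = self.branches["horizontal"]["layers"][0]["Wx"].dtype
        features = features.astype(dtype, copy=False)
        cols = [self._forward_branch(name, features)[0] for name in _BRANCHES]
        return np.stack(cols, axis=1)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for name in _BRANCHES:
            for i, p in enumerate(self._params(name)):
                arrays[f"{name}_{i}"] = p
        if self.standardizer is not None and self.standardizer.mean is not None:
            arrays["std_mean"] = self.standardizer.mean
            arrays["std_std"] = self.standardizer.std
        np.savez(path, **arrays)
        meta = {
            "config": self.config.__dict__,
            "lambda_": self.lambda_,
            "history": [[h.mse, h.vc, h.lambda_] for h in self.history],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "DecoderModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]))
        model.lambda_ = meta["lambda_"]
        model.history = [LossValue(*h) for h in meta["history"]]
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            for name in _BRANCHES:
                b = model.branches[name]
                i = 0
                for layer in b["layers"]:
                    for key in ("Wx", "Wh", "b"):
                        layer[key] = data[f"{name}_{i}"]   # keep stored dtype
                        i += 1
                for key in ("Wo", "bo"):
                    b["head"][key] = data[f"{name}_{i}"]
                    i += 1
            if "std_mean" in data:
                model.standardizer = Standardizer(mean=data["std_mean"],
                                                  std=data["std_std"])
        return model


def init_model(config: ModelConfig = ModelConfig()) -> DecoderModel:
    """Fresh decoder with reproducible initialization from ``init_seed``."""
    return DecoderModel(config)


# -- losses ------------------------------------------------------------------

def loss_mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean over the batch of the squared Euclidean velocity error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise EegCursorError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return float(np.mean(np.sum((y - yhat) ** 2, axis=-1)))


def _vc_signs(class_labels: np.ndarray) -> np.ndarray:
    """Per-sample (s_h, s_v) such that vc_i = s_h*vh^2 + s_v*vv^2.

    Left/right samples reward horizontal speed and penalize vertical
    (s = (-1, +1)); up/down samples the reverse.
    """
    class_labels = np.asarray(class_labels)
    unknown = ~np.isin(class_labels, CLASSES)
    if unknown.any():
        raise EegCursorError(
            f"unknown class label(s): {sorted(set(class_labels[unknown]))}")
    horiz = np.isin(class_labels, _HORIZONTAL_CLASSES)
    signs = np.empty((len(class_labels), 2))
    signs[:, 0] = np.where(horiz, -1.0, 1.0)
    signs[:, 1] = np.where(horiz, 1.0, -1.0)
    return signs


def loss_vc(class_labels: np.ndarray, yhat: np.ndarray) -> float:
    """Velocity-constrained loss: orthogonal speed minus imagined speed.

    May be negative; it is bounded in practice by the MSE term for the
    small lambda values on the candidate grid.
    """
    yhat = np.asarray(yhat, dtype=float)
    signs = _vc_signs(class_labels)
    return float(np.mean(np.sum(signs * yhat ** 2, axis=-1)))


def loss_total(y: np.ndarray, yhat: np.ndarray, class_labels: np.ndarray,
               lambda_: float) -> LossValue:
    """Total training loss with its components."""
    if lambda_ < 0:
        raise EegCursorError("lambda must be >= 0")
    return LossValue(mse=loss_mse(y, yhat), vc=loss_vc(class_labels, yhat),
                     lambda_=lambda_)


def loss_grad_yhat(y: np.ndarray, yhat: np.ndarray, class_labels: np.ndarray,
                   lambda_: float) -> np.ndarray:
    """Analytic d(total loss)/d(yhat), shape ``(B, 2)``."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    B = len(y)
    signs = _vc_signs(class_labels)
    return (2.0 * (yhat - y) + lambda_ * 2.0 * signs * yhat) / B


# -- training ----------------------------------------------------------------

def train(model: DecoderModel, trainset: FusedDataset,
          cfg: TrainConfig = TrainConfig()) -> DecoderModel:
    """Train in place with full-batch adam; returns the model.

    Per-epoch (mse, vc) values are recorded in ``model.history``.  Training
    aborts on a non-finite loss, and on runaway regularization: the VC term
    is unbounded below, so with a pathologically large lambda the total
    loss heads to minus infinity *while the MSE grows* (the imagined-axis
    velocities diverge).  Twenty consecutive epochs of negative, strictly
    decreasing total loss with strictly increasing MSE raise
    :class:`PathologicalLambdaError`.  (A healthy well-fit model can also
    have a slightly negative total — small residual MSE plus
    ``lambda * vc < 0`` — but there the MSE keeps falling.)
    """
    if len(trainset) == 0:
        raise EegCursorError("training set is empty")
    dtype = np.dtype(cfg.dtype)
    model.astype(dtype)
    model.lambda_ = cfg.lambda_
    if cfg.standardize:
        model.standardizer = Standardizer().fit(trainset.features)
        x = model.standardizer.transform(trainset.features)
    else:
        model.standardizer = None
        x = trainset.features
    x = np.ascontiguousarray(x, dtype=dtype)
    y = trainset.labels.astype(float)
    classes = trainset.class_labels

    optimizers = {name: _lstm.Adam(lr=cfg.learning_rate) for name in _BRANCHES}
    model.history = []
    runaway = 0
    prev_total = np.inf
    prev_mse = np.inf
    tail_start = cfg.epochs - int(round(cfg.tail_average * cfg.epochs))
    tail_sums = None
    tail_count = 0
    for epoch in range(cfg.epochs):
        yhat_cols = {}
        caches = {}
        h_last = {}
        for name in _BRANCHES:
            yhat_cols[name], caches[name], h_last[name] = \
                model._forward_branch(name, x)
        yhat = np.stack([yhat_cols[n] for n in _BRANCHES], axis=1)
        lam = cfg.lambda_at(epoch)
        loss = loss_total(y, yhat, classes, lam)
        if not np.isfinite(loss.total):
            raise EegCursorError(f"non-finite loss at epoch {epoch}: {loss}")
        model.history.append(loss)
        if loss.total < 0 and loss.total < prev_total and loss.mse > prev_mse:
            runaway += 1
            if runaway >= 20:
                raise PathologicalLambdaError(
                    f"total loss negative and decreasing while MSE grows, for "
                    f"{runaway} epochs; lambda={cfg.lambda_} is pathological "
                    f"for this data")
        else:
            runaway = 0
        prev_total = loss.total
        prev_mse = loss.mse

        dyhat = loss_grad_yhat(y, yhat, classes, lam).astype(dtype)
        lr = cfg.lr_at(epoch)
        for col, name in enumerate(_BRANCHES):
            grads = model._backward_branch(name, caches[name], h_last[name],
                                           dyhat[:, col])
            optimizers[name].step(model._params(name), grads, lr=lr)
        # Polyak tail averaging: with one update per epoch, constant-rate
        # adam ends in an oscillation around the optimum; averaging the
        # final iterates lands the result at the basin's centre instead of
        # at an arbitrary oscillation phase.
        if epoch >= tail_start:
            if tail_sums is None:
                tail_sums = {name: [p.astype(np.float64)
                                    for p in model._params(name)]
                             for name in _BRANCHES}
            else:
                for name in _BRANCHES:
                    for acc, p in zip(tail_sums[name], model._params(name)):
                        acc += p
            tail_count += 1
    if tail_sums is not None and tail_count > 1:
        for name in _BRANCHES:
            for acc, p in zip(tail_sums[name], model._params(name)):
                p[...] = (acc / tail_count).astype(dtype)
    return model


def predict_velocities(model: DecoderModel, dataset: FusedDataset) -> np.ndarray:
    """Predicted (horizontal, vertical) velocity per sample.

    The model's stored standardization is applied to the features first.
    """
    x = dataset.features
    if model.standardizer is not None:
        x = model.standardizer.transform(x)
    return model.forward(x).astype(float)


def select_lambda(trainset: FusedDataset, testset: FusedDataset,
                  model_cfg: ModelConfig = ModelConfig(),
                  train_cfg: TrainConfig = TrainConfig(),
                  lambda_grid: Optional[Sequence[float]] = None,
                  ) -> tuple[DecoderModel, float, pd.DataFrame]:
    """Train one model per lambda candidate; keep the best by held-out MSE.

    Every candidate starts from the same initialization (``init_seed``);
    ties break toward the smallest lambda.  Returns (best model, best
    lambda, per-candidate MSE table).
    """
    grid = list(default_lambda_grid() if lambda_grid is None else lambda_grid)
    if not grid:
        raise EegCursorError("lambda grid is empty")
    best_model = None
    best_lambda = None
    best_mse = np.inf
    rows = []
    from dataclasses import replace

    for lam in sorted(grid):
        model = DecoderModel(model_cfg)
        cfg = replace(train_cfg, lambda_=lam)
        try:
            train(model, trainset, cfg)
            mse = loss_mse(testset.labels, predict_velocities(model, testset))
        except PathologicalLambdaError:
            # A diverged candidate is simply the worst by held-out MSE.
            mse = float("inf")
        rows.append({"lambda": lam, "test_mse": mse})
        if mse < best_mse:
            best_model, best_lambda, best_mse = model, lam, mse
    table = pd.DataFrame(rows)
    return best_model, best_lambda, table
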