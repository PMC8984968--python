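"""Minimal numpy LSTM with full backpropagation through time.

Only what the velocity decoder needs: a uni-directional LSTM layer, a
linear head reading the final hidden state, and an adam optimizer.  Forward
and backward are written with batched BLAS matmuls (``(B, 4H)`` gate blocks
per time step) and in-place elementwise updates; the gate layout is
``i | f | o | g`` so one contiguous ``expit`` covers all three sigmoid
gates.  Gradients are exact and verified against central finite differences
in the test suite.

Everything is plain float arrays in parameter dicts, which keeps runs
bit-reproducible for a fixed seed and makes serialization a plain ``npz``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def init_lstm_layer(input_size: int, hidden: int, rng: np.random.Generator,
                    dtype=np.float64) -> dict[str, np.ndarray]:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization, gates stacked i|f|o|g."""
    bound = 1.0 / np.sqrt(hidden)
    def u(*shape):
        return rng.uniform(-bound, bound, size=shape).astype(dtype)
    return {"Wx": u(input_size, 4 * hidden), "Wh": u(hidden, 4 * hidden),
            "b": u(4 * hidden)}


def init_head(hidden: int, rng: np.random.Generator,
              dtype=np.float64) -> dict[str, np.ndarray]:
    bound = 1.0 / np.sqrt(hidden)
    return {"Wo": rng.uniform(-bound, bound, size=(hidden, 1)).astype(dtype),
            "bo": rng.uniform(-bound, bound, size=(1,)).astype(dtype)}


def lstm_forward(params: dict, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run one LSTM layer over ``x`` of shape ``(B, T, E)``.

    Returns the hidden-state sequence ``(B, T, H)`` and a cache for
    :func:`lstm_backward`.
    """
    B, T, _ = x.shape
    H = params["Wh"].shape[0]
    dtype = params["Wx"].dtype
    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    gates = np.empty((T, B, 4 * H), dtype=dtype)   # post-activation i|f|o|g
    cs = np.empty((T, B, H), dtype=dtype)
    tcs = np.empty((T, B, H), dtype=dtype)         # tanh(c), reused in backward
    hs = np.empty((T, B, H), dtype=dtype)
    # Input contributions (plus bias) for all steps in one gemm; x is
    # constant per epoch, only the recurrent term needs the time loop.
    xw = (x.reshape(B * T, -1) @ params["Wx"]).reshape(B, T, 4 * H)
    xw += params["b"]
    tmp = np.empty((B, H), dtype=dtype)
    for t in range(T):
        z = gates[t]
        np.matmul(h, params["Wh"], out=z)
        z += xw[:, t]
        expit(z[:, :3 * H], out=z[:, :3 * H])      # i, f, o
        np.tanh(z[:, 3 * H:], out=z[:, 3 * H:])    # g
        i = z[:, :H]
        f = z[:, H:2 * H]
        o = z[:, 2 * H:3 * H]
        g = z[:, 3 * H:]
        c_new = cs[t]
        np.multiply(f, c, out=c_new)
        np.multiply(i, g, out=tmp)
        c_new += tmp
        c = c_new
        tc = tcs[t]
        np.tanh(c, out=tc)
        h = hs[t]
        np.multiply(o, tc, out=h)
    cache = {"x": x, "gates": gates, "cs": cs, "tcs": tcs, "hs": hs}
    return hs.transpose(1, 0, 2), cache


def lstm_backward(params: dict, cache: dict, dh_seq: np.ndarray | None = None,
                  dh_last: np.ndarray | None = None,
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Backprop through time.

    Pass either ``dh_seq``, the loss gradient w.r.t. the whole hidden-state
    sequence ``(B, T, H)``, or — when only the final hidden state feeds the
    head — just ``dh_last`` of shape ``(B, H)``.  Returns parameter
    gradients and the gradient w.r.t. the layer input ``(B, T, E)``.
    """
    x, gates, cs, tcs, hs = (cache["x"], cache["gates"], cache["cs"],
                             cache["tcs"], cache["hs"])
    B, T, E = x.shape
    H = params["Wh"].shape[0]
    dtype = params["Wx"].dtype
    dWh = np.zeros_like(params["Wh"])
    dz_all = np.empty((T, B, 4 * H), dtype=dtype)
    dh = np.zeros((B, H), dtype=dtype)
    dc = np.zeros((B, H), dtype=dtype)
    for t in range(T - 1, -1, -1):
        if dh_seq is not None:
            dh = dh + dh_seq[:, t]
        elif t == T - 1 and dh_last is not None:
            dh = dh + dh_last
        z = gates[t]
        i = z[:, :H]
        f = z[:, H:2 * H]
        o = z[:, 2 * H:3 * H]
        g = z[:, 3 * H:]
        tc = tcs[t]
        c_prev = cs[t - 1] if t > 0 else None
        # dc += dh * o * (1 - tanh(c)^2)
        dc += dh * o * (1.0 - tc * tc)
        dz = dz_all[t]
        np.multiply(dh, tc, out=dz[:, 2 * H:3 * H])           # do
        np.multiply(dc, g, out=dz[:, :H])                     # di
        if t > 0:
            np.multiply(dc, c_prev, out=dz[:, H:2 * H])       # df
        else:
            dz[:, H:2 * H] = 0.0
        np.multiply(dc, i, out=dz[:, 3 * H:])                 # dg
        # through the activations, in place
        dz[:, :3 * H] *= z[:, :3 * H]
        dz[:, :3 * H] *= 1.0 - z[:, :3 * H]
        dz[:, 3 * H:] *= 1.0 - g * g
        if t > 0:
            dWh += hs[t - 1].T @ dz
        dh = dz @ params["Wh"].T
        dc *= f
    # Input-side weight gradients in one batched gemm.
    dz_flat = np.ascontiguousarray(dz_all.transpose(1, 0, 2)).reshape(B * T, 4 * H)
    dWx = x.reshape(B * T, E).T @ dz_flat
    db = dz_flat.sum(axis=0)
    dx = (dz_flat @ params["Wx"].T).reshape(B, T, E)
    return {"Wx": dWx, "Wh": dWh, "b": db}, dx


def head_forward(params: dict, h_last: np.ndarray) -> np.ndarray:
    """Linear read-out of the final hidden state -> ``(B,)`` scalars."""
    return (h_last @ params["Wo"] + params["bo"])[:, 0]


def head_backward(params: dict, h_last: np.ndarray, dy: np.ndarray,
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    dy = dy[:, None]
    return ({"Wo": h_last.T @ dy, "bo": dy.sum(axis=0)},
            dy @ params["Wo"].T)


class Adam:
    """Standard adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr: float | None = None) -> None:
        """Update arrays in place; pairing of params/grads is positional.

        ``lr`` overrides the base learning rate for this step (schedules).
        """
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for idx, (p, g) in enumerate(zip(params, grads)):
            if idx not in self.m:
                self.m[idx] = np.zeros_like(p)
                self.v[idx] = np.zeros_like(p)
            m = self.m[idx]
            v = self.v[idx]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
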