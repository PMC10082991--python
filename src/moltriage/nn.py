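"""Minimal NumPy neural-network primitives used by the generator and
discriminator: parameter initialization, a stacked LSTM with full
backpropagation through time, softmax/sigmoid helpers, and Adam.

Parameters and gradients travel as flat ``dict[str, ndarray]`` so the
optimizer and checkpointing stay agnostic of model structure.  All
gradients here are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "init_lstm_params",
    "lstm_forward",
    "lstm_backward",
    "lstm_step",
    "softmax",
    "sigmoid",
    "clip_grads",
    "zeros_like_params",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # clipping at ±60 keeps exp finite; the result is exact to float64
    z = np.clip(z, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


def init_lstm_params(
    d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float64
) -> dict:
    """Glorot-scaled LSTM weights; forget-gate bias starts at 1."""
    sw = np.sqrt(6.0 / (d_in + 4 * hidden))
    su = np.sqrt(6.0 / (hidden + 4 * hidden))
    b = np.zeros(4 * hidden, dtype=dtype)
    b[hidden : 2 * hidden] = 1.0
    return {
        "W": rng.uniform(-sw, sw, (d_in, 4 * hidden)).astype(dtype),
        "U": rng.uniform(-su, su, (hidden, 4 * hidden)).astype(dtype),
        "b": b,
    }


def lstm_step(x, h_prev, c_prev, W, U, b):
    """One LSTM step for a batch.  Gate order: input, forget, cell, output."""
    H = h_prev.shape[1]
    a = x @ W + h_prev @ U + b
    i = sigmoid(a[:, :H])
    f = sigmoid(a[:, H : 2 * H])
    g = np.tanh(a[:, 2 * H : 3 * H])
    o = sigmoid(a[:, 3 * H :])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    return h, c, (i, f, g, o, tc, c_prev)


def lstm_forward(x, params, h0=None, c0=None):
    """Run an LSTM layer over a full (B, L, D) input.

    Returns the per-step hidden states (B, L, H) and a cache for
    :func:`lstm_backward`.
    """
    B, L, _ = x.shape
    H = params["U"].shape[0]
    h = np.zeros((B, H), dtype=x.dtype) if h0 is None else h0
    c = np.zeros((B, H), dtype=x.dtype) if c0 is None else c0
    hs = np.empty((B, L, H), dtype=x.dtype)
    gates = []
    h_prevs = np.empty((B, L, H), dtype=x.dtype)
    for t in range(L):
        h_prevs[:, t] = h
        h, c, g = lstm_step(x[:, t], h, c, params["W"], params["U"], params["b"])
        hs[:, t] = h
        gates.append(g)
    cache = (x, h_prevs, gates, H)
    return hs, (h, c), cache


def lstm_backward(dhs, cache, params):
    """Backprop through :func:`lstm_forward`.

    ``dhs`` is dLoss/d(hidden states), shape (B, L, H).  Returns the
    gradient w.r.t. the layer input and a parameter-gradient dict.
    """
    x, h_prevs, gates, H = cache
    B, L, _ = x.shape
    dW = np.zeros_like(params["W"])
    dU = np.zeros_like(params["U"])
    db = np.zeros_like(params["b"])
    dx = np.empty_like(x)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dc_next = np.zeros((B, H), dtype=x.dtype)
    for t in range(L - 1, -1, -1):
        i, f, g, o, tc, c_prev = gates[t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x[:, t].T @ da
        dU += h_prevs[:, t].T @ da
        db += da.sum(axis=0)
        dx[:, t] = da @ params["W"].T
        dh_next = da @ params["U"].T
    return dx, {"W": dW, "U": dU, "b": db}


def clip_grads(grads: dict, max_norm: float) -> float:
    """Global-norm gradient clipping in place; returns the norm."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def zeros_like_params(params: dict) -> dict:
    return {k: np.zeros_like(v) for k, v in params.items()}


class Adam:
    """Adam optimizer over a flat parameter dict."""

    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        """One update, minimizing the loss whose gradient is ``grads``."""
        if self.lr == 0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
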