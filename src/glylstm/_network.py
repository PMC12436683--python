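"""Numpy implementation of the stacked-LSTM classifier.

Forward, backpropagation through time and the Adam update are implemented
directly on float32 arrays.  The fixed layer stack is::

    LSTM(u1, tanh, L2 on kernel) -> dropout
    -> LSTM(u2, tanh, L2 on kernel) -> dropout
    -> Dense(ud, ReLU) -> dropout
    -> Dense(2, softmax)

Gate order inside the packed weight matrices is (i, f, g, o).  All
randomness (initialization, dropout masks) flows from explicit
``numpy.random.Generator`` objects, so results are bit-reproducible for a
given seed on a given platform.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

DTYPE = np.float32


def _glorot_uniform(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _orthogonal(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    # QR of a Gaussian matrix; sign-fixed so the decomposition is unique.
    a = rng.standard_normal(size=(max(shape), min(shape)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if q.shape != shape:
        q = q.T
    return q[: shape[0], : shape[1]].astype(DTYPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_init(rng: np.random.Generator, input_dim: int, units: int) -> Dict[str, np.ndarray]:
    wx = _glorot_uniform(rng, (input_dim, 4 * units))
    wh = np.concatenate(
        [_orthogonal(rng, (units, units)) for _ in range(4)], axis=1
    ).astype(DTYPE)
    b = np.zeros(4 * units, dtype=DTYPE)
    b[units: 2 * units] = 1.0  # forget-gate bias starts open
    return {"Wx": wx, "Wh": wh, "b": b}


def _lstm_forward(X: np.ndarray, p: Dict[str, np.ndarray]):
    """Run an LSTM over (B, T, D) input; returns the full hidden sequence."""
    B, T, _ = X.shape
    H = p["Wh"].shape[0]
    zx = X @ p["Wx"] + p["b"]  # (B, T, 4H)
    hs = np.zeros((B, T, H), dtype=DTYPE)
    gates = np.zeros((B, T, 4 * H), dtype=DTYPE)
    cs = np.zeros((B, T, H), dtype=DTYPE)
    tanh_cs = np.zeros((B, T, H), dtype=DTYPE)
    h = np.zeros((B, H), dtype=DTYPE)
    c = np.zeros((B, H), dtype=DTYPE)
    for t in range(T):
        z = zx[:, t] + h @ p["Wh"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H: 2 * H])
        g = np.tanh(z[:, 2 * H: 3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[:, t, :H] = i
        gates[:, t, H: 2 * H] = f
        gates[:, t, 2 * H: 3 * H] = g
        gates[:, t, 3 * H:] = o
        cs[:, t] = c
        tanh_cs[:, t] = tc
        hs[:, t] = h
    cache = (X, hs, gates, cs, tanh_cs)
    return hs, cache


def _lstm_backward(dhs: np.ndarray, p: Dict[str, np.ndarray], cache):
    """BPTT given upstream gradients on the full hidden sequence (B, T, H)."""
    X, hs, gates, cs, tanh_cs = cache
    B, T, D = X.shape
    H = p["Wh"].shape[0]
    dWx = np.zeros_like(p["Wx"])
    dWh = np.zeros_like(p["Wh"])
    db = np.zeros_like(p["b"])
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, H), dtype=DTYPE)
    dc_next = np.zeros((B, H), dtype=DTYPE)
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H: 2 * H]
        g = gates[:, t, 2 * H: 3 * H]
        o = gates[:, t, 3 * H:]
        tc = tanh_cs[:, t]
        c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=DTYPE)
        h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=DTYPE)

        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i

        dz = np.empty((B, 4 * H), dtype=DTYPE)
        dz[:, :H] = di * i * (1.0 - i)
        dz[:, H: 2 * H] = df * f * (1.0 - f)
        dz[:, 2 * H: 3 * H] = dg * (1.0 - g * g)
        dz[:, 3 * H:] = do * o * (1.0 - o)

        dWx += X[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ p["Wx"].T
        dh_next = dz @ p["Wh"].T
        dc_next = dc * f
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


class LSTMNetwork:
    """The fixed stacked-LSTM classifier, trained by mini-batch Adam."""

    def __init__(self, input_width: int, units1: int = 64, units2: int = 32,
                 dense_units: int = 16, n_classes: int = 2,
                 dropout_rates: Tuple[float, float, float] = (0.2, 0.2, 0.2),
                 l2: float = 0.01, seed: int = 0):
        self.input_width = int(input_width)
        self.units1 = int(units1)
        self.units2 = int(units2)
        self.dense_units = int(dense_units)
        self.n_classes = int(n_classes)
        self.dropout_rates = tuple(float(r) for r in dropout_rates)
        self.l2 = float(l2)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.params: Dict[str, np.ndarray] = {}
        for key, val in _lstm_init(rng, self.input_width, self.units1).items():
            self.params[f"l1_{key}"] = val
        for key, val in _lstm_init(rng, self.units1, self.units2).items():
            self.params[f"l2_{key}"] = val
        self.params["d1_W"] = _glorot_uniform(rng, (self.units2, self.dense_units))
        self.params["d1_b"] = np.zeros(self.dense_units, dtype=DTYPE)
        self.params["out_W"] = _glorot_uniform(rng, (self.dense_units, self.n_classes))
        self.params["out_b"] = np.zeros(self.n_classes, dtype=DTYPE)

    # -- forward ---------------------------------------------------------

    def num_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _sub(self, prefix: str) -> Dict[str, np.ndarray]:
        n = len(prefix) + 1
        return {k[n:]: v for k, v in self.params.items() if k.startswith(prefix + "_")}

    def forward(self, X: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Class probabilities (and caches when ``training``).

        Dropout is active only in training mode; inference is deterministic.
        """
        X = np.ascontiguousarray(X, dtype=DTYPE)
        if X.ndim != 3 or X.shape[2] != self.input_width:
            raise ValueError(
                f"expected input of shape (n, T, {self.input_width}), got {X.shape}"
            )
        p1, p2 = self._sub("l1"), self._sub("l2")
        hs1, cache1 = _lstm_forward(X, p1)
        masks = [None, None, None]
        if training and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        h1d = hs1
        if training and self.dropout_rates[0] > 0:
            masks[0] = (rng.random(hs1.shape) >= self.dropout_rates[0]).astype(DTYPE) / (
                1.0 - self.dropout_rates[0])
            h1d = hs1 * masks[0]
        hs2, cache2 = _lstm_forward(h1d, p2)
        h2 = hs2[:, -1]  # final hidden state feeds the dense head
        h2d = h2
        if training and self.dropout_rates[1] > 0:
            masks[1] = (rng.random(h2.shape) >= self.dropout_rates[1]).astype(DTYPE) / (
                1.0 - self.dropout_rates[1])
            h2d = h2 * masks[1]
        a1 = h2d @ self.params["d1_W"] + self.params["d1_b"]
        r1 = np.maximum(a1, 0.0)
        r1d = r1
        if training and self.dropout_rates[2] > 0:
            masks[2] = (rng.random(r1.shape) >= self.dropout_rates[2]).astype(DTYPE) / (
                1.0 - self.dropout_rates[2])
            r1d = r1 * masks[2]
        logits = r1d @ self.params["out_W"] + self.params["out_b"]
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        probs = e / e.sum(axis=1, keepdims=True)
        if not training:
            return probs
        caches = (X, cache1, h1d, cache2, h2, h2d, a1, r1, r1d, masks)
        return probs, caches

    # -- loss & gradients --------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator):
        """Mean cross-entropy (+ L2 kernel penalty) and parameter gradients."""
        probs, caches = self.forward(X, training=True, rng=rng)
        (Xc, cache1, h1d, cache2, h2, h2d, a1, r1, r1d, masks) = caches
        B = X.shape[0]
        eps = 1e-12
        self._last_batch_correct = int(np.sum(probs.argmax(axis=1) == y))
        data_loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        reg_loss = 0.5 * self.l2 * (
            float(np.sum(self.params["l1_Wx"] ** 2)) +
            float(np.sum(self.params["l2_Wx"] ** 2))
        )
        grads: Dict[str, np.ndarray] = {}

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits = (dlogits / B).astype(DTYPE)

        grads["out_W"] = r1d.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dr1d = dlogits @ self.params["out_W"].T
        dr1 = dr1d * masks[2] if masks[2] is not None else dr1d
        da1 = dr1 * (a1 > 0)
        grads["d1_W"] = h2d.T @ da1
        grads["d1_b"] = da1.sum(axis=0)
        dh2d = da1 @ self.params["d1_W"].T
        dh2 = dh2d * masks[1] if masks[1] is not None else dh2d

        dhs2 = np.zeros((B, X.shape[1], self.units2), dtype=DTYPE)
        dhs2[:, -1] = dh2
        dh1d, g2 = _lstm_backward(dhs2, self._sub("l2"), cache2)
        for k, v in g2.items():
            grads[f"l2_{k}"] = v
        dhs1 = dh1d * masks[0] if masks[0] is not None else dh1d
        _, g1 = _lstm_backward(dhs1, self._sub("l1"), cache1)
        for k, v in g1.items():
            grads[f"l1_{k}"] = v

        grads["l1_Wx"] = grads["l1_Wx"] + self.l2 * self.params["l1_Wx"]
        grads["l2_Wx"] = grads["l2_Wx"] + self.l2 * self.params["l2_Wx"]
        return data_loss + reg_loss, grads

    def get_weights(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(weights[k], dtype=DTYPE).copy()


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Dict[str, np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
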