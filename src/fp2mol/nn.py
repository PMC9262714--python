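"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces the generative model needs — dense layers,
batch normalization with moving statistics, a multi-layer LSTM with
backprop through time, softmax cross-entropy, and the Adam optimizer — in
plain NumPy with hand-derived gradients (validated by finite differences in
the test suite).

Conventions: parameters live in per-layer dicts ``{name: ndarray}``;
``forward``/``forward_seq`` cache activations; ``backward`` consumes the
upstream gradient, accumulates parameter gradients into ``grads`` and
returns the gradient with respect to the input. LSTM cells follow the
standard formulation: tanh cell activation, sigmoid gates, gate order
(input, forget, cell, output), forget-gate bias initialized to 1.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Dense:
    """Fully connected layer, optionally rectified-linear."""

    def __init__(self, rng, d_in: int, units: int, relu: bool = False):
        self.params = {"W": glorot_uniform(rng, (d_in, units)),
                       "b": np.zeros(units)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.relu = relu
        self._cache = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        y = x @ self.params["W"] + self.params["b"]
        if self.relu:
            y = np.maximum(y, 0.0)
        if cache:
            self._cache = (x, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, y = self._cache
        if self.relu:
            dy = dy * (y > 0)
        flat_x = x.reshape(-1, x.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += flat_x.T @ flat_dy
        self.grads["b"] += flat_dy.sum(axis=0)
        return dy @ self.params["W"].T


class BatchNorm:
    """Per-channel batch normalization (eps 0.001, momentum 0.99).

    In training mode normalizes with batch statistics and updates moving
    statistics; in inference mode uses the stored moving statistics, making
    the forward pass deterministic per sample.
    """

    def __init__(self, d: int, eps: float = 1e-3, momentum: float = 0.99):
        self.params = {"gamma": np.ones(d), "beta": np.zeros(d)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.moving_mean = np.zeros(d)
        self.moving_var = np.ones(d)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        shape = x.shape
        x2 = x.reshape(-1, shape[-1])
        if training:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.moving_mean = (self.momentum * self.moving_mean
                                + (1 - self.momentum) * mean)
            self.moving_var = (self.momentum * self.moving_var
                               + (1 - self.momentum) * var)
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x2 - mean) * inv
        y = self.params["gamma"] * xhat + self.params["beta"]
        self._cache = (xhat, inv, training)
        return y.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = dy.shape
        dy2 = dy.reshape(-1, shape[-1])
        xhat, inv, training = self._cache
        self.grads["gamma"] += (dy2 * xhat).sum(axis=0)
        self.grads["beta"] += dy2.sum(axis=0)
        g = self.params["gamma"]
        if not training:
            return (dy2 * g * inv).reshape(shape)
        m = dy2.shape[0]
        dxhat = dy2 * g
        dx = inv * (dxhat - dxhat.mean(axis=0)
                    - xhat * (dxhat * xhat).mean(axis=0))
        return dx.reshape(shape)


class LSTMStack:
    """Stack of LSTM layers with full-sequence BPTT and a stepwise API."""

    def __init__(self, rng, d_in: int, units: int, n_layers: int):
        self.units = units
        self.n_layers = n_layers
        self.layers = []
        for li in range(n_layers):
            d = d_in if li == 0 else units
            Wh = np.concatenate([orthogonal(rng, units) for _ in range(4)], axis=1)
            b = np.zeros(4 * units)
            b[units : 2 * units] = 1.0  # forget gate bias
            self.layers.append({"Wx": glorot_uniform(rng, (d, 4 * units)),
                                "Wh": Wh, "b": b})
        self.grads = [{k: np.zeros_like(v) for k, v in lay.items()}
                      for lay in self.layers]
        self._cache = None

    # -- shared cell ------------------------------------------------------
    def _cell(self, lay, x, h_prev, c_prev):
        u = self.units
        z = x @ lay["Wx"] + h_prev @ lay["Wh"] + lay["b"]
        i = sigmoid(z[:, :u])
        f = sigmoid(z[:, u : 2 * u])
        g = np.tanh(z[:, 2 * u : 3 * u])
        o = sigmoid(z[:, 3 * u :])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, c, (i, f, g, o, tc)

    # -- sequence API -----------------------------------------------------
    def forward_seq(self, X: np.ndarray, init_states=None) -> np.ndarray:
        """Run the stack over X (B, T, d_in); returns top-layer H (B, T, U).

        ``init_states``: optional list of (h0, c0) pairs per layer.
        """
        B, T, _ = X.shape
        u = self.units
        if init_states is None:
            init_states = [(np.zeros((B, u)), np.zeros((B, u)))
                           for _ in range(self.n_layers)]
        cache = []
        cur = X
        for li, lay in enumerate(self.layers):
            h, c = init_states[li]
            hs = np.empty((B, T, u))
            steps = []
            for t in range(T):
                x_t = cur[:, t]
                h_prev, c_prev = h, c
                h, c, gates = self._cell(lay, x_t, h_prev, c_prev)
                hs[:, t] = h
                steps.append((x_t, h_prev, c_prev, gates))
            cache.append(steps)
            cur = hs
        self._cache = (cache, init_states)
        return cur

    def backward_seq(self, dH: np.ndarray):
        """Backprop through time; returns (dX, d_init_states)."""
        cache, init_states = self._cache
        u = self.units
        B, T, _ = dH.shape
        d_init = []
        dh_out = dH
        for li in reversed(range(self.n_layers)):
            lay = self.layers[li]
            gr = self.grads[li]
            steps = cache[li]
            d_in = np.empty((B, T, lay["Wx"].shape[0]))
            dh_next = np.zeros((B, u))
            dc_next = np.zeros((B, u))
            for t in reversed(range(T)):
                x_t, h_prev, c_prev, (i, f, g, o, tc) = steps[t]
                dh = dh_out[:, t] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     dg * (1 - g * g), do * o * (1 - o)], axis=1)
                gr["Wx"] += x_t.T @ dz
                gr["Wh"] += h_prev.T @ dz
                gr["b"] += dz.sum(axis=0)
                d_in[:, t] = dz @ lay["Wx"].T
                dh_next = dz @ lay["Wh"].T
            d_init.append((dh_next, dc_next))
            dh_out = d_in
        d_init.reverse()
        return dh_out, d_init

    # -- stepwise API (inference) ----------------------------------------
    def zero_state(self, batch: int):
        u = self.units
        return [(np.zeros((batch, u)), np.zeros((batch, u)))
                for _ in range(self.n_layers)]

    def step(self, x: np.ndarray, states):
        """Advance one time step; returns (h_top, new_states). No cache."""
        new_states = []
        cur = x
        for lay, (h, c) in zip(self.layers, states):
            h, c, _ = self._cell(lay, cur, h, c)
            new_states.append((h, c))
            cur = h
        return cur, new_states


class Adam:
    """Adam optimizer over a flat {name: array} parameter mapping."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def collect_params(modules: dict[str, object]) -> dict[str, np.ndarray]:
    """Flatten layer parameter dicts into one namespaced mapping.

    LSTM stacks contribute per-layer entries ``<name>.<li>.<key>``; plain
    layers contribute ``<name>.<key>``. Arrays are shared, not copied.
    """
    flat: dict[str, np.ndarray] = {}
    for name, mod in modules.items():
        if isinstance(mod, LSTMStack):
            for li, lay in enumerate(mod.layers):
                for k, arr in lay.items():
                    flat[f"{name}.{li}.{k}"] = arr
        else:
            for k, arr in mod.params.items():
                flat[f"{name}.{k}"] = arr
    return flat


def collect_grads(modules: dict[str, object]) -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    for name, mod in modules.items():
        if isinstance(mod, LSTMStack):
            for li, gr in enumerate(mod.grads):
                for k, arr in gr.items():
                    flat[f"{name}.{li}.{k}"] = arr
        else:
            for k, arr in mod.grads.items():
                flat[f"{name}.{k}"] = arr
    return flat


def zero_grads(modules: dict[str, object]) -> None:
    for mod in modules.values():
        if isinstance(mod, LSTMStack):
            for gr in mod.grads:
                for arr in gr.values():
                    arr[...] = 0.0
        else:
            for arr in mod.grads.values():
                arr[...] = 0.0
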