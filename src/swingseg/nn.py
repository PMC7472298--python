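"""Minimal neural-network engine: the layers the segmentation models need.

Implemented directly on numpy (LSTM recurrences through numba-compiled
kernels) with hand-derived backward passes and an Adam optimizer.  The
engine is deliberately small -- dense, tanh, 1-D convolution, max pooling
and bidirectional LSTM stacks are all the two models require -- and fully
deterministic given a seeded ``numpy`` Generator.  Gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# numba LSTM kernels (time-major: (T, B, ...))


@njit(cache=True, fastmath=True)
def _lstm_forward(xp, Wh, H):
    """xp: (T,B,4H) input projections (x @ Wx + b).  Returns h, c and the
    post-activation gate stash (i, f, g, o) needed for the backward pass."""
    T, B, H4 = xp.shape
    h = np.zeros((T, B, H), dtype=xp.dtype)
    c = np.zeros((T, B, H), dtype=xp.dtype)
    gates = np.zeros((T, B, H4), dtype=xp.dtype)
    hprev = np.zeros((B, H), dtype=xp.dtype)
    cprev = np.zeros((B, H), dtype=xp.dtype)
    for t in range(T):
        g = xp[t] + np.dot(hprev, Wh)
        for b in range(B):
            for j in range(H):
                i_ = 1.0 / (1.0 + np.exp(-g[b, j]))
                f_ = 1.0 / (1.0 + np.exp(-g[b, H + j]))
                g_ = np.tanh(g[b, 2 * H + j])
                o_ = 1.0 / (1.0 + np.exp(-g[b, 3 * H + j]))
                cv = f_ * cprev[b, j] + i_ * g_
                c[t, b, j] = cv
                h[t, b, j] = o_ * np.tanh(cv)
                gates[t, b, j] = i_
                gates[t, b, H + j] = f_
                gates[t, b, 2 * H + j] = g_
                gates[t, b, 3 * H + j] = o_
        hprev = h[t]
        cprev = c[t]
    return h, c, gates


@njit(cache=True, fastmath=True)
def _lstm_backward(dh_out, h, c, gates, Wh, H):
    """Backprop through time.  Returns dxp (grad of the input projections)
    and dWh; dWx/db follow from dxp outside the kernel."""
    T, B, _ = dh_out.shape
    dxp = np.zeros((T, B, 4 * H), dtype=dh_out.dtype)
    dWh = np.zeros_like(Wh)
    dh_rec = np.zeros((B, H), dtype=dh_out.dtype)
    dc_rec = np.zeros((B, H), dtype=dh_out.dtype)
    dG = np.zeros((B, 4 * H), dtype=dh_out.dtype)
    WhT = Wh.T.copy()
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                i_ = gates[t, b, j]
                f_ = gates[t, b, H + j]
                g_ = gates[t, b, 2 * H + j]
                o_ = gates[t, b, 3 * H + j]
                cprev = c[t - 1, b, j] if t > 0 else 0.0
                tc = np.tanh(c[t, b, j])
                dh = dh_out[t, b, j] + dh_rec[b, j]
                do = dh * tc
                dc = dc_rec[b, j] + dh * o_ * (1.0 - tc * tc)
                di = dc * g_
                df = dc * cprev
                dgg = dc * i_
                dc_rec[b, j] = dc * f_
                dG[b, j] = di * i_ * (1.0 - i_)
                dG[b, H + j] = df * f_ * (1.0 - f_)
                dG[b, 2 * H + j] = dgg * (1.0 - g_ * g_)
                dG[b, 3 * H + j] = do * o_ * (1.0 - o_)
        dxp[t] = dG
        if t > 0:
            dWh += np.dot(h[t - 1].T.copy(), dG)
        dh_rec = np.dot(dG, WhT)
    return dxp, dWh


# ---------------------------------------------------------------------------
# modules


class Module:
    """A layer with named parameters and matching gradient buffers."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _glorot(rng, shape, fan_in, fan_out, dtype):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class Dense(Module):
    def __init__(self, in_dim, out_dim, rng, dtype=np.float32):
        super().__init__()
        self.params = {
            "W": _glorot(rng, (in_dim, out_dim), in_dim, out_dim, dtype),
            "b": np.zeros(out_dim, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Tanh(Module):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv1d(Module):
    """Channel-first 1-D convolution with 'same' zero padding.

    x: (B, C_in, T) -> (B, C_out, T).  Weights are (C_in, k, C_out).
    """

    def __init__(self, in_ch, out_ch, kernel, rng, dtype=np.float32):
        super().__init__()
        self.kernel = kernel
        self.params = {
            "W": _glorot(rng, (in_ch, kernel, out_ch), in_ch * kernel, out_ch, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x):
        k = self.kernel
        left = k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (left, k - 1 - left)))
        self._wins = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=2)
        y = np.einsum("bfmk,fko->bom", self._wins, self.params["W"], optimize=True)
        return (y + self.params["b"][None, :, None]).astype(x.dtype)

    def backward(self, dout):
        k = self.kernel
        left = k // 2
        self.grads["W"] += np.einsum(
            "bfmk,bom->fko", self._wins, dout, optimize=True
        ).astype(self.params["W"].dtype)
        self.grads["b"] += dout.sum(axis=(0, 2))
        dyp = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        dwins = np.lib.stride_tricks.sliding_window_view(dyp, k, axis=2)
        Wf = self.params["W"][:, ::-1, :]
        dxpad = np.einsum("bomk,fko->bfm", dwins, Wf, optimize=True)
        T = dout.shape[2]
        return dxpad[:, :, left : left + T].astype(dout.dtype)


class MaxPool1d(Module):
    """Non-overlapping max pooling along time; trailing remainder is cropped."""

    def __init__(self, pool):
        super().__init__()
        self.pool = pool

    def forward(self, x):
        B, C, T = x.shape
        p = self.pool
        Tp = T // p
        self._in_T = T
        xv = x[:, :, : Tp * p].reshape(B, C, Tp, p)
        self._arg = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, dout):
        B, C, Tp = dout.shape
        p = self.pool
        dx = np.zeros((B, C, self._in_T), dtype=dout.dtype)
        b, c, m = np.meshgrid(
            np.arange(B), np.arange(C), np.arange(Tp), indexing="ij"
        )
        dx[b, c, m * p + self._arg] = dout
        return dx


class BiLSTM(Module):
    """One bidirectional LSTM layer, time-major (T, B, F) -> (T, B, 2H)."""

    def __init__(self, in_dim, hidden, rng, dtype=np.float32):
        super().__init__()
        self.H = hidden
        p = {}
        for d in ("f", "b"):
            p[f"Wx_{d}"] = _glorot(rng, (in_dim, 4 * hidden), in_dim, hidden, dtype)
            p[f"Wh_{d}"] = _glorot(rng, (hidden, 4 * hidden), hidden, hidden, dtype)
            bias = np.zeros(4 * hidden, dtype=dtype)
            bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
            p[f"b_{d}"] = bias
        self.params = p
        self.zero_grad()

    def _run(self, x, d):
        T, B, F = x.shape
        xp = (x.reshape(T * B, F) @ self.params[f"Wx_{d}"]).reshape(T, B, 4 * self.H)
        xp += self.params[f"b_{d}"]
        h, c, gates = _lstm_forward(
            np.ascontiguousarray(xp), self.params[f"Wh_{d}"], self.H
        )
        return xp, h, c, gates

    def forward(self, x):
        self._x = x
        self._fwd = self._run(x, "f")
        self._bwd = self._run(x[::-1], "b")
        return np.concatenate([self._fwd[1], self._bwd[1][::-1]], axis=2)

    def _back_dir(self, dh, x, stash, d):
        _, h, c, gates = stash
        dxp, dWh = _lstm_backward(
            np.ascontiguousarray(dh), h, c, gates, self.params[f"Wh_{d}"], self.H
        )
        T, B, F = x.shape
        dxp2 = dxp.reshape(T * B, 4 * self.H)
        self.grads[f"Wx_{d}"] += x.reshape(T * B, F).T @ dxp2
        self.grads[f"Wh_{d}"] += dWh
        self.grads[f"b_{d}"] += dxp2.sum(axis=0)
        return (dxp2 @ self.params[f"Wx_{d}"].T).reshape(T, B, F)

    def backward(self, dout):
        H = self.H
        dx_f = self._back_dir(dout[:, :, :H], self._x, self._fwd, "f")
        dx_b = self._back_dir(
            np.ascontiguousarray(dout[::-1, :, H:]), self._x[::-1], self._bwd, "b"
        )
        return dx_f + dx_b[::-1]


class Sequential(Module):
    def __init__(self, modules: List[Module]):
        super().__init__()
        self.modules = modules

    def forward(self, x):
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout

    def zero_grad(self):
        for m in self.modules:
            m.zero_grad()

    def param_items(self) -> Iterable[Tuple[Module, str]]:
        for m in self.modules:
            for k in m.params:
                yield m, k

    def n_params(self) -> int:
        return sum(p.size for m in self.modules for p in m.params.values())

    def state(self) -> List[np.ndarray]:
        return [m.params[k].copy() for m, k in self.param_items()]

    def load_state(self, state: List[np.ndarray]) -> None:
        for (m, k), arr in zip(self.param_items(), state):
            m.params[k] = arr.copy()


# ---------------------------------------------------------------------------
# losses


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over all leading axes; logits (..., C), labels (...).

    Returns (loss, dlogits)."""
    p = softmax(logits)
    n = labels.size
    flat = p.reshape(n, p.shape[-1])
    idx = labels.reshape(n)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(flat[np.arange(n), idx] + eps).mean())
    d = flat.copy()
    d[np.arange(n), idx] -= 1.0
    return loss, (d / n).reshape(logits.shape)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target.astype(pred.dtype)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with bias correction; operates in-place on a Sequential's params."""

    def __init__(self, model: Sequential, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(m.params[k]) for m, k in model.param_items()]
        self._v = [np.zeros_like(m.params[k]) for m, k in model.param_items()]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (mod, key), m, v in zip(self.model.param_items(), self._m, self._v):
            g = mod.grads[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mod.params[key] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
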