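"""Minimal neural-network layers with hand-written gradients.

The sequence tagger needs only four building blocks — embeddings, a
masked batched LSTM, a dense projection, and inverted dropout — so they
are implemented directly on numpy arrays.  Every layer exposes
``forward`` returning ``(output, cache)`` and ``backward`` consuming the
upstream gradient plus the cache and accumulating into ``Param.grad``.
Gradient correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad", "m", "v")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip: float = 5.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip = clip
        self.t = 0

    def step(self) -> None:
        self.t += 1
        norm = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in self.params))
        scale = self.clip / norm if self.clip and norm > self.clip else 1.0
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p in self.params:
            g = p.grad * scale
            p.m = self.beta1 * p.m + (1 - self.beta1) * g
            p.v = self.beta2 * p.v + (1 - self.beta2) * g * g
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def glorot(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Embedding:
    """Lookup table; gradient is scatter-added over the batch."""

    def __init__(self, name: str, n: int, dim: int, rng: np.random.Generator):
        self.table = Param(name, rng.normal(0.0, 0.1, size=(n, dim)))

    @property
    def params(self) -> List[Param]:
        return [self.table]

    def forward(self, ids: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return self.table.value[ids], ids

    def backward(self, d_out: np.ndarray, ids: np.ndarray) -> None:
        np.add.at(self.table.grad, ids.ravel(),
                  d_out.reshape(-1, d_out.shape[-1]))


class Linear:
    def __init__(self, name: str, d_in: int, d_out: int,
                 rng: np.random.Generator):
        self.W = Param(f"{name}.W", glorot(rng, (d_in, d_out)))
        self.b = Param(f"{name}.b", np.zeros(d_out))

    @property
    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return x @ self.W.value + self.b.value, x

    def backward(self, d_out: np.ndarray, x: np.ndarray) -> np.ndarray:
        flat_x = x.reshape(-1, x.shape[-1])
        flat_d = d_out.reshape(-1, d_out.shape[-1])
        self.W.grad += flat_x.T @ flat_d
        self.b.grad += flat_d.sum(axis=0)
        return d_out @ self.W.value.T


class LSTM:
    """Single-direction LSTM over padded batches ``(B, T, D)``.

    ``mask`` is a contiguous-prefix boolean matrix ``(B, T)``; at padded
    positions the hidden and cell states carry forward unchanged, so the
    final row of the returned states is each sequence's last real state.
    Gate order is input, forget, cell, output; the forget gate bias starts
    at 1 to ease gradient flow early in training.
    """

    def __init__(self, name: str, d_in: int, hidden: int,
                 rng: np.random.Generator):
        self.d_in, self.hidden = d_in, hidden
        self.W = Param(f"{name}.W", glorot(rng, (d_in, 4 * hidden)))
        self.U = Param(f"{name}.U", glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Param(f"{name}.b", b)

    @property
    def params(self) -> List[Param]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray
                ) -> Tuple[np.ndarray, dict]:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = {"x": x, "mask": mask, "steps": []}
        for t in range(T):
            m = mask[:, t].astype(float)[:, None]
            a = x[:, t, :] @ self.W.value + h @ self.U.value + self.b.value
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache["steps"].append((h, c, i, f, g, o, c_new, tc, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            hs[:, t, :] = h
        return hs, cache

    def backward(self, d_hs: np.ndarray, cache: dict) -> np.ndarray:
        x, mask = cache["x"], cache["mask"]
        B, T, _ = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc, m = cache["steps"][t]
            dh = dh + d_hs[:, t, :]
            dh_new = dh * m
            dh_carry = dh * (1 - m)
            dc_new = dc * m
            dc_carry = dc * (1 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc ** 2)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dc_prev = dc_new * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2),
                 do * o * (1 - o)], axis=1)
            self.W.grad += x[:, t, :].T @ da
            self.U.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t, :] = da @ self.W.value.T
            dh = da @ self.U.value.T + dh_carry
            dc = dc_prev + dc_carry
        return dx


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence's valid prefix, keeping padding at the end."""
    out = np.zeros_like(x)
    for b, n in enumerate(lengths):
        n = int(n)
        out[b, :n] = x[b, :n][::-1]
        out[b, n:] = x[b, n:]
    return out


class BiLSTM:
    """Concatenation of a forward and a reversed-input LSTM pass."""

    def __init__(self, name: str, d_in: int, hidden: int,
                 rng: np.random.Generator):
        self.fwd = LSTM(f"{name}.fwd", d_in, hidden, rng)
        self.bwd = LSTM(f"{name}.bwd", d_in, hidden, rng)
        self.hidden = hidden

    @property
    def params(self) -> List[Param]:
        return self.fwd.params + self.bwd.params

    def forward(self, x: np.ndarray, mask: np.ndarray
                ) -> Tuple[np.ndarray, dict]:
        lengths = mask.sum(axis=1)
        xr = reverse_padded(x, lengths)
        hf, cf = self.fwd.forward(x, mask)
        hbr, cb = self.bwd.forward(xr, mask)
        hb = reverse_padded(hbr, lengths)
        out = np.concatenate([hf, hb], axis=2)
        return out, {"cf": cf, "cb": cb, "lengths": lengths}

    def backward(self, d_out: np.ndarray, cache: dict) -> np.ndarray:
        H = self.hidden
        lengths = cache["lengths"]
        d_hf = d_out[:, :, :H]
        d_hb = reverse_padded(d_out[:, :, H:], lengths)
        dx_f = self.fwd.backward(d_hf, cache["cf"])
        dx_b = reverse_padded(self.bwd.backward(d_hb, cache["cb"]), lengths)
        return dx_f + dx_b


class Dropout:
    """Inverted dropout driven by an explicit RNG; identity when eval."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, rng: Optional[np.random.Generator],
                train: bool) -> Tuple[np.ndarray, Optional[np.ndarray]]:
        if not train or self.rate <= 0.0:
            return x, None
        keep = 1.0 - self.rate
        m = (rng.random(x.shape) < keep).astype(float) / keep
        return x * m, m

    def backward(self, d_out: np.ndarray,
                 m: Optional[np.ndarray]) -> np.ndarray:
        return d_out if m is None else d_out * m
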