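"""Minimal CNN building blocks over (batch, channel, RT, m/z) tensors.

Implemented directly on numpy with hand-written backward passes; convolution
is lowered to a GEMM via an im2col restricted to the RT axis (and the m/z
axis only in 2D-filter mode).  The 1D-filter adaptation central to this
package means kernels of extent 1 along m/z and pooling that never merges
adjacent m/z channels, so no parameter ever mixes neighbouring ion channels.

All math in float32.  Layers cache what their backward pass needs when
``train=True`` and release it on ``zero_cache``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = val.astype(np.float32)
        self.grad = np.zeros_like(self.val)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def zero_cache(self) -> None:
        pass


class Conv(Layer):
    """Same-padded convolution with kernel (kt x km); km=1 is the 1D-filter mode."""

    def __init__(self, c_in: int, c_out: int, kt: int = 3, km: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kt * km
        self.kt, self.km, self.c_in, self.c_out = kt, km, c_in, c_out
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, kt * km * c_in)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols = None
        self._xshape = None

    @property
    def kernel_shape(self) -> tuple[int, int]:
        return (self.kt, self.km)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, T, M = x.shape
        pt, pm = self.kt // 2, self.km // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (pm, pm)))
        cols = np.empty((B, self.kt * self.km * C, T, M), dtype=x.dtype)
        q = 0
        for dt in range(self.kt):
            for dm in range(self.km):
                cols[:, q * C:(q + 1) * C] = xp[:, :, dt:dt + T, dm:dm + M]
                q += 1
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = self._im2col(x)
        if train:
            self._cols, self._xshape = cols, x.shape
        out = np.tensordot(self.W.val, cols, axes=(1, 1))      # (c_out, B, T, M)
        out = out.transpose(1, 0, 2, 3)
        out += self.b.val[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T, M = self._xshape
        pt, pm = self.kt // 2, self.km // 2
        self.W.grad += np.tensordot(dout, self._cols, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dcols = np.tensordot(self.W.val, dout, axes=(0, 1))    # (ktkmC, B, T, M)
        dxp = np.zeros((B, C, T + 2 * pt, M + 2 * pm), dtype=dout.dtype)
        q = 0
        for dt in range(self.kt):
            for dm in range(self.km):
                dxp[:, :, dt:dt + T, dm:dm + M] += \
                    dcols[q * C:(q + 1) * C].transpose(1, 0, 2, 3)
                q += 1
        return dxp[:, :, pt:pt + T, pm:pm + M]

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def zero_cache(self) -> None:
        self._cols = None


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def zero_cache(self) -> None:
        self._mask = None


class MaxPool(Layer):
    """Max pooling (pt x pm); pm=1 never merges m/z channels.  Trailing rows
    that do not fill a pool cell are cropped."""

    def __init__(self, pt: int = 2, pm: int = 1):
        self.pt, self.pm = pt, pm

    @property
    def pool_shape(self) -> tuple[int, int]:
        return (self.pt, self.pm)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, T, M = x.shape
        T2, M2 = T - T % self.pt, M - M % self.pm
        xc = x[:, :, :T2, :M2]
        r = xc.reshape(B, C, T2 // self.pt, self.pt, M2 // self.pm, self.pm)
        r = r.transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, T2 // self.pt, M2 // self.pm, self.pt * self.pm)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T, M = self._xshape
        T2, M2 = T - T % self.pt, M - M % self.pm
        r = np.zeros((B, C, T2 // self.pt, M2 // self.pm, self.pt * self.pm),
                     dtype=dout.dtype)
        np.put_along_axis(r, self._idx[..., None], dout[..., None], axis=-1)
        r = r.reshape(B, C, T2 // self.pt, M2 // self.pm, self.pt, self.pm)
        r = r.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, T2, M2)
        dx = np.zeros((B, C, T, M), dtype=dout.dtype)
        dx[:, :, :T2, :M2] = r
        return dx

    def zero_cache(self) -> None:
        self._idx = None


class GlobalAvgPool(Layer):
    """Mean over the RT and m/z extents: (B, C, T, M) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T, M = self._xshape
        return np.broadcast_to(dout[:, :, None, None] / (T * M),
                               (B, C, T, M)).astype(dout.dtype)


class AvgPoolRTFlatten(Layer):
    """Mean over the RT extent, then flatten: (B, C, T, M) -> (B, C * M).

    The m/z axis is kept: with 1D filters the network never mixes ion
    channels, so averaging across m/z as well would erase exactly the
    information that distinguishes compounds.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._xshape = x.shape
        B, C, T, M = x.shape
        return x.mean(axis=2).reshape(B, C * M)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T, M = self._xshape
        d = dout.reshape(B, C, 1, M) / T
        return np.broadcast_to(d, (B, C, T, M)).astype(dout.dtype)


class Dense(Layer):
    """Fully-connected layer; ``n_in=None`` defers weight init to the first
    forward pass (the flattened feature size depends on the input window)."""

    def __init__(self, n_in: int | None, n_out: int,
                 rng: np.random.Generator | None = None):
        self._rng = rng or np.random.default_rng(0)
        self.n_out = n_out
        self.W: Param | None = None
        self.b: Param | None = None
        if n_in is not None:
            self.materialise(n_in)

    def materialise(self, n_in: int) -> None:
        self.W = Param(self._rng.normal(0.0, np.sqrt(2.0 / n_in),
                                        size=(n_in, self.n_out)).astype(np.float32))
        self.b = Param(np.zeros(self.n_out, dtype=np.float32))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.W is None:
            self.materialise(x.shape[1])
        if train:
            self._x = x
        return x @ self.W.val + self.b.val

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.val.T

    def params(self) -> list[Param]:
        return [] if self.W is None else [self.W, self.b]

    def zero_cache(self) -> None:
        self._x = None


class ResidualBlock(Layer):
    """conv-relu-conv plus identity (or 1x1-conv projection) skip, final ReLU."""

    def __init__(self, c_in: int, c_out: int, km: int = 1,
                 rng: np.random.Generator | None = None):
        kt = 3
        self.conv1 = Conv(c_in, c_out, kt, km, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv(c_out, c_out, kt, km, rng)
        self.proj = Conv(c_in, c_out, 1, 1, rng) if c_in != c_out else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train),
                               train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        y = h + s
        out = np.maximum(y, 0.0)
        if train:
            self._mask = y > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout * self._mask
        dh = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        ds = self.proj.backward(d) if self.proj is not None else d
        return dh + ds

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def zero_cache(self) -> None:
        for sub in (self.conv1, self.relu1, self.conv2, self.proj):
            if sub is not None:
                sub.zero_cache()
        self._mask = None

    def sublayers(self):
        return [l for l in (self.conv1, self.conv2, self.proj) if l is not None]


class DenseLayer(Layer):
    """One densely-connected step: concat(x, relu(conv(x))) along channels."""

    def __init__(self, c_in: int, growth: int, km: int = 1,
                 rng: np.random.Generator | None = None):
        self.c_in = c_in
        self.conv = Conv(c_in, growth, 3, km, rng)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.relu.forward(self.conv.forward(x, train), train)
        return np.concatenate([x, f], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx, df = dout[:, :self.c_in], dout[:, self.c_in:]
        return dx + self.conv.backward(self.relu.backward(df))

    def params(self) -> list[Param]:
        return self.conv.params()

    def zero_cache(self) -> None:
        self.conv.zero_cache()
        self.relu.zero_cache()

    def sublayers(self):
        return [self.conv]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and d(loss)/d(logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment optimiser over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.val -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
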