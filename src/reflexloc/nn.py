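"""Minimal NumPy layers for spatiotemporal (3-D) convolutional networks.

Tensors are ``(N, C, T, H, W)`` float32.  Convolutions iterate over kernel
offsets (at most ``kt*kh*kw`` slim ``einsum`` calls) instead of building an
im2col matrix, which keeps memory flat for the 20-frame windows this package
trains on.  Everything is deterministic given the ``numpy.random.Generator``
used for initialization and batching.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv3D",
    "ReLU",
    "AvgPool3D",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "ConcatBranches",
    "Adam",
    "softmax",
    "cross_entropy",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64), axis=1)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Layer:
    """Forward/backward unit with named parameters and matching gradients."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def iter_layers(self) -> Iterable["Layer"]:
        yield self


def _triple(k: int | tuple[int, int, int]) -> tuple[int, int, int]:
    return (k, k, k) if isinstance(k, int) else tuple(k)  # type: ignore[return-value]


class Conv3D(Layer):
    """3-D convolution with 'same' padding and unit stride.

    Kernel sizes must be odd so that the output keeps the input's T, H, W.
    Weights use He-normal initialization from the supplied generator.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int | tuple[int, int, int],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.kernel = _triple(kernel)
        if any(k < 1 or k % 2 == 0 for k in self.kernel):
            raise ValueError(f"kernel sizes must be odd and positive: {self.kernel}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * int(np.prod(self.kernel))
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in),
            size=(out_channels, in_channels, *self.kernel),
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._xp: np.ndarray | None = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        pt, ph, pw = (k // 2 for k in self.kernel)
        return np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, T, H, W); got {x.shape}"
            )
        xp = self._pad(x.astype(np.float32, copy=False))
        self._xp = xp
        N, _, T, H, W = x.shape
        kt, kh, kw = self.kernel
        Wk = self.params["W"]
        out = np.zeros((N, self.out_channels, T, H, W), dtype=np.float32)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    xs = xp[:, :, it:it + T, ih:ih + H, iw:iw + W]
                    out += np.einsum(
                        "ncthw,oc->nothw", xs, Wk[:, :, it, ih, iw],
                        optimize=True,
                    )
        out += self.params["b"][None, :, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward called before forward"
        N, _, Tp, Hp, Wp = xp.shape
        kt, kh, kw = self.kernel
        T, H, W = dy.shape[2:]
        Wk = self.params["W"]
        dW = np.zeros_like(Wk)
        dxp = np.zeros_like(xp)
        dy = dy.astype(np.float32, copy=False)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    xs = xp[:, :, it:it + T, ih:ih + H, iw:iw + W]
                    dW[:, :, it, ih, iw] = np.einsum(
                        "nothw,ncthw->oc", dy, xs, optimize=True
                    )
                    dxp[:, :, it:it + T, ih:ih + H, iw:iw + W] += np.einsum(
                        "nothw,oc->ncthw", dy, Wk[:, :, it, ih, iw],
                        optimize=True,
                    )
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        pt, ph, pw = (k // 2 for k in self.kernel)
        return dxp[:, :, pt:Tp - pt or None, ph:Hp - ph or None, pw:Wp - pw or None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32, copy=False)


class AvgPool3D(Layer):
    """Non-overlapping average pooling; trailing remainder frames are cropped."""

    def __init__(self, pool: int | tuple[int, int, int]) -> None:
        super().__init__()
        self.pool = _triple(pool)
        if any(p < 1 for p in self.pool):
            raise ValueError(f"pool sizes must be >= 1: {self.pool}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        pt, ph, pw = self.pool
        N, C, T, H, W = x.shape
        To, Ho, Wo = T // pt, H // ph, W // pw
        if min(To, Ho, Wo) < 1:
            raise ValueError(f"input {x.shape} smaller than pool {self.pool}")
        self._in_shape = x.shape
        xc = x[:, :, : To * pt, : Ho * ph, : Wo * pw]
        y = xc.reshape(N, C, To, pt, Ho, ph, Wo, pw).mean(axis=(3, 5, 7))
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pt, ph, pw = self.pool
        N, C, To, Ho, Wo = dy.shape
        scale = 1.0 / (pt * ph * pw)
        g = (dy * scale)[:, :, :, None, :, None, :, None]
        g = np.broadcast_to(g, (N, C, To, pt, Ho, ph, Wo, pw))
        g = g.reshape(N, C, To * pt, Ho * ph, Wo * pw)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : To * pt, : Ho * ph, : Wo * pw] = g
        return dx


class GlobalAvgPool(Layer):
    """(N, C, T, H, W) -> (N, C) mean over all spatiotemporal positions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, T, H, W = self._in_shape
        g = dy[:, :, None, None, None] / float(T * H * W)
        return np.broadcast_to(g, self._in_shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self) -> Iterable[Layer]:
        for layer in self.layers:
            yield from layer.iter_layers()


class ConcatBranches(Layer):
    """Parallel branches applied to the same input; outputs concatenated on
    the channel axis.  The building block of inception-style modules."""

    def __init__(self, branches: Sequence[Layer]) -> None:
        super().__init__()
        if not branches:
            raise ValueError("at least one branch required")
        self.branches = list(branches)

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [b.forward(x) for b in self.branches]
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        parts = np.split(dy, self._split, axis=1)
        dx = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
        return dx

    def iter_layers(self) -> Iterable[Layer]:
        for branch in self.branches:
            yield from branch.iter_layers()


class Adam:
    """Adam with bias correction; state keyed by layer order, deterministic."""

    def __init__(self, root: Layer, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.root = root
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.root.iter_layers()):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
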