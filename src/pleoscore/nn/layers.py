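"""Minimal explicit-backprop layers (NHWC, float32).

Just enough of a convnet toolkit to express a densely connected
regression network on a CPU: 'same'-padded convolutions implemented as a
sum of nine shifted matmuls, ReLU, 2x2 average pooling, global average
pooling and a linear head.  Each layer caches what its backward pass
needs; gradients are accumulated into ``grads`` aligned with ``params``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base: parameters and gradients are aligned dicts of arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding, He init."""

    def __init__(self, cin: int, cout: int, ksize: int, rng):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (ksize, ksize, cin, cout))
        self.params = {"w": w.astype(DTYPE),
                       "b": np.zeros(cout, DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        n, h, w_, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp_shape = xp.shape
        self._xp = xp
        out = np.broadcast_to(self.params["b"], (n, h, w_, self.cout)).copy()
        wgt = self.params["w"]
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + h, j:j + w_, :] @ wgt[i, j]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w_, _ = dout.shape
        xp = self._xp
        dxp = np.zeros(self._xp_shape, DTYPE)
        wgt = self.params["w"]
        dout2 = dout.reshape(-1, self.cout)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + h, j:j + w_, :].reshape(-1, self.cin)
                self.grads["w"][i, j] += patch.T @ dout2
                dxp[:, i:i + h, j:j + w_, :] += dout @ wgt[i, j].T
        self.grads["b"] += dout2.sum(axis=0)
        p = k // 2
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool2(Layer):
    """2x2 average pooling, stride 2 (even spatial dims required)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2 needs even spatial dims")
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
        return (d / 4.0).astype(DTYPE)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return (np.broadcast_to(dout[:, None, None, :], self._shape)
                / (h * w)).astype(DTYPE)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(1.0 / cin), (cin, cout))
        self.params = {"w": w.astype(DTYPE), "b": np.zeros(cout, DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["w"].T


class DenseBlock(Layer):
    """Densely connected block: each layer sees every earlier feature map.

    Layer ``l`` maps concat(x, f_1, ..., f_{l-1}) through a 3x3 conv +
    ReLU into ``growth`` new channels; the block returns the concatenation
    of its input with all produced maps.
    """

    def __init__(self, cin: int, n_layers: int, growth: int, rng):
        super().__init__()
        self.convs: list[Conv2d] = []
        self.relus: list[ReLU] = []
        c = cin
        for _ in range(n_layers):
            self.convs.append(Conv2d(c, growth, 3, rng))
            self.relus.append(ReLU())
            c += growth
        self.cout = c

    @property
    def children(self) -> list[Layer]:
        return list(self.convs)

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        self._widths = [x.shape[-1]]
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(np.concatenate(feats, axis=-1)))
            feats.append(h)
            self._widths.append(h.shape[-1])
        return np.concatenate(feats, axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        splits = np.cumsum(self._widths)[:-1]
        dfeats = list(np.split(dout, splits, axis=-1))
        for l in range(len(self.convs) - 1, -1, -1):
            d = self.relus[l].backward(dfeats[l + 1])
            dcat = self.convs[l].backward(d)
            w0 = 0
            for m in range(l + 1):
                dfeats[m] = dfeats[m] + dcat[..., w0:w0 + self._widths[m]]
                w0 += self._widths[m]
        return np.ascontiguousarray(dfeats[0])

    def zero_grad(self) -> None:
        for conv in self.convs:
            conv.zero_grad()


class Transition(Layer):
    """Channel-compressing 1x1 conv + ReLU + 2x2 average pool."""

    def __init__(self, cin: int, compression: float, rng):
        super().__init__()
        self.cout = max(1, int(np.floor(cin * compression)))
        self.conv = Conv2d(cin, self.cout, 1, rng)
        self.relu = ReLU()
        self.pool = AvgPool2()

    @property
    def children(self) -> list[Layer]:
        return [self.conv]

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.pool.forward(self.relu.forward(self.conv.forward(x)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(
            self.relu.backward(self.pool.backward(dout)))

    def zero_grad(self) -> None:
        self.conv.zero_grad()
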