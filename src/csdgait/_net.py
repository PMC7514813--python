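"""Minimal CNN engine: layers, softmax cross-entropy, SGD with momentum.

Self-contained float32 implementation sized for small binary-image
classifiers (a few conv layers on ~48x32 inputs).  Convolutions use
same-padding and are evaluated as matrix products against an im2col
expansion, so the heavy lifting runs in BLAS.  Everything is pure numpy
and deterministic for a fixed `numpy.random.Generator`.

Tensor layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2DSame",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
    "SGDMomentum",
    "Sequential",
]


from ._kernels import col2im_t, im2col, maxpool_backward, maxpool_forward


class Conv2DSame:
    """Odd-kernel convolution with same padding, stride 1.

    Weight rows follow the row-major reshape of an (out_ch, in_ch, k, k)
    tensor.  Set ``need_input_grad = False`` on the first layer to skip
    the (useless) input-gradient fold.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, need_input_grad: bool = True):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.need_input_grad = need_input_grad
        self.W = np.zeros((out_ch, in_ch * k * k), dtype=np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init_params(self, rng: np.random.Generator, std, bias: float) -> None:
        if std == "he":  # fan-in scaled: unit forward gain under ReLU
            std = float(np.sqrt(2.0 / self.W.shape[1]))
        self.W[:] = rng.normal(0.0, std, self.W.shape).astype(np.float32)
        self.b[:] = bias

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        x_pad = np.pad(np.ascontiguousarray(x, dtype=np.float32),
                       ((0, 0), (0, 0), (p, p), (p, p)))
        self._cols = im2col(x_pad, self.k, h, w)  # (N, C*k*k, H*W)
        self._in_shape = x.shape
        out = np.matmul(self.W, self._cols)  # (N, out_ch, H*W)
        out += self.b[None, :, None]
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        g = np.ascontiguousarray(dout.reshape(n, self.out_ch, h * w))
        self.db = g.sum(axis=(0, 2))
        # accumulate dW over the batch: (out_ch, C*k*k)
        self.dW = np.matmul(g, self._cols.transpose(0, 2, 1)).sum(axis=0)
        if not self.need_input_grad:
            self._cols = None
            return None
        # one large GEMM beats a batched one here: fold from (C*k*k, N*H*W)
        g_t = np.ascontiguousarray(g.transpose(1, 0, 2).reshape(self.out_ch, -1))
        dcols_t = (self.W.T @ g_t).reshape(-1, n, h * w)
        self._cols = None
        return col2im_t(dcols_t, n, c, h, w, self.k)


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0.0))


class MaxPool2x2:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped.

    Ties route the gradient to the first maximal element of the window
    (row-major order), so the winner is always unique.
    """

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        out, self._arg = maxpool_forward(np.ascontiguousarray(x, dtype=np.float32))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        _, _, h, w = self._in_shape
        return maxpool_backward(
            np.ascontiguousarray(dout, dtype=np.float32), self._arg, h, w
        )


class Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, in_dim: int, out_dim: int):
        self.W = np.zeros((in_dim, out_dim), dtype=np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init_params(self, rng: np.random.Generator, std, bias: float) -> None:
        if std == "he":
            std = float(np.sqrt(2.0 / self.W.shape[0]))
        self.W[:] = rng.normal(0.0, std, self.W.shape).astype(np.float32)
        self.b[:] = bias

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    g = p
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(np.float32)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def param_count(self) -> int:
        return sum(int(w.size) for w, _ in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for (w, _), new in zip(own, weights):
            if w.shape != new.shape:
                raise ValueError(f"weight shape mismatch: {w.shape} vs {new.shape}")
            w[:] = new


class SGDMomentum:
    """v <- mu*v - lr*(grad + wd*w);  w <- w + v  (classical momentum).

    Gradients are re-read from the network each step, since layers may
    rebind their gradient arrays during backward.
    """

    def __init__(self, net: "Sequential", lr: float, momentum: float, weight_decay: float):
        self.net = net
        self.lr = np.float32(lr)
        self.mu = np.float32(momentum)
        self.wd = np.float32(weight_decay)
        self.velocity = [np.zeros_like(w) for w, _ in net.params]

    def step(self) -> None:
        from ._kernels import sgd_update

        for (w, g), v in zip(self.net.params, self.velocity):
            sgd_update(
                w.ravel(),
                np.ascontiguousarray(g, dtype=np.float32).ravel(),
                v.ravel(),
                self.lr,
                self.mu,
                self.wd,
            )
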