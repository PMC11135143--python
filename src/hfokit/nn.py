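"""Minimal CNN engine on numpy: im2col convolutions, Adam, MAC accounting.

Supports exactly the layer vocabulary the event classifiers need — 3x3
same-padding convolutions, ReLU, non-overlapping max pooling, flatten and
dense layers with a softmax cross-entropy head — each with an analytic
multiply-accumulate (MAC) count, plus structured channel removal with
dependency propagation for pruning.  float32 throughout; all randomness via
an injected generator.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: forward/backward plus parameter and MAC introspection."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape

    def macs(self, in_shape: tuple) -> int:
        return 0


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((b, c * self.k * self.k, h * w), dtype=np.float32)
        i = 0
        for ci in range(c):
            for di in range(self.k):
                for dj in range(self.k):
                    cols[:, i, :] = xp[:, ci, di:di + h, dj:dj + w].reshape(b, -1)
                    i += 1
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        b, _, h, w = x.shape
        wm = self.w.reshape(self.out_ch, -1)
        out = np.matmul(wm[None, :, :], self._cols) + self.b[None, :, None]
        return out.reshape(b, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h, w = self._in_shape
        dm = dout.reshape(dout.shape[0], self.out_ch, -1)
        self.grads[0][...] = (
            np.matmul(dm, self._cols.transpose(0, 2, 1)).sum(axis=0)
        ).reshape(self.w.shape)
        self.grads[1][...] = dm.sum(axis=(0, 2))
        wm = self.w.reshape(self.out_ch, -1)
        dcols = np.matmul(wm.T[None, :, :], dm)  # (b, c*k*k, h*w)
        p = self.k // 2
        dxp = np.zeros((b, self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        i = 0
        for ci in range(self.in_ch):
            for di in range(self.k):
                for dj in range(self.k):
                    dxp[:, ci, di:di + h, dj:dj + w] += dcols[:, i, :].reshape(b, h, w)
                    i += 1
        return dxp[:, :, p:p + h, p:p + w]

    def out_shape(self, in_shape: tuple) -> tuple:
        _, h, w = in_shape
        return (self.out_ch, h, w)

    def macs(self, in_shape: tuple) -> int:
        c, h, w = in_shape
        return self.out_ch * h * w * (self.k * self.k * c)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool(Layer):
    """Non-overlapping square max pooling; input sides must divide evenly."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.s = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        s = self.s
        if h % s or w % s:
            raise ValueError(f"input side not divisible by pool size {s}")
        self._in_shape = x.shape
        xr = x.reshape(b, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // s, w // s, s * s)
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        s = self.s
        dxr = np.zeros((b, c, h // s, w // s, s * s), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(b, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(b, c, h, w)

    def out_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        return (c, h // self.s, w // self.s)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)

    def out_shape(self, in_shape: tuple) -> tuple:
        n = 1
        for d in in_shape:
            n *= d
        return (n,)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T

    def out_shape(self, in_shape: tuple) -> tuple:
        return (self.w.shape[1],)

    def macs(self, in_shape: tuple) -> int:
        return int(self.w.shape[0] * self.w.shape[1])


class Network:
    """A sequential stack with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer], input_shape: tuple) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Class probabilities, computed in fixed-size batches."""
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            chunks.append(_softmax(logits))
        return np.concatenate(chunks, axis=0)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch; fills every layer's gradients."""
        logits = self.forward(x, train=True)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 128) -> float:
        probs = self.predict_proba(x, batch_size=batch_size)
        return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = state[f"p{i}"]
            if src.shape != p.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{src.shape} vs {p.shape}")
            p[...] = src

    def shapes_through(self) -> list[tuple]:
        """Activation shape (without batch) entering each layer."""
        shapes = [self.input_shape]
        for layer in self.layers:
            shapes.append(layer.out_shape(shapes[-1]))
        return shapes[:-1]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def count_macs(net: Network, input_shape: tuple | None = None) -> int:
    """Analytic multiply-accumulate count for one forward pass of one sample.

    Convolutions contribute output-element count x kernel fan-in; dense
    layers contribute their weight-matrix size; activations and pooling are
    MAC-free.
    """
    shape = tuple(input_shape) if input_shape is not None else self_shape(net)
    total = 0
    for layer in net.layers:
        total += layer.macs(shape)
        shape = layer.out_shape(shape)
    return total


def self_shape(net: Network) -> tuple:
    return net.input_shape


class Adam:
    """Adam optimizer over a network's parameter list."""

    def __init__(self, net: Network, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.parameters()]
        self.v = [np.zeros_like(p) for p in net.parameters()]

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.net.parameters(), self.net.gradients(),
                              self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# structured pruning


def _conv_indices(net: Network) -> list[int]:
    return [i for i, l in enumerate(net.layers) if isinstance(l, Conv2d)]


def _next_param_layer(net: Network, after: int) -> int | None:
    for j in range(after + 1, len(net.layers)):
        if isinstance(net.layers[j], (Conv2d, Dense)):
            return j
    return None


def prune_channel(net: Network, conv_idx: int, channel: int) -> None:
    """Remove one output channel of a convolution and propagate the removal.

    The consumer of the channel — the next convolution's input slice, or the
    dense layer rows that flattening maps to that channel — shrinks with it,
    so the network stays consistent (DepGraph-style dependency handling for
    a sequential stack).
    """
    conv = net.layers[conv_idx]
    if not isinstance(conv, Conv2d):
        raise TypeError("conv_idx must point at a convolution")
    if conv.out_ch <= 1:
        raise ValueError("cannot prune the last remaining channel")
    keep = [c for c in range(conv.out_ch) if c != channel]
    conv.w = conv.w[keep]
    conv.b = conv.b[keep]
    conv.out_ch -= 1
    conv.params = [conv.w, conv.b]
    conv.grads = [np.zeros_like(conv.w), np.zeros_like(conv.b)]

    nxt_idx = _next_param_layer(net, conv_idx)
    if nxt_idx is None:
        raise ValueError("output-layer channels cannot be pruned")
    nxt = net.layers[nxt_idx]
    if isinstance(nxt, Conv2d):
        nxt.w = nxt.w[:, keep]
        nxt.in_ch -= 1
        nxt.params = [nxt.w, nxt.b]
        nxt.grads = [np.zeros_like(nxt.w), np.zeros_like(nxt.b)]
    else:  # Dense after Flatten: drop the channel-major block of rows
        c_before = conv.out_ch + 1
        hw = nxt.w.shape[0] // c_before
        rows = np.ones(nxt.w.shape[0], dtype=bool)
        rows[channel * hw:(channel + 1) * hw] = False
        nxt.w = nxt.w[rows]
        nxt.params = [nxt.w, nxt.b]
        nxt.grads = [np.zeros_like(nxt.w), np.zeros_like(nxt.b)]


def smallest_channel(net: Network, min_channels: int = 1) -> tuple[int, int]:
    """(layer index, channel) of the smallest-L2-norm prunable conv filter."""
    best: tuple[float, int, int] | None = None
    for i in _conv_indices(net):
        conv = net.layers[i]
        if conv.out_ch <= min_channels or _next_param_layer(net, i) is None:
            continue
        norms = np.sqrt((conv.w.reshape(conv.out_ch, -1) ** 2).sum(axis=1))
        c = int(norms.argmin())
        if best is None or norms[c] < best[0]:
            best = (float(norms[c]), i, c)
    if best is None:
        raise ValueError("no prunable channel left above the minimum width")
    return best[1], best[2]
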