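"""A small convolutional network with explicit forward/backward passes.

Desk-scale object classifier trained from scratch: conv/ReLU/max-pool
stages, global average pooling and a linear head.  The backward pass is
written out layer by layer, which buys two things a black-box fit cannot:
gradients with respect to any intermediate feature map (for class
activation mapping) and a guided mode in which every rectifier's backward
pass zeroes both negative upstream gradients and positions with negative
forward activations (guided backpropagation).

All gradient paths are validated against finite differences in the test
suite.  Arrays are ``(batch, channels, rows, cols)`` float64 throughout;
runs are deterministic for a fixed seed on one device.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2x2", "GlobalAvgPool", "Dense",
           "SmallCNN", "softmax"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return cols, (n, c, hp, wp, oh, ow)


def _col2im(dcols: np.ndarray, meta, kh: int, kw: int, stride: int, pad: int):
    n, c, hp, wp, oh, ow = meta
    dx = np.zeros((n, c, hp, wp))
    dwin = dcols.reshape(n, oh, ow, c, kh, kw)
    for di in range(kh):
        for dj in range(kw):
            dx[:, :, di:di + oh * stride:stride, dj:dj + ow * stride:stride] += \
                dwin[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2D:
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, pad: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.W = rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_ch)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = ("W", "b")

    def forward(self, x):
        cols, meta = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._cache = (cols, meta)
        n, _, _, _, oh, ow = meta
        out = cols @ self.W.T + self.b
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout, guided=False):
        cols, meta = self._cache
        n, _, _, _, oh, ow = meta
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, -1)
        self.dW = dflat.T @ cols
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W
        return _col2im(dcols, meta, self.kernel, self.kernel,
                       self.stride, self.pad)


class ReLU:
    params = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout, guided=False):
        grad = dout * self._mask
        if guided:
            grad = grad * (dout > 0)
        return grad


class MaxPool2x2:
    params = ()

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 needs even spatial dims")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = win.argmax(axis=-1)
        self._shape = x.shape
        return win.max(axis=-1)

    def backward(self, dout, guided=False):
        n, c, h, w = self._shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], -1)
        dwin = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dwin.reshape(n, c, h, w)


class GlobalAvgPool:
    params = ()

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout, guided=False):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               (n, c, h, w)).copy()


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.standard_normal((out_dim, in_dim)) * np.sqrt(2.0 / in_dim)
        self.b = np.zeros(out_dim)
        self.params = ("W", "b")

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout, guided=False):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Conv stages + global average pooling + linear head.

    ``stage_names`` label the ReLU output of each conv stage; those
    activations (and their gradients) are retrievable for attention maps.
    """

    def __init__(self, in_channels: int = 3, n_classes: int = 7,
                 channels: tuple[int, ...] = (16, 32, 32), seed: int = 0,
                 pool_after: tuple[bool, ...] | None = None):
        rng = np.random.default_rng(seed)
        self.layers: list = []
        self.stage_of_layer: dict[str, int] = {}
        prev = in_channels
        pool_after = pool_after or tuple(True for _ in channels)
        for i, (ch, do_pool) in enumerate(zip(channels, pool_after)):
            self.layers.append(Conv2D(prev, ch, rng=rng))
            self.layers.append(ReLU())
            self.stage_of_layer[f"conv{i + 1}"] = len(self.layers) - 1
            if do_pool:
                self.layers.append(MaxPool2x2())
            prev = ch
        self.layers.append(GlobalAvgPool())
        self.head = Dense(prev, n_classes, rng=rng)
        self.n_classes = n_classes
        self.last_stage = f"conv{len(channels)}"

    # -- plumbing -----------------------------------------------------------
    def forward(self, x: np.ndarray,
                record: tuple[str, ...] = ()) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        self._acts: dict[str, np.ndarray] = {}
        for idx, layer in enumerate(self.layers):
            x = layer.forward(x)
            for name, lidx in self.stage_of_layer.items():
                if lidx == idx and name in record:
                    self._acts[name] = x
        return self.head.forward(x)

    def activation(self, name: str) -> np.ndarray:
        return self._acts[name]

    def backward(self, dlogits: np.ndarray, guided: bool = False,
                 capture: tuple[str, ...] = ()) -> np.ndarray:
        """Backpropagate from the logits; returns the input gradient."""
        grad = self.head.backward(dlogits, guided=guided)
        self._grads: dict[str, np.ndarray] = {}
        capture_at = {self.stage_of_layer[name]: name for name in capture}
        for idx in range(len(self.layers) - 1, -1, -1):
            if idx in capture_at:
                self._grads[capture_at[idx]] = grad
            grad = self.layers[idx].backward(grad, guided=guided)
        return grad

    def gradient(self, name: str) -> np.ndarray:
        return self._grads[name]

    def class_score_grad(self, x: np.ndarray, target_class: int,
                         guided: bool = False,
                         capture: tuple[str, ...] = ()) -> np.ndarray:
        """Input gradient of the raw target-class logit."""
        logits = self.forward(x, record=capture)
        onehot = np.zeros_like(logits)
        onehot[:, target_class] = 1.0
        return self.backward(onehot, guided=guided, capture=capture)

    # -- training -----------------------------------------------------------
    def _trainables(self):
        for layer in [*self.layers, self.head]:
            for p in layer.params:
                yield layer, p

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 30,
            lr: float = 1e-3, batch_size: int = 32, seed: int = 0,
            verbose: bool = False) -> list[float]:
        """Adam training on softmax cross-entropy; returns per-epoch losses."""
        rng = np.random.default_rng(seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        m_state: dict[tuple[int, str], np.ndarray] = {}
        v_state: dict[tuple[int, str], np.ndarray] = {}
        step = 0
        losses = []
        for epoch in range(epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), batch_size):
                idx = order[start:start + batch_size]
                logits = self.forward(X[idx])
                probs = softmax(logits)
                eps = 1e-12
                epoch_loss += float(
                    -np.log(probs[np.arange(len(idx)), y[idx]] + eps).sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                self.backward(dlogits)
                step += 1
                for li, (layer, p) in enumerate(self._trainables()):
                    g = getattr(layer, "d" + p)
                    key = (li, p)
                    m = m_state.setdefault(key, np.zeros_like(g))
                    v = v_state.setdefault(key, np.zeros_like(g))
                    m *= 0.9; m += 0.1 * g
                    v *= 0.999; v += 0.001 * g * g
                    mhat = m / (1 - 0.9 ** step)
                    vhat = v / (1 - 0.999 ** step)
                    setattr(layer, p, getattr(layer, p)
                            - lr * mhat / (np.sqrt(vhat) + 1e-8))
            losses.append(epoch_loss / len(X))
            if verbose:
                print(f"epoch {epoch + 1}: loss {losses[-1]:.4f}")
        return losses

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, len(X), batch_size):
            logits = self.forward(X[start:start + batch_size])
            out.append(logits.argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)
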