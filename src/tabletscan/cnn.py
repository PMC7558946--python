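"""A small convolutional network for tablet-crop classification.

The architecture mirrors the compact image-classification networks used
for this kind of 4-class color problem: repeated blocks of 3x3 "same"
convolution -> ReLU -> 2x2 max pooling (stride 2), followed by a dense
softmax layer.  Filter sizes are fixed by :class:`CnnSpec` at 3x3
(convolution) and 2x2 (pooling).  Training is plain mini-batch Adam on
softmax cross-entropy with the training set reshuffled every epoch; the
iteration budget is ``epochs x ceil(n_train / batch_size)``.

Everything — initialization, shuffling, batching — runs off one seeded
``numpy.random.Generator``, so a fit is bit-reproducible for a fixed spec
and input.  The network is implemented directly on numpy (im2col
convolutions, argmax-routed pooling gradients); at the crop sizes this
package works with (tens of pixels before pooling) that is fast on a
single CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CnnSpec", "SmallCnn", "iterations_per_epoch", "iteration_cap"]


def iterations_per_epoch(n_train: int, batch_size: int) -> int:
    """Mini-batches per full pass over the training set."""
    if n_train < 1 or batch_size < 1:
        raise ValueError("n_train and batch_size must be positive")
    return math.ceil(n_train / batch_size)


def iteration_cap(epochs: int, iters_per_epoch: int) -> int:
    """Total optimizer steps implied by an (epochs, iterations/epoch) budget."""
    return int(epochs) * int(iters_per_epoch)


@dataclass
class CnnSpec:
    """Training configuration.

    ``conv_filter`` and ``pool_filter`` are fixed at 3 and 2.  The default
    budget (128 epochs, 372 training images drawn per class) matches the
    full-scale study regime; tests and desk-scale runs override
    ``epochs``/``train_per_class`` downward.  ``train_per_class=None``
    uses every available training image.
    """

    conv_filter: int = 3
    pool_filter: int = 2
    n_conv_blocks: int = 3
    channels_per_block: tuple[int, ...] = (8, 16, 32)
    epochs: int = 128
    batch_size: int = 32
    learning_rate: float = 0.01
    shuffle_each_epoch: bool = True
    train_per_class: int | None = 372
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_filter != 3 or self.pool_filter != 2:
            raise ValueError("filter sizes are fixed: conv 3x3, pool 2x2")
        if len(self.channels_per_block) != self.n_conv_blocks:
            raise ValueError("channels_per_block length must equal n_conv_blocks")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


# ---------------------------------------------------------------------------
# layer primitives (NCHW, stride-1 same-padded conv, 2x2/2 pool)

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (n, c, oh, ow, k, k) -> (n, c*k*k, oh*ow)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    oh, ow = h, w  # stride 1, same padding
    d = dcols.reshape(n, c, k, k, oh, ow)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + oh, j : j + ow] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.b = np.zeros(c_out)
        self.k, self.pad = k, k // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n = x.shape[0]
        out = self.W @ self._cols + self.b[None, :, None]
        return out.reshape(n, -1, x.shape[2], x.shape[3])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f = dout.shape[0], dout.shape[1]
        dflat = dout.reshape(n, f, -1)
        self.dW = np.einsum("nfp,ncp->fc", dflat, self._cols)
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fc,nfp->ncp", self.W, dflat)
        return _col2im(dcols, self._xshape, self.k, self.pad)


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"feature map {h}x{w} too small to pool")
        xc = x[:, :, : 2 * h2, : 2 * w2]
        self._xshape = x.shape
        windows = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        windows = windows.reshape(n, c, h2, w2, 4)
        self._arg = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        dwin = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dxc = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxc = dxc.reshape(n, c, 2 * h2, 2 * w2)
        dx = np.zeros(self._xshape)
        dx[:, :, : 2 * h2, : 2 * w2] = dxc
        return dx


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class SmallCnn:
    """Conv(3x3)->ReLU->MaxPool(2x2) blocks + dense softmax, Adam-trained."""

    def __init__(self, in_shape: tuple[int, int, int], n_classes: int,
                 spec: CnnSpec, rng: np.random.Generator):
        c, h, w = in_shape
        self.spec = spec
        self.blocks: list[tuple[_Conv, _ReLU, _MaxPool2]] = []
        for c_out in spec.channels_per_block:
            self.blocks.append((_Conv(c, c_out, spec.conv_filter, rng),
                                _ReLU(), _MaxPool2()))
            c = c_out
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError(
                    "input too small for the configured number of conv/pool "
                    f"blocks (feature map collapsed to {h}x{w})"
                )
        self.dense = _Dense(c * h * w, n_classes, rng)
        self._flat_shape = (c, h, w)
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        for conv, relu, pool in self.blocks:
            x = pool.forward(relu.forward(conv.forward(x)))
        self._pre_flat = x.shape
        return self.dense.forward(x.reshape(x.shape[0], -1))

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.dense.backward(dlogits).reshape(self._pre_flat)
        for conv, relu, pool in reversed(self.blocks):
            dx = conv.backward(relu.backward(pool.backward(dx)))

    def _parameters(self):
        for conv, _, _ in self.blocks:
            yield conv, "W"
            yield conv, "b"
        yield self.dense, "W"
        yield self.dense, "b"

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._t += 1
        for i, (layer, name) in enumerate(self._parameters()):
            g = getattr(layer, "d" + name)
            p = getattr(layer, name)
            if i not in self._adam_state:
                self._adam_state[i] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self._adam_state[i]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mh = m / (1 - beta1**self._t)
            vh = v / (1 - beta2**self._t)
            p -= lr * mh / (np.sqrt(vh) + eps)

    # ------------------------------------------------------------------
    def fit(self, x: np.ndarray, y_idx: np.ndarray,
            rng: np.random.Generator) -> list[dict]:
        """Train in place; returns a per-epoch log of loss and accuracy."""
        spec = self.spec
        n = x.shape[0]
        ipe = iterations_per_epoch(n, spec.batch_size)
        cap = iteration_cap(spec.epochs, ipe)
        log: list[dict] = []
        it = 0
        for epoch in range(spec.epochs):
            order = rng.permutation(n) if spec.shuffle_each_epoch else np.arange(n)
            losses = []
            correct = 0
            for b in range(ipe):
                if it >= cap:
                    break
                sel = order[b * spec.batch_size : (b + 1) * spec.batch_size]
                xb, yb = x[sel], y_idx[sel]
                logits = self.forward(xb)
                logits = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(logits)
                probs = expz / expz.sum(axis=1, keepdims=True)
                losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean()))
                correct += int((probs.argmax(axis=1) == yb).sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self.backward(dlogits)
                self.adam_step(spec.learning_rate)
                it += 1
            log.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "train_acc": correct / n, "iterations": it})
        return log

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)
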