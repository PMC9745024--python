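"""A small deterministic CNN for binary image classification.

Pure-numpy implementation (im2col convolutions, max pooling, dense
layers, Adam, weighted binary cross-entropy) sized for 200x400
grayscale inputs on a single CPU.  Determinism contract: given the same
data, architecture and seed, training reproduces identical weights and
predictions run-to-run.

Layout is NHWC.  Images are average-pooled by a fixed integer factor at
the input (the polyline structure survives coarse resolution and the
network stays small), then passed through ``n_conv`` conv(+ReLU)+maxpool
blocks, a hidden dense stack with dropout, and a sigmoid head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetConfig", "CNNClassifier", "downsample"]


def downsample(images: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool (N, H, W) images by an integer factor (crops remainder)."""
    n, h, w = images.shape
    hh, ww = h // factor, w // factor
    x = images[:, :hh * factor, :ww * factor]
    return x.reshape(n, hh, factor, ww, factor).mean(axis=(2, 4))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (N, H, W, C) -> (N, Ho, Wo, C*k*k)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    n, ho, wo, c, _, _ = win.shape
    return np.ascontiguousarray(win).reshape(n, ho, wo, c * k * k)


class _Conv:
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, scale, size=(in_ch * k * k, out_ch))
        self.b = np.zeros(out_ch)
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        self._col = _im2col(x, self.k)
        return self._col @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, ho, wo, _ = grad.shape
        col2 = self._col.reshape(-1, self.W.shape[0])
        g2 = grad.reshape(-1, self.out_ch)
        self.dW = col2.T @ g2
        self.db = g2.sum(axis=0)
        dcol = (g2 @ self.W.T).reshape(n, ho, wo, self.in_ch, self.k, self.k)
        dx = np.zeros(self._x_shape)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + ho, j:j + wo, :] += dcol[:, :, :, :, i, j]
        return dx

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _MaxPool:
    params: list = []
    grads: list = []

    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x, train):
        s = self.s
        n, h, w, c = x.shape
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        xr = x[:, :ho * s, :wo * s, :].reshape(n, ho, s, wo, s, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, s * s)
        self._idx = xr.argmax(axis=-1)
        self._pooled_shape = (n, ho, wo, c)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        s = self.s
        n, ho, wo, c = self._pooled_shape
        flat = np.zeros((n, ho, wo, c, s * s))
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, ho, wo, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape)
        dx[:, :ho * s, :wo * s, :] = flat.reshape(n, ho * s, wo * s, c)
        return dx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


@dataclass
class NetConfig:
    """Architecture and optimiser settings for one sub-model."""

    input_shape: tuple[int, int] = (200, 400)
    pool_input: int = 4          # fixed average-pool factor at the input
    n_conv: int = 2
    kernel_size: int = 3
    n_filters: int = 8           # filters in the first conv block (doubled per block)
    n_dense: int = 1             # hidden dense layers before the sigmoid head
    dense_units: int = 32
    dropout: float = 0.25
    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 8
    seed: int | tuple = 0


class CNNClassifier:
    """Binary CNN with weighted BCE loss and validation-loss early stopping."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self._train_rng = np.random.default_rng(rng.integers(2**31))
        self.layers = self._build(rng)

    def _build(self, rng: np.random.Generator) -> list:
        cfg = self.config
        h = cfg.input_shape[0] // cfg.pool_input
        w = cfg.input_shape[1] // cfg.pool_input
        layers: list = []
        in_ch = 1
        for block in range(cfg.n_conv):
            out_ch = cfg.n_filters * (2 ** block)
            layers.append(_Conv(in_ch, out_ch, cfg.kernel_size, rng))
            layers.append(_ReLU())
            layers.append(_MaxPool(2))
            h = (h - cfg.kernel_size + 1) // 2
            w = (w - cfg.kernel_size + 1) // 2
            in_ch = out_ch
        layers.append(_Flatten())
        n_feat = h * w * in_ch
        for _ in range(cfg.n_dense):
            layers.append(_Dense(n_feat, cfg.dense_units, rng))
            layers.append(_ReLU())
            layers.append(_Dropout(cfg.dropout, self._train_rng))
            n_feat = cfg.dense_units
        layers.append(_Dense(n_feat, 1, rng))
        return layers

    # ------------------------------------------------------------ plumbing

    def _prep(self, images: np.ndarray) -> np.ndarray:
        x = downsample(np.asarray(images, dtype=float), self.config.pool_input)
        return x[..., None]

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def _backward(self, grad: np.ndarray) -> None:
        g = grad[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1

    # ------------------------------------------------------------ training

    @staticmethod
    def _bce(logits: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
        # numerically stable log(1 + exp(-|z|)) formulation
        loss = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
        return float(np.average(loss, weights=w))

    def fit(self, images: np.ndarray, y: np.ndarray,
            val_images: np.ndarray, val_y: np.ndarray,
            class_weight: dict[int, float] | None = None) -> dict:
        """Train with Adam; keep the weights of the best validation epoch."""
        cfg = self.config
        x = self._prep(images)
        xv = self._prep(val_images)
        y = np.asarray(y, dtype=float)
        val_y = np.asarray(val_y, dtype=float)
        if class_weight is None:
            n_pos = max(y.sum(), 1.0)
            n_neg = max(len(y) - y.sum(), 1.0)
            class_weight = {0: len(y) / (2 * n_neg), 1: len(y) / (2 * n_pos)}
        w = np.where(y == 1, class_weight[1], class_weight[0])
        wv = np.where(val_y == 1, class_weight[1], class_weight[0])

        params = [p for layer in self.layers for p in layer.params]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss = np.inf
        best_weights = self.get_weights()
        best_epoch = -1
        history = []
        rng = self._train_rng
        n = len(y)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self._forward(x[idx], train=True)
                p = 1.0 / (1.0 + np.exp(-logits))
                grad = (p - y[idx]) * w[idx] / w[idx].sum()
                self._backward(grad)
                grads = [g for layer in self.layers for g in layer.grads]
                t += 1
                for i, (pr, g) in enumerate(zip(params, grads)):
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g * g
                    mh = m[i] / (1 - b1 ** t)
                    vh = v[i] / (1 - b2 ** t)
                    pr -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            val_loss = self._bce(self._forward(xv, train=False), val_y, wv)
            history.append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = self.get_weights()
                best_epoch = epoch
            elif epoch - best_epoch >= cfg.patience:
                break
        self.set_weights(best_weights)
        return {"best_val_loss": best_loss, "best_epoch": best_epoch,
                "history": history}

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._prep(images)
        out = []
        for start in range(0, len(x), batch_size):
            logits = self._forward(x[start:start + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(out) if out else np.empty(0)
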