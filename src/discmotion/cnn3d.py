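"""A compact NumPy 3-D convolutional network for heatmap-stack classification.

Architecture: two blocks of [3-D convolution -> leaky ReLU -> max pooling ->
batch normalization], global average pooling, and two dense layers producing
three outputs; the outputs are trained with per-class binary cross entropy
against one-hot emotion labels (a categorical cross-entropy option is also
provided) and the predicted class is the arg-max output.  Input samples are
short stacks of adjacent displacement-magnitude lattices, so the convolutions
see spatial structure within a heatmap and temporal structure across adjacent
frames.

All layers implement explicit forward/backward passes over mini-batches and
are optimized with Adam.  Every stochastic step (initialization, shuffling)
derives from one explicit seed, so training is reproducible run-to-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CNN3DConfig:
    """Hyperparameters of the 3-D network.

    ``channels`` are the two convolution widths, ``kernel`` the (depth,
    height, width) kernel (odd sides required for 'same' padding), ``pool``
    the max-pool window (depth preserved by default), ``dense_units`` the
    hidden dense width, ``leaky_slope`` the negative slope of the leaky ReLU.
    """

    channels: tuple[int, int] = (8, 16)
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool: tuple[int, int, int] = (1, 2, 2)
    dense_units: int = 32
    leaky_slope: float = 0.01
    loss: Literal["bce", "ce"] = "bce"
    lr: float = 3e-3
    batch_size: int = 64
    epochs: int = 40
    seed: int = 20230310


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class _Conv3D:
    """Stride-1 'same'-padded 3-D convolution (odd kernels only)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator) -> None:
        kd, kh, kw = kernel
        assert kd % 2 and kh % 2 and kw % 2, "same padding requires odd kernels"
        fan_in = c_in * kd * kh * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kd, kh, kw))
        self.b = np.zeros(c_out)
        self.kernel = kernel

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel
        return np.pad(
            x, ((0, 0), (0, 0), (kd // 2,) * 2, (kh // 2,) * 2, (kw // 2,) * 2)
        )

    @staticmethod
    def _im2col(x: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
        """(N, C, D', H', W', kd, kh, kw) windows as a (N*D'*H'*W', C*kd*kh*kw) GEMM operand."""
        win = sliding_window_view(x, kernel, axis=(2, 3, 4))
        n, c, d, h, w = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, -1)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, d, h, w = x.shape
        self._cols = self._im2col(self._pad(x), self.kernel)
        self._in_channels = x.shape[1]
        wmat = self.W.reshape(self.W.shape[0], -1)
        y = self._cols @ wmat.T
        return y.reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3) + self.b[
            None, :, None, None, None
        ]

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        n, o, d, h, w = dy.shape
        dy_mat = dy.transpose(0, 2, 3, 4, 1).reshape(-1, o)
        dW = (dy_mat.T @ self._cols).reshape(self.W.shape)
        db = dy.sum(axis=(0, 2, 3, 4))
        self._cols = None
        # dx = full correlation of dy with flipped kernels ('same', stride 1)
        wflip = self.W[:, :, ::-1, ::-1, ::-1]
        wmat = wflip.transpose(1, 0, 2, 3, 4).reshape(self._in_channels, -1)
        dy_cols = self._im2col(self._pad(dy), self.kernel)
        dx = (dy_cols @ wmat.T).reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3)
        return dx, [dW, db]


class _LeakyReLU:
    def __init__(self, slope: float) -> None:
        self.slope = slope

    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        return np.where(self._mask, dy, self.slope * dy), []


class _MaxPool3D:
    """Non-overlapping max pooling; trailing remainders are cropped."""

    def __init__(self, pool: tuple[int, int, int]) -> None:
        self.pool = pool

    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        pd, ph, pw = self.pool
        n, c, d, h, w = x.shape
        dd, hh, ww = d // pd, h // ph, w // pw
        self._in_shape = x.shape
        xc = x[:, :, : dd * pd, : hh * ph, : ww * pw]
        z = (
            xc.reshape(n, c, dd, pd, hh, ph, ww, pw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, dd, hh, ww, pd * ph * pw)
        )
        self._argmax = z.argmax(axis=-1)
        return np.take_along_axis(z, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        pd, ph, pw = self.pool
        n, c, d, h, w = self._in_shape
        dd, hh, ww = d // pd, h // ph, w // pw
        dz = np.zeros((n, c, dd, hh, ww, pd * ph * pw))
        np.put_along_axis(dz, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, : dd * pd, : hh * ph, : ww * pw] = (
            dz.reshape(n, c, dd, hh, ww, pd, ph, pw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, dd * pd, hh * ph, ww * pw)
        )
        return dx, []


class _BatchNorm3D:
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._istd.reshape(shape)
        return self.gamma.reshape(shape) * self._xhat + self.beta.reshape(shape)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        dgamma = (dy * self._xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(shape)
        dx = (
            self._istd.reshape(shape)
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes).reshape(shape)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(shape)
            )
        )
        return dx, [dgamma, dbeta]


class _GlobalAvgPool:
    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        n, c, d, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None] / (d * h * w), self._shape
        ).copy(), []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx, [dW, db]


class _LeakyReLU1D(_LeakyReLU):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class Conv3DNet:
    """The two-block 3-D CNN emotion classifier over heatmap stacks.

    ``fit`` expects ``X`` of shape (N, 1, depth, H, W) and integer class
    labels in [0, n_classes); inputs are standardized by the training mean
    and standard deviation.
    """

    def __init__(self, config: CNN3DConfig | None = None, n_classes: int = 3) -> None:
        self.config = config or CNN3DConfig()
        self.n_classes = n_classes
        self._built = False

    def _build(self, sample_shape: tuple[int, ...]) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c1, c2 = cfg.channels
        self.layers = [
            _Conv3D(sample_shape[0], c1, cfg.kernel, rng),
            _LeakyReLU(cfg.leaky_slope),
            _MaxPool3D(cfg.pool),
            _BatchNorm3D(c1),
            _Conv3D(c1, c2, cfg.kernel, rng),
            _LeakyReLU(cfg.leaky_slope),
            _MaxPool3D(cfg.pool),
            _BatchNorm3D(c2),
            _GlobalAvgPool(),
            _Dense(c2, cfg.dense_units, rng),
            _LeakyReLU1D(cfg.leaky_slope),
            _Dense(cfg.dense_units, self.n_classes, rng),
        ]
        self._rng = rng
        self._built = True

    def _set_training(self, training: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, _BatchNorm3D):
                layer.training = training

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv3DNet":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if X.ndim != 5:
            raise ValueError("X must have shape (N, C, depth, H, W)")
        self._mu = X.mean()
        self._sd = X.std() or 1.0
        Xs = (X - self._mu) / self._sd
        if not self._built:
            self._build(X.shape[1:])
        onehot = np.eye(self.n_classes)[y]
        params: list[np.ndarray] = []
        for layer in self.layers:
            params.extend(layer.params)
        opt = _Adam(params, self.config.lr)
        n = len(Xs)
        self._set_training(True)
        losses = []
        for _ in range(self.config.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                xb, yb = Xs[idx], onehot[idx]
                logits = self._forward(xb)
                if self.config.loss == "bce":
                    p = _sigmoid(logits)
                    eps = 1e-12
                    loss = -np.mean(
                        yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)
                    )
                    dlogits = (p - yb) / (len(idx) * self.n_classes)
                else:
                    p = _softmax(logits)
                    loss = -np.mean(np.log(p[np.arange(len(idx)), y[idx]] + 1e-12))
                    dlogits = (p - yb) / len(idx)
                epoch_loss += loss * len(idx)
                grads: list[np.ndarray] = []
                dy = dlogits
                for layer in reversed(self.layers):
                    dy, g = layer.backward(dy)
                    grads = g + grads
                opt.step(grads)
            losses.append(epoch_loss / n)
        self.loss_history_ = np.asarray(losses)
        self._set_training(False)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self._mu) / self._sd
        self._set_training(False)
        logits = self._forward(Xs)
        if self.config.loss == "bce":
            return _sigmoid(logits)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
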