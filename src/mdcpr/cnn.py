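"""A small convolutional regression network on spectrogram images.

Self-contained NumPy implementation (forward and backward passes written
out explicitly) of an 18-layer image-regression network:

    input -> [conv 3x3/8, BN, ReLU, avg-pool 2x2/2]
          -> [conv 3x3/32, BN, ReLU, avg-pool 2x2/2]
          -> [conv 3x3/32, BN, ReLU]
          -> [conv 3x3/32, BN, ReLU]
          -> fully-connected 32 -> fully-connected 1 -> squared-error loss

Convolutions use same padding; pooling is average, 2x2 with stride 2.
Training is stochastic gradient descent with momentum, mean-squared-error
loss, a held-out validation split and early stopping; the returned weights
come from the epoch with the lowest validation loss.

At the default 64x64 single-channel input the network has 283,329
trainable parameters (convs 80 + 2,336 + 9,248 + 9,248, batch-norm 208,
fully-connected 262,176 + 33).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*9) patches of the 1-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3) -> (B, H*W, C*9)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * 9)


class Conv2D(_Layer):
    """3x3 same-padding convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.params = [w.astype(np.float64), np.zeros(c_out)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train):
        self._shape = x.shape
        b, c, h, w = x.shape
        self._cols = _im2col(x)
        wmat = self.params[0].reshape(self.c_out, -1).T  # (C*9, F)
        out = self._cols @ wmat + self.params[1]
        return out.transpose(0, 2, 1).reshape(b, self.c_out, h, w)

    def backward(self, dout):
        b, f, h, w = dout.shape
        dmat = dout.reshape(b, f, h * w).transpose(0, 2, 1)  # (B, HW, F)
        self.grads[0][...] = (
            np.einsum("bpf,bpc->fc", dmat, self._cols).reshape(self.params[0].shape)
        )
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        # dx = same-conv of dout with spatially flipped, channel-swapped kernel
        wback = self.params[0][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, F, 3, 3)
        cols = _im2col(dout)
        dx = cols @ wback.reshape(self.c_in, -1).T
        return dx.transpose(0, 2, 1).reshape(self._shape)


class BatchNorm2D(_Layer):
    """Per-channel batch normalisation over (batch, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = [np.ones(c), np.zeros(c)]  # gamma, beta
        self.grads = [np.zeros(c), np.zeros(c)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._train = train
        return self.params[0][None, :, None, None] * self._xhat + self.params[1][None, :, None, None]

    def backward(self, dout):
        g = self.params[0][None, :, None, None]
        self.grads[0][...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * g
        if not self._train:
            return dxhat / self._std
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        return (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class AvgPool2(_Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x, train):
        b, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        b, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, :, None, :, None] / 4.0, (b, c, h // 2, 2, w // 2, 2)
        ).reshape(self._shape)


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w, np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class CnnSpec:
    """Architecture description; the canonical layer order is enforced."""

    input_hw: tuple[int, int] = (64, 64)
    input_channels: int = 1
    conv_filters: tuple[int, int, int, int] = (8, 32, 32, 32)
    fc_width: int = 32

    def __post_init__(self) -> None:
        if self.input_hw[0] % 4 or self.input_hw[1] % 4:
            raise ValueError("input size must be divisible by 4 (two 2x2 stride-2 pools)")
        if len(self.conv_filters) != 4:
            raise ValueError("exactly four convolution stages are required")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    momentum: float = 0.9
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 1.0 / 7.0
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class CnnRegressor:
    """The fixed 18-layer sequence with scalar regression output."""

    def __init__(self, spec: CnnSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        f1, f2, f3, f4 = spec.conv_filters
        h, w = spec.input_hw
        flat = (h // 4) * (w // 4) * f4
        self.layers: list[_Layer] = [
            Conv2D(spec.input_channels, f1, rng),
            BatchNorm2D(f1),
            ReLU(),
            AvgPool2(),
            Conv2D(f1, f2, rng),
            BatchNorm2D(f2),
            ReLU(),
            AvgPool2(),
            Conv2D(f2, f3, rng),
            BatchNorm2D(f3),
            ReLU(),
            Conv2D(f3, f4, rng),
            BatchNorm2D(f4),
            ReLU(),
            Flatten(),
            Dense(flat, spec.fc_width, rng),
            Dense(spec.fc_width, 1, rng),
        ]

    @property
    def n_params(self) -> int:
        """Trainable parameter count (283,329 at the 64x64 default)."""
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dout = dpred[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = _as_input(images, self.spec)
        out = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(p.copy() for p in layer.params)
            if isinstance(layer, BatchNorm2D):
                out.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = weights[i].copy()
                layer.running_var = weights[i + 1].copy()
                i += 2


def build_cnn(spec: CnnSpec | None = None, seed: int = 0) -> CnnRegressor:
    """Instantiate the network; identical seeds give identical weights."""
    return CnnRegressor(spec or CnnSpec(), seed=seed)


def _as_input(images: np.ndarray, spec: CnnSpec) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.shape[1:] != (spec.input_channels, *spec.input_hw):
        raise ValueError(f"images must be (n, {spec.input_channels}, *{spec.input_hw})")
    return x


def train_cnn(
    model: CnnRegressor,
    images: np.ndarray,
    labels_cm: np.ndarray,
    config: TrainConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Train with SGD + momentum, MSE loss and early stopping.

    ``validation`` may supply an explicit held-out split; otherwise
    ``config.validation_fraction`` of the data is split off at random.
    Training stops once the validation loss has not improved for
    ``config.patience`` epochs (or at ``max_epochs``); the model is left
    holding the weights of the best-validation epoch.  Returns the per
    epoch loss history.
    """
    cfg = config or TrainConfig()
    x = _as_input(images, model.spec)
    y = np.asarray(labels_cm, dtype=np.float64).ravel()
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("images and labels must be equal-length and non-empty")
    ss = np.random.SeedSequence(cfg.seed)
    rng_split, rng_shuffle = (np.random.default_rng(s) for s in ss.spawn(2))

    if validation is None:
        n_val = max(1, int(round(cfg.validation_fraction * len(x))))
        if n_val >= len(x):
            raise ValueError("validation split leaves no training data")
        perm = rng_split.permutation(len(x))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_tr, y_tr = x[tr_idx], y[tr_idx]
        x_val, y_val = x[val_idx], y[val_idx]
    else:
        x_tr, y_tr = x, y
        x_val = _as_input(validation[0], model.spec)
        y_val = np.asarray(validation[1], dtype=np.float64).ravel()
        if len(x_val) == 0:
            raise ValueError("empty validation set")

    velocity = {
        id(p): np.zeros_like(p) for layer in model.layers for p in layer.params
    }
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    history = []
    stall = 0

    for epoch in range(cfg.max_epochs):
        order = rng_shuffle.permutation(len(x_tr))
        train_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: "
                    "reduce the learning rate"
                )
            train_losses.append(loss)
            model.backward(2.0 * err / len(idx))
            for layer in model.layers:
                for p, g in zip(layer.params, layer.grads):
                    v = velocity[id(p)]
                    v *= cfg.momentum
                    v -= cfg.learning_rate * g
                    p += v
        val_pred = model.predict(x_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    model.set_weights(best_weights)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    hist.attrs["best_val_loss"] = best_val
    return hist


def evaluate_cnn(model: CnnRegressor, images: np.ndarray, labels_cm: np.ndarray) -> float:
    """RMSE (cm) of the model on a held-out set."""
    y = np.asarray(labels_cm, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(images)
    return float(np.sqrt(np.mean((pred - y) ** 2)))
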