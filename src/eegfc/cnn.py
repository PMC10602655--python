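"""A minimal numpy implementation of the shallow 2-D CNN.

Architecture (fixed topology, sizes configurable):

    conv(5x5, 50, same) -> batchnorm -> ReLU
        -> maxpool(2x2, floor)
    conv(5x5, 50, same) -> batchnorm -> ReLU
        -> flatten -> dense(3) -> softmax

trained with stochastic gradient descent with momentum (lr 0.001,
momentum 0.9), batch size 128, at most 50 passes over the training set,
with early stopping on validation loss checked every 8 iterations and a
patience of 20 consecutive checks; the best-validation-loss weights are
restored at the end.  Convolutions are evaluated as im2col matrix
products in float32; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CnnConfig:
    n_filters: int = 50
    kernel: int = 5
    pool: int = 2
    n_classes: int = 3
    input_shape: tuple[int, int] = (19, 19)
    padding: str = "same"
    lr: float = 0.001
    momentum: float = 0.9
    max_epochs: int = 50
    batch_size: int = 128
    patience: int = 20           # consecutive validation checks
    validation_every: int = 8    # iterations between checks
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel", "pool", "n_classes",
                     "max_epochs", "batch_size", "patience",
                     "validation_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        h, w = self.input_shape
        if h != w:
            raise ValueError("input must be square")
        if self.padding == "valid" and h < self.kernel:
            raise ValueError(
                f"{h}x{w} input smaller than {self.kernel}x{self.kernel} kernel"
            )


# ---------------------------------------------------------------------------
# layer primitives (functional, float32)

def _im2col(x: np.ndarray, k: int, pad: int,
            bufs: dict | None = None, tag: str = "") -> tuple[np.ndarray, tuple[int, int, int]]:
    """Channels-last patch matrix: (B, H, W, C) -> (B*Ho*Wo, k*k*C).

    Built as k*k bulk slice copies, which is far cheaper than a strided
    gather for the small feature maps this network sees.  ``bufs`` is an
    optional per-layer scratch cache so the (large) padded and patch
    arrays are allocated once per shape, not once per iteration.
    """
    def _buffer(key, shape, dtype, zero):
        if bufs is None:
            return np.zeros(shape, dtype) if zero else np.empty(shape, dtype)
        buf = bufs.get((key, shape))
        if buf is None or buf.dtype != dtype:
            buf = np.zeros(shape, dtype) if zero else np.empty(shape, dtype)
            bufs[(key, shape)] = buf
        return buf

    if pad:
        b, h, w, c = x.shape
        padded = _buffer(f"{tag}pad", (b, h + 2 * pad, w + 2 * pad, c),
                         x.dtype, zero=True)
        padded[:, pad: pad + h, pad: pad + w, :] = x
        x = padded
    b, h, w, c = x.shape
    ho, wo = h - k + 1, w - k + 1
    cols = _buffer(f"{tag}cols", (b, ho, wo, k, k, c), x.dtype, zero=False)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = x[:, i: i + ho, j: j + wo, :]
    return cols.reshape(b * ho * wo, k * k * c), (b, ho, wo)


class _Conv:
    """Stride-1 2-D convolution via im2col GEMM."""

    def __init__(self, c_in: int, c_out: int, k: int, padding: str,
                 rng: np.random.Generator, need_dx: bool = True):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, c_in, k, k))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.pad = (k - 1) // 2 if padding == "same" else 0
        self.need_dx = need_dx
        self._bufs: dict = {}

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def _wmat(self) -> np.ndarray:
        # (c_out, c_in, k, k) -> (k*k*c_in, c_out), matching _im2col layout
        return np.ascontiguousarray(
            self.w.transpose(2, 3, 1, 0).reshape(-1, self.w.shape[0]))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, (b, ho, wo) = _im2col(x, self.k, self.pad, self._bufs, "fwd")
        out = cols @ self._wmat() + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(b, ho, wo, -1)

    def backward(self, dout: np.ndarray):
        cols, x_shape = self._cache
        b, ho, wo, c_out = dout.shape
        dmat = dout.reshape(-1, c_out)
        k = self.k
        c_in = self.w.shape[1]
        dw_mat = cols.T @ dmat            # (k*k*c_in, c_out)
        self.dw = dw_mat.reshape(k, k, c_in, c_out).transpose(3, 2, 0, 1)
        self.db = dmat.sum(axis=0)
        if not self.need_dx:   # first layer: input gradient unused
            return None
        # dx = "full" correlation of dout with the 180-degree-rotated kernels
        w_flip = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1].transpose(2, 3, 0, 1).reshape(-1, c_in))
        pad_back = self.k - 1 - self.pad
        cols_b, (_, hi, wi) = _im2col(dout, self.k, pad_back, self._bufs, "bwd")
        dx = (cols_b @ w_flip).reshape(b, hi, wi, c_in)
        # crop to original input size (same padding keeps them equal)
        _, h0, w0, _ = x_shape
        return np.ascontiguousarray(dx[:, :h0, :w0, :])


class _BatchNorm:
    """Per-feature-map batch normalization."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        m = x.shape[0] * x.shape[1] * x.shape[2]
        if train:
            mean = np.einsum("bhwc->c", x) / m
            var = np.einsum("bhwc,bhwc->c", x, x) / m - mean * mean
            var = np.maximum(var, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = x * inv
        xhat -= mean.astype(x.dtype) * inv
        out = xhat * self.gamma
        out += self.beta
        if train:
            self._cache = (xhat, inv)
        return out

    def backward(self, dout: np.ndarray):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.dgamma = np.einsum("bhwc,bhwc->c", dout, xhat)
        self.dbeta = np.einsum("bhwc->c", dout)
        dx = dout - self.dbeta / m
        dx -= xhat * (self.dgamma / m)
        dx *= self.gamma * inv
        return dx


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray):
        return dout * self._mask


class _MaxPool:
    """Non-overlapping pooling with floor-mode cropping of odd edges."""

    def __init__(self, size: int):
        self.size = size

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.size
        b, h, w, c = x.shape
        ho, wo = h // p, w // p
        tiles = x[:, : ho * p, : wo * p, :].reshape(b, ho, p, wo, p, c)
        out = tiles.max(axis=(2, 4))
        if train:
            # routing mask; exact ties (rare with float activations) send
            # the gradient to every maximum
            self._mask = tiles == out[:, :, None, :, None, :]
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray):
        p = self.size
        b, h, w, c = self._in_shape
        ho, wo = h // p, w // p
        core = (self._mask * dout[:, :, None, :, None, :]).reshape(
            b, ho * p, wo * p, c)
        if (ho * p, wo * p) == (h, w):
            return core
        dx = np.zeros((b, h, w, c), dtype=dout.dtype)
        dx[:, : ho * p, : wo * p, :] = core
        return dx


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_in, d_out))
                  * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ShallowCNN:
    """The shallow two-block CNN classifier."""

    def __init__(self, cfg: CnnConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, w = cfg.input_shape
        if cfg.padding == "same":
            h1, w1 = h, w
        else:
            h1, w1 = h - cfg.kernel + 1, w - cfg.kernel + 1
        hp, wp = h1 // cfg.pool, w1 // cfg.pool
        if min(hp, wp) < 1:
            raise ValueError("input too small: pooled feature map is empty")
        if cfg.padding == "same":
            h2, w2 = hp, wp
        else:
            h2, w2 = hp - cfg.kernel + 1, wp - cfg.kernel + 1
            if min(h2, w2) < 1:
                raise ValueError("input too small for the second block")
        self.layers = [
            _Conv(1, cfg.n_filters, cfg.kernel, cfg.padding, rng, need_dx=False),
            _BatchNorm(cfg.n_filters),
            _ReLU(),
            _MaxPool(cfg.pool),
            _Conv(cfg.n_filters, cfg.n_filters, cfg.kernel, cfg.padding, rng),
            _BatchNorm(cfg.n_filters),
            _ReLU(),
            _Flatten(),
            _Dense(h2 * w2 * cfg.n_filters, cfg.n_classes, rng),
        ]
        self.feature_map_entering_block2 = (hp, wp, cfg.n_filters)

    # -- bookkeeping ------------------------------------------------------

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for _, p in layer.params())

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                state[f"{i}.{name}"] = p.copy()
            if isinstance(layer, _BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                p[...] = state[f"{i}.{name}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]

    # -- forward/backward -------------------------------------------------

    @staticmethod
    def _as_batch(x: np.ndarray) -> np.ndarray:
        """Accept (N, H, W) or (N, H, W, 1); channels-last internally."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, :, :, None]
        return x

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = self._as_batch(x)
        out = [
            _softmax(self._forward(x[i: i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out).astype(np.float64)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def _loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self._forward(x, train=True)
        p = _softmax(logits)
        n = x.shape[0]
        loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return float(loss)

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(cross-entropy loss, accuracy) in inference mode."""
        p = self.predict_proba(x)
        n = len(y)
        loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
        acc = float((p.argmax(axis=1) == y).mean())
        return loss, acc


def train_cnn(
    model: ShallowCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> dict:
    """Train with SGDM and validation-loss early stopping.

    Returns a training log dict with per-check statistics, the stopping
    iteration, and the best validation loss; the model is left holding
    the best-validation checkpoint weights.
    """
    cfg = model.cfg
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    x_train = model._as_batch(x_train)
    x_val_b = np.asarray(x_val, dtype=np.float32)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)

    velocity = {
        (i, name): np.zeros_like(p)
        for i, layer in enumerate(model.layers)
        for name, p in layer.params()
    }
    rng = np.random.default_rng(cfg.seed + 1)
    best_loss = np.inf
    best_state = model.state_dict()
    checks_since_best = 0
    iteration = 0
    log = {"check_iter": [], "train_loss": [], "val_loss": [], "val_acc": []}
    stop = False

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            loss = model._loss_and_grad(x_train[idx], y_train[idx])
            for i, layer in enumerate(model.layers):
                grads = {"w": getattr(layer, "dw", None),
                         "b": getattr(layer, "db", None),
                         "gamma": getattr(layer, "dgamma", None),
                         "beta": getattr(layer, "dbeta", None)}
                for name, p in layer.params():
                    g = grads[name]
                    v = velocity[(i, name)]
                    v *= cfg.momentum
                    v -= cfg.lr * g.astype(np.float32)
                    p += v
            iteration += 1
            if iteration % cfg.validation_every == 0:
                val_loss, val_acc = model.evaluate(x_val_b, y_val)
                log["check_iter"].append(iteration)
                log["train_loss"].append(loss)
                log["val_loss"].append(val_loss)
                log["val_acc"].append(val_acc)
                if val_loss < best_loss:
                    best_loss = val_loss
                    best_state = model.state_dict()
                    checks_since_best = 0
                else:
                    checks_since_best += 1
                    if checks_since_best >= cfg.patience:
                        stop = True
                        break
        if stop:
            break

    model.load_state_dict(best_state)
    log["stopped_at_iteration"] = iteration
    log["best_val_loss"] = float(best_loss)
    return log
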