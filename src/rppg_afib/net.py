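"""Sample-level 1-D convolutional network for 30-s rPPG rhythm clips.

The classifier follows the sample-level CNN design originally used for
raw-waveform audio: a deep stack of small (kernel-3) 1-D convolutions
with batch normalization, ReLU and stride-3 max pooling, so the
temporal extent shrinks geometrically while the channel width grows,
followed by a global max pool, dropout and a single fully-connected
output unit.  With the default architecture there are 12 weight layers
(11 convolutional + 1 fully connected) and a 30-s clip at 84 Hz
(2520 samples) is reduced to length 1 after seven pools.

The network, its backpropagation and the Adam optimizer are implemented
directly on NumPy arrays.  Training is deterministic under a fixed
seed: initialization, mini-batch order and dropout masks all derive
from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .segment import Segment, TaskDataset

__all__ = [
    "ArchConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "param_count",
    "default_arch",
    "train_model",
    "predict_proba",
    "save_model",
    "load_model",
]

CHECKPOINT_VERSION = 1

DEFAULT_CHANNELS = (16, 16, 32, 32, 64, 64, 64, 128, 128, 128, 256)


DEFAULT_POOL_AFTER = (1, 2, 3, 5, 7)
_POOL_CANDIDATES = (1, 2, 3, 5, 7, 9, 11)


@dataclass(frozen=True)
class ArchConfig:
    """Architecture of the sample-level CNN.

    ``pool_after`` holds 1-based indices of the convolutional layers
    followed by a max pool.  Pooling uses floor semantics (a trailing
    remainder shorter than ``pool_size`` is dropped), and the schedule
    must leave at least one temporal sample before the global pool.

    The front end and pool placement are tuned to the 84-Hz pulse band
    rather than to audio rates: a beat lasts ~50-100 samples, so the
    receptive field must span at least one full beat-to-beat interval
    *before* pooling decimates the temporal axis below the pulse
    frequency, or interval irregularity — the discriminative signal —
    becomes invisible.  A stride-4 first convolution (the pulse band is
    14x oversampled at 84 Hz) plus kernel 7 and pools spread over
    layers 1-7 satisfies this; kernel 3 with a pool after every early
    layer (the audio-style schedule) measurably does not.
    """

    input_length: int = 2520
    kernel_size: int = 7
    first_stride: int = 4
    channel_widths: tuple[int, ...] = DEFAULT_CHANNELS
    pool_after: tuple[int, ...] = DEFAULT_POOL_AFTER
    pool_size: int = 3
    dropout_rate: float = 0.5        # before the fully-connected head
    conv_dropout_rate: float = 0.0   # channel dropout inside each conv block
    batchnorm: bool = True

    @property
    def n_conv_layers(self) -> int:
        return len(self.channel_widths)

    @property
    def n_weight_layers(self) -> int:
        return self.n_conv_layers + 1  # + fully-connected head

    def temporal_lengths(self) -> list[int]:
        """Temporal length after each conv(+pool) block; validates the
        pooling schedule against the input length."""
        lengths = []
        length = int(self.input_length)
        if length < 1:
            raise ValueError("input_length must be >= 1")
        for i in range(1, self.n_conv_layers + 1):
            if i == 1:
                length = -(-length // self.first_stride)  # ceil
            if i in self.pool_after:
                length //= self.pool_size
                if length < 1:
                    raise ValueError(
                        f"pooling after layer {i} exhausts the temporal axis "
                        f"for input_length={self.input_length}")
            lengths.append(length)
        return lengths


def default_arch(input_length: int = 2520, pool_size: int = 3,
                 first_stride: int = 4, **kwargs) -> ArchConfig:
    """Default 12-weight-layer architecture, with the pooling schedule
    trimmed so the temporal axis survives the given input length
    (shorter clips take fewer pools before the global max pool)."""
    n_pools = 0
    length = -(-int(input_length) // first_stride)
    while n_pools < len(_POOL_CANDIDATES) and length // pool_size >= 1:
        length //= pool_size
        n_pools += 1
    return ArchConfig(input_length=int(input_length), pool_size=pool_size,
                      first_stride=first_stride,
                      pool_after=_POOL_CANDIDATES[:n_pools], **kwargs)


def param_count(arch: ArchConfig) -> int:
    """Number of trainable weights: sum of k*c_in*c_out + c_out over the
    conv stack plus the fully-connected head (batch-norm scale/shift
    parameters counted separately below are excluded on purpose — this
    mirrors the convention of counting weight layers only)."""
    total = 0
    c_in = 1
    for c_out in arch.channel_widths:
        total += arch.kernel_size * c_in * c_out + c_out
        c_in = c_out
    total += c_in * 1 + 1
    return total


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv1dSame:
    """Kernel-k 'same' convolution (optionally strided) via im2col and
    one matmul; output length is ceil(L / stride)."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, stride: int = 1):
        fan_in = c_in * k
        self.w = (rng.standard_normal((c_out, fan_in)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.stride = stride
        self.c_in = c_in
        self.c_out = c_out
        self.params = ["w", "b"]

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        n, c, length = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = cols[:, :, ::self.stride, :]  # (n, c, L_out, k)
        l_out = cols.shape[2]
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n, l_out, c * self.k)
        if train:
            self._cols = cols
            self._in_len = length
        y = cols @ self.w.T + self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c_out, l_out = dy.shape
        dyt = dy.transpose(0, 2, 1).reshape(n * l_out, c_out)
        cols = self._cols.reshape(n * l_out, -1)
        self.dw = (dyt.T @ cols).astype(np.float32)
        self.db = dyt.sum(axis=0).astype(np.float32)
        dcols = (dyt @ self.w).reshape(n, l_out, self.c_in, self.k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (n, c_in, L_out, k)
        pad = self.k // 2
        length = self._in_len
        dxp = np.zeros((n, self.c_in, length + 2 * pad), dtype=np.float32)
        s = self.stride
        for j in range(self.k):
            dst = dxp[:, :, j:j + (l_out - 1) * s + 1:s]
            dst += dcols[:, :, :dst.shape[2], j]
        del self._cols
        return dxp[:, :, pad:pad + length]


class _BatchNorm1d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = ["gamma", "beta"]

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        if train:
            self._xhat = xhat
            self._std = std
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = dy.shape
        m = n * length
        dgamma = (dy * self._xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        self.dgamma = dgamma.astype(np.float32)
        self.dbeta = dbeta.astype(np.float32)
        g_over_std = (self.gamma / self._std)[None, :, None]
        dx = g_over_std * (dy - dbeta[None, :, None] / m
                           - self._xhat * dgamma[None, :, None] / m)
        del self._xhat
        return dx.astype(np.float32)


class _ReLU:
    params: list[str] = []

    def forward(self, x, train, rng):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        out = dy * self._mask
        del self._mask
        return out


class _MaxPool1d:
    params: list[str] = []

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train, rng):
        n, c, length = x.shape
        l_out = length // self.size
        trimmed = x[:, :, :l_out * self.size].reshape(n, c, l_out, self.size)
        idx = trimmed.argmax(axis=3)
        if train:
            self._idx = idx
            self._in_len = length
        return np.take_along_axis(trimmed, idx[..., None], axis=3)[..., 0]

    def backward(self, dy):
        n, c, l_out = dy.shape
        dx_blocks = np.zeros((n, c, l_out, self.size), dtype=np.float32)
        np.put_along_axis(dx_blocks, self._idx[..., None], dy[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=np.float32)
        dx[:, :, :l_out * self.size] = dx_blocks.reshape(n, c, l_out * self.size)
        del self._idx
        return dx


class _GlobalMaxPool:
    params: list[str] = []

    def forward(self, x, train, rng):
        idx = x.argmax(axis=2)
        if train:
            self._idx = idx
            self._in_len = x.shape[2]
        return np.take_along_axis(x, idx[..., None], axis=2)[..., 0]

    def backward(self, dy):  # dy: (n, c)
        n, c = dy.shape
        dx = np.zeros((n, c, self._in_len), dtype=np.float32)
        np.put_along_axis(dx, self._idx[..., None], dy[..., None], axis=2)
        del self._idx
        return dx


class _Dropout:
    """Inverted dropout; with ``channelwise`` the mask drops whole
    feature channels per sample (spatial dropout), which regularizes
    convolutions far better than i.i.d. masks over correlated samples."""

    params: list[str] = []

    def __init__(self, rate: float, channelwise: bool = False):
        self.rate = rate
        self.channelwise = channelwise

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0], x.shape[1], 1) if self.channelwise and x.ndim == 3 \
            else x.shape
        self._mask = (rng.random(shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if not hasattr(self, "_mask"):
            return dy
        out = dy * self._mask
        del self._mask
        return out


class _Dense:
    def __init__(self, c_in: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((c_in, 1)) *
                  np.sqrt(2.0 / c_in)).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)
        self.params = ["w", "b"]

    def forward(self, x, train, rng):  # x: (n, c_in)
        if train:
            self._x = x
        return (x @ self.w + self.b)[:, 0]

    def backward(self, dz):  # dz: (n,)
        self.dw = (self._x.T @ dz[:, None]).astype(np.float32)
        self.db = np.asarray([dz.sum()], dtype=np.float32)
        dx = dz[:, None] @ self.w.T
        del self._x
        return dx.astype(np.float32)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class AFibNet:
    """The assembled network; operates on (n, input_length) float32."""

    def __init__(self, arch: ArchConfig, seed: int = 0):
        arch.temporal_lengths()  # validates the pooling schedule
        self.arch = arch
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
        self.layers: list = []
        c_in = 1
        for i, c_out in enumerate(arch.channel_widths, start=1):
            stride = arch.first_stride if i == 1 else 1
            self.layers.append(_Conv1dSame(c_in, c_out, arch.kernel_size, rng,
                                           stride=stride))
            if arch.batchnorm:
                self.layers.append(_BatchNorm1d(c_out))
            self.layers.append(_ReLU())
            if i in arch.pool_after:
                self.layers.append(_MaxPool1d(arch.pool_size))
            if arch.conv_dropout_rate > 0:
                self.layers.append(_Dropout(arch.conv_dropout_rate,
                                            channelwise=True))
            c_in = c_out
        self.layers.append(_GlobalMaxPool())
        self.layers.append(_Dropout(arch.dropout_rate))
        self.head = _Dense(c_in, rng)
        self.layers.append(self.head)

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[tuple[object, str]]:
        return [(layer, name) for layer in self.layers
                for name in getattr(layer, "params", [])]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters and batch-norm running statistics."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name in getattr(layer, "params", []):
                out[f"layer{i}.{name}"] = getattr(layer, name)
            if isinstance(layer, _BatchNorm1d):
                out[f"layer{i}.running_mean"] = layer.running_mean
                out[f"layer{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".", 1)
            setattr(self.layers[int(idx[5:])], name, value.copy())

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.arch.input_length:
            raise ValueError(
                f"expected input of shape (n, {self.arch.input_length}), got {x.shape}")
        out = x.astype(np.float32)[:, None, :]  # (n, 1, L)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dz: np.ndarray) -> None:
        grad = dz
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for start in range(0, x.shape[0], batch_size):
            z = self.forward_logits(x[start:start + batch_size], train=False)
            probs.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.concatenate(probs) if probs else np.empty(0)


def build_model(arch: ArchConfig | None = None, seed: int = 0) -> AFibNet:
    """Construct an untrained network; raises if the pooling schedule is
    inconsistent with the input length."""
    return AFibNet(arch or ArchConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    patience: int | None = 10     # early stop on validation loss; None = off
    val_fraction: float = 0.1     # held out from training data when patience on
    class_weight: bool = False    # inverse-frequency loss weights
    weight_decay: float = 0.0     # decoupled (AdamW-style), conv/dense only
    shift_augment: bool = True    # random circular time shift per example
    warp_augment: bool = True     # random time-scale warp per example
    warp_range: tuple[float, float] = (0.75, 1.3)
    noise_augment: float = 0.0    # max added-noise SD (on z-scored clips)
    lr_schedule: str = "constant"  # "constant" or "cosine" decay
    ensemble: int = 2             # models trained per fold (seed-averaged)
    tta_shifts: int = 3           # circular shifts averaged at inference
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


@dataclass
class TrainedModel:
    arch: ArchConfig
    net: AFibNet
    train_log: list[dict] = field(default_factory=list)
    seed: int = 0
    config: TrainConfig | None = None


class _Adam:
    def __init__(self, net: AFibNet, cfg: TrainConfig):
        self.cfg = cfg
        self.slots = [(layer, name,
                       np.zeros_like(getattr(layer, name)),
                       np.zeros_like(getattr(layer, name)))
                      for layer, name in net.parameters()]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        c = self.cfg
        lr = c.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - c.adam_beta1 ** self.t
        bc2 = 1.0 - c.adam_beta2 ** self.t
        for layer, name, m, v in self.slots:
            g = getattr(layer, "d" + name)
            m *= c.adam_beta1
            m += (1 - c.adam_beta1) * g
            v *= c.adam_beta2
            v += (1 - c.adam_beta2) * g * g
            p = getattr(layer, name)
            update = lr * (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)
            if c.weight_decay and name in ("w",):  # not BN scale/shift or biases
                update = update + lr * c.weight_decay * p
            setattr(layer, name, p - update.astype(np.float32))


def _augment_batch(xb: np.ndarray, cfg: TrainConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation of waveform clips.

    The rhythm class of a clip is invariant to where it starts (circular
    shift), to a moderate change of the underlying heart rate (time
    warp), and to extra measurement noise of random depth (noise
    injection).  All are applied per example; the warp removes the
    shortcut of memorizing a training subject's rate, and the noise
    injection teaches that a poor signal-to-noise ratio is not by
    itself evidence of AF.
    """
    n, length = xb.shape
    if not (cfg.shift_augment or cfg.warp_augment or cfg.noise_augment):
        return xb
    if not (cfg.shift_augment or cfg.warp_augment):
        sd = rng.uniform(0.0, cfg.noise_augment, size=(n, 1)).astype(np.float32)
        return ((xb + sd * rng.standard_normal(xb.shape).astype(np.float32))
                / np.sqrt(1.0 + sd * sd))
    pos = np.broadcast_to(np.arange(length, dtype=np.float64), (n, length))
    if cfg.warp_augment:
        lo, hi = cfg.warp_range
        scale = rng.uniform(lo, hi, size=(n, 1))
        pos = pos * scale
    if cfg.shift_augment:
        pos = pos + rng.integers(0, length, size=(n, 1))
    pos = np.mod(pos, length)
    i0 = pos.astype(np.intp)
    frac = (pos - i0).astype(np.float32)
    i1 = i0 + 1
    i1[i1 == length] = 0
    x0 = np.take_along_axis(xb, i0, axis=1)
    x1 = np.take_along_axis(xb, i1, axis=1)
    out = x0 * (1.0 - frac) + x1 * frac
    if cfg.noise_augment > 0:
        sd = rng.uniform(0.0, cfg.noise_augment, size=(n, 1)).astype(np.float32)
        out = ((out + sd * rng.standard_normal(out.shape).astype(np.float32))
               / np.sqrt(1.0 + sd * sd))
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray,
                     w: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy; returns (mean loss, dL/dz)."""
    z64 = z.astype(np.float64)
    loss = np.maximum(z64, 0) - z64 * y + np.log1p(np.exp(-np.abs(z64)))
    p = 1.0 / (1.0 + np.exp(-z64))
    wsum = w.sum()
    dz = (w * (p - y) / wsum).astype(np.float32)
    return float((w * loss).sum() / wsum), dz


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, TaskDataset):
        return data.matrix(), data.labels().astype(np.float64)
    x, y = data
    return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.float64)


def train_model(data: TaskDataset | tuple[np.ndarray, np.ndarray],
                cfg: TrainConfig,
                arch: ArchConfig | None = None) -> TrainedModel:
    """Train the classifier by mini-batch Adam on binary cross-entropy.

    ``data`` is a TaskDataset or an (X, y) pair of z-scored clips and
    binary labels.  When ``cfg.patience`` is set, a stratified
    ``val_fraction`` of the data is held out and the parameters giving
    the lowest validation loss are restored at the end; with
    ``patience=None`` all data is used and all epochs run.  Everything
    random (init, shuffling, dropout, the validation split) derives
    from ``cfg.seed``.
    """
    x, y = _as_xy(data)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training data contains a single class: {classes}")
    arch = arch or default_arch(x.shape[1])
    if x.shape[1] != arch.input_length:
        raise ValueError(f"segments of length {x.shape[1]} vs arch input "
                         f"{arch.input_length}")

    ss = np.random.SeedSequence([int(cfg.seed), 0xA1])
    split_rng, order_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    use_val = cfg.patience is not None and cfg.val_fraction > 0
    if use_val:
        val_idx: list[int] = []
        for cls in classes:
            members = np.flatnonzero(y == cls)
            members = split_rng.permutation(members)
            n_val = max(1, int(round(cfg.val_fraction * members.size)))
            val_idx.extend(members[:n_val])
        val_mask = np.zeros(x.shape[0], dtype=bool)
        val_mask[val_idx] = True
        if np.unique(y[~val_mask]).size < 2:
            use_val = False  # too small to split; fall back to all data
    if use_val:
        x_tr, y_tr = x[~val_mask], y[~val_mask]
        x_val, y_val = x[val_mask], y[val_mask]
    else:
        x_tr, y_tr = x, y

    if cfg.class_weight:
        n_pos = float((y_tr == 1).sum())
        n_neg = float((y_tr == 0).sum())
        w_pos = y_tr.size / (2.0 * n_pos)
        w_neg = y_tr.size / (2.0 * n_neg)
    else:
        w_pos = w_neg = 1.0
    weights = np.where(y_tr == 1, w_pos, w_neg)

    net = build_model(arch, seed=cfg.seed)
    opt = _Adam(net, cfg)
    log_rows: list[dict] = []
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0

    n = x_tr.shape[0]
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            frac = epoch / max(1, cfg.epochs - 1)
            lr = cfg.lr * (0.55 + 0.45 * np.cos(np.pi * frac))
        else:
            lr = cfg.lr
        order = order_rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb, wb = x_tr[idx], y_tr[idx], weights[idx]
            xb = _augment_batch(xb, cfg, drop_rng)
            z = net.forward_logits(xb, train=True, rng=drop_rng)
            loss, dz = _bce_with_logits(z, yb, wb)
            net.backward(dz)
            opt.step(lr)
            epoch_loss += loss * idx.size
            correct += int(((z > 0) == (yb > 0.5)).sum())
        row = {"epoch": epoch, "train_loss": epoch_loss / n,
               "train_acc": correct / n}
        if use_val:
            zv = net.forward_logits(x_val, train=False)
            val_loss, _ = _bce_with_logits(zv, y_val, np.ones_like(y_val))
            row["val_loss"] = val_loss
            row["val_acc"] = float(((zv > 0) == (y_val > 0.5)).mean())
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = {k: v.copy() for k, v in net.state_arrays().items()}
                stale = 0
            else:
                stale += 1
        log_rows.append(row)
        if use_val and cfg.patience is not None and stale > cfg.patience:
            break
    if use_val and best_state is not None:
        net.load_state_arrays(best_state)
    return TrainedModel(arch=arch, net=net, train_log=log_rows,
                        seed=cfg.seed, config=cfg)


def predict_proba(model: TrainedModel,
                  segments: list[Segment] | np.ndarray) -> np.ndarray:
    """AF probability per clip, in input order; batch-size independent
    (inference uses running batch-norm statistics and no dropout)."""
    if isinstance(segments, np.ndarray):
        x = segments.astype(np.float32)
    else:
        x = np.stack([s.samples for s in segments]).astype(np.float32)
    if x.ndim != 2 or x.shape[1] != model.arch.input_length:
        raise ValueError(
            f"segments of length {x.shape[-1]} do not match model input "
            f"{model.arch.input_length}")
    return model.net.predict_proba(x)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: architecture + weights + running stats."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "arch": asdict(model.arch),
        "seed": model.seed,
        "train_log": model.train_log,
    }
    state = model.net.state_arrays()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        arch_dict = meta["arch"]
        arch_dict["channel_widths"] = tuple(arch_dict["channel_widths"])
        arch_dict["pool_after"] = tuple(arch_dict["pool_after"])
        arch = ArchConfig(**arch_dict)
        net = build_model(arch, seed=meta["seed"])
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net.load_state_arrays(state)
    return TrainedModel(arch=arch, net=net, train_log=meta["train_log"],
                        seed=meta["seed"])
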