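"""Hybrid convolution-attention-BiLSTM respiratory waveform regressor.

The network maps a T x 4 window of conditioned channels (face rPPG, face
motion, chest rPPG, chest motion) to a T x 1 respiratory waveform:

1. a per-timestep affine embedding 4 -> d_model;
2. an encoder of three 1-D convolution blocks with decreasing kernel sizes
   (7, 5, 3; each conv -> ReLU -> batch norm -> dropout, same-length padding)
   followed by 8-head scaled-dot-product self-attention with a residual
   connection and layer normalization;
3. a two-layer bidirectional LSTM whose per-direction width is d_model/2, so
   the concatenated forward/backward states keep width d_model;
4. a convolutional decoder d_model -> 64 -> 32 -> 1 (kernels 5, 3, 1).

Training minimizes the mean squared error against the conditioned belt
reference with AdamW and a reduce-on-plateau schedule; everything is seeded
and CPU-deterministic. The estimator wrapper follows scikit-learn
conventions (``fit``/``predict``, ``get_params``, trailing-underscore
fitted attributes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .signals import MultiChannelWindow

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "RespNet",
    "WaveformRegressor",
    "subject_kfold_split",
    "stitch_windows",
    "windows_to_array",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults are the reference configuration)."""

    d_model: int = 128
    conv_kernels: tuple[int, ...] = (7, 5, 3)
    n_heads: int = 8
    lstm_layers: int = 2
    lstm_hidden: int = 64
    decoder_channels: tuple[int, ...] = (64, 32, 1)
    decoder_kernels: tuple[int, ...] = (5, 3, 1)
    dropout: float = 0.2
    n_channels: int = 4
    channel_weights: tuple[float, ...] | None = None  # optional region scaling

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if 2 * self.lstm_hidden != self.d_model:
            raise ValueError("2 * lstm_hidden must equal d_model so the BiLSTM "
                             "output keeps the embedding width")
        if self.decoder_channels[-1] != 1:
            raise ValueError("decoder must end in a single channel")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if len(self.decoder_kernels) != len(self.decoder_channels):
            raise ValueError("decoder kernel/channel lists must match in length")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup)."""

    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    weight_decay: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    val_fraction: float = 0.1
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")


class RespNet:
    """The assembled network; forward/backward over (B, T, 4) arrays."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        d = config.d_model
        self.embed = nn.Dense(config.n_channels, d, rng, dtype)
        self.conv_blocks = []
        for k in config.conv_kernels:
            self.conv_blocks.append({
                "conv": nn.Conv1d(d, d, k, rng, dtype),
                "relu": nn.ReLU(),
                "bn": nn.BatchNorm1d(d, dtype=dtype),
                "drop": nn.Dropout(config.dropout, self._dropout_rng),
            })
        self.attention = nn.MultiHeadAttention(d, config.n_heads, config.dropout,
                                               rng, dtype)
        self.lstms = []
        c_in = d
        for _ in range(config.lstm_layers):
            self.lstms.append({
                "bilstm": nn.BiLSTM(c_in, config.lstm_hidden, rng, dtype),
                "drop": nn.Dropout(config.dropout, self._dropout_rng),
            })
            c_in = 2 * config.lstm_hidden
        self.decoder = []
        dec_in = c_in
        n_dec = len(config.decoder_channels)
        for i, (c_out, k) in enumerate(zip(config.decoder_channels, config.decoder_kernels)):
            self.decoder.append({
                "conv": nn.Conv1d(dec_in, c_out, k, rng, dtype),
                "relu": nn.ReLU() if i < n_dec - 1 else None,
            })
            dec_in = c_out
        cw = config.channel_weights
        self._channel_scale = None if cw is None else np.asarray(cw, dtype=dtype)

    # -- plumbing ----------------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        params = self.embed.parameters()
        for blk in self.conv_blocks:
            params += blk["conv"].parameters() + blk["bn"].parameters()
        params += self.attention.parameters()
        for blk in self.lstms:
            params += blk["bilstm"].parameters()
        for blk in self.decoder:
            params += blk["conv"].parameters()
        return params

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T, 4) -> (B, T) predicted waveform."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[-1] != self.config.n_channels:
            raise ValueError(f"expected (B, T, {self.config.n_channels}) input")
        if self._channel_scale is not None:
            x = x * self._channel_scale
        h = self.embed.forward(x, train)
        for blk in self.conv_blocks:
            h = blk["conv"].forward(h, train)
            h = blk["relu"].forward(h, train)
            h = blk["bn"].forward(h, train)
            h = blk["drop"].forward(h, train)
        h = self.attention.forward(h, train)
        for blk in self.lstms:
            h = blk["bilstm"].forward(h, train)
            h = blk["drop"].forward(h, train)
        for blk in self.decoder:
            h = blk["conv"].forward(h, train)
            if blk["relu"] is not None:
                h = blk["relu"].forward(h, train)
        return h[..., 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = np.asarray(grad_out, dtype=self.dtype)[..., None]
        for blk in reversed(self.decoder):
            if blk["relu"] is not None:
                g = blk["relu"].backward(g)
            g = blk["conv"].backward(g)
        for blk in reversed(self.lstms):
            g = blk["drop"].backward(g)
            g = blk["bilstm"].backward(g)
        g = self.attention.backward(g)
        for blk in reversed(self.conv_blocks):
            g = blk["drop"].backward(g)
            g = blk["bn"].backward(g)
            g = blk["relu"].backward(g)
            g = blk["conv"].backward(g)
        self.embed.backward(g)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.parameters()]
        for blk in self.conv_blocks:
            arrs += [blk["bn"].running_mean, blk["bn"].running_var]
        return arrs

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, state[:len(params)]):
            p.value[...] = a
        extra = state[len(params):]
        for i, blk in enumerate(self.conv_blocks):
            blk["bn"].running_mean[...] = extra[2 * i]
            blk["bn"].running_var[...] = extra[2 * i + 1]

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: versioned config + weights + seed."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "seed": self.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.__dict__.items()},
        }
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RespNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_d = meta["config"]
        for key in ("conv_kernels", "decoder_channels", "decoder_kernels"):
            cfg_d[key] = tuple(cfg_d[key])
        if cfg_d.get("channel_weights") is not None:
            cfg_d["channel_weights"] = tuple(cfg_d["channel_weights"])
        net = cls(ModelConfig(**cfg_d), seed=meta["seed"])
        n = len([k for k in data.files if k.startswith("arr_")])
        net.set_state([data[f"arr_{i}"] for i in range(n)])
        return net


def windows_to_array(windows) -> np.ndarray:
    """Stack MultiChannelWindows (or raw T x 4 arrays) into (n, T, 4)."""
    mats = [w.values if isinstance(w, MultiChannelWindow) else np.asarray(w)
            for w in windows]
    return np.stack(mats)


class WaveformRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn style wrapper around :class:`RespNet`.

    ``fit(X, y)`` takes ``X`` of shape (n_windows, T, 4) and ``y`` of shape
    (n_windows, T); ``predict`` returns (n_windows, T) waveforms from a
    deterministic evaluation-mode forward pass.

    Fitted attributes: ``net_`` (the trained network, best-validation
    weights), ``history_`` (per-epoch train/val loss and learning rate),
    ``n_epochs_``.
    """

    def __init__(self, d_model: int = 128, conv_kernels: tuple = (7, 5, 3),
                 n_heads: int = 8, lstm_layers: int = 2, lstm_hidden: int = 64,
                 decoder_channels: tuple = (64, 32, 1),
                 decoder_kernels: tuple = (5, 3, 1), dropout: float = 0.2,
                 channel_weights: tuple | None = None, lr: float = 1e-3,
                 batch_size: int = 32, epochs: int = 100,
                 weight_decay: float = 1e-4, plateau_factor: float = 0.5,
                 plateau_patience: int = 5, val_fraction: float = 0.1,
                 random_state: int = 0, verbose: bool = False):
        self.d_model = d_model
        self.conv_kernels = conv_kernels
        self.n_heads = n_heads
        self.lstm_layers = lstm_layers
        self.lstm_hidden = lstm_hidden
        self.decoder_channels = decoder_channels
        self.decoder_kernels = decoder_kernels
        self.dropout = dropout
        self.channel_weights = channel_weights
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.verbose = verbose

    def _model_config(self) -> ModelConfig:
        return ModelConfig(d_model=self.d_model, conv_kernels=tuple(self.conv_kernels),
                           n_heads=self.n_heads, lstm_layers=self.lstm_layers,
                           lstm_hidden=self.lstm_hidden,
                           decoder_channels=tuple(self.decoder_channels),
                           decoder_kernels=tuple(self.decoder_kernels),
                           dropout=self.dropout,
                           channel_weights=(None if self.channel_weights is None
                                            else tuple(self.channel_weights)))

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[-1] != 4:
            raise ValueError("X must have shape (n_windows, T, 4)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if y is None:
            return X
        y = np.asarray(y, dtype=np.float32)
        if y.shape != X.shape[:2]:
            raise ValueError("y must have shape (n_windows, T)")
        return X, y

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with AdamW + MSE; keeps the best-validation-loss weights.

        When no explicit validation set is given, the last ``val_fraction``
        of a seeded shuffle is held out.
        """
        X, y = self._validate_xy(X, y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n = X.shape[0]
            n_val = int(round(self.val_fraction * n))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val, y_val = self._validate_xy(X_val, y_val)

        net = RespNet(self._model_config(), seed=self.random_state)
        opt = nn.AdamW(net.parameters(), lr=self.lr, weight_decay=self.weight_decay)
        sched = nn.ReduceLROnPlateau(opt, factor=self.plateau_factor,
                                     patience=self.plateau_patience)
        n = X.shape[0]
        best_val = np.inf
        best_state = net.get_state()
        history = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                opt.zero_grad()
                pred = net.forward(xb, train=True)
                err = pred - yb
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; aborting")
                net.backward(2.0 * err / err.size)
                opt.step()
                epoch_loss += loss * len(idx)
            train_loss = epoch_loss / n
            val_loss = self._loss(net, X_val, y_val) if len(X_val) else train_loss
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "lr": opt.lr})
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.get_state()
            sched.step(val_loss)
            if self.verbose:
                print(f"epoch {epoch:3d} train {train_loss:.5f} val {val_loss:.5f} "
                      f"lr {opt.lr:.2e}")
        net.set_state(best_state)
        self.net_ = net
        self.best_val_loss_ = best_val
        self.n_epochs_ = self.epochs
        import pandas as pd

        self.history_ = pd.DataFrame(history)
        return self

    @staticmethod
    def _loss(net: RespNet, X, y, batch: int = 64) -> float:
        total, count = 0.0, 0
        for s in range(0, len(X), batch):
            pred = net.forward(X[s:s + batch])
            total += float(np.sum((pred - y[s:s + batch]) ** 2))
            count += pred.size
        return total / max(count, 1)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X = self._validate_xy(X)
        out = []
        for s in range(0, len(X), 64):
            out.append(self.net_.forward(X[s:s + 64]))
        return np.concatenate(out) if out else np.empty((0, 0))

    def save(self, path) -> None:
        self.net_.save(path)


def subject_kfold_split(subject_ids, k: int = 5, seed: int = 0,
                        val_fraction: float = 0.1) -> list[dict]:
    """Subject-exclusive k-fold assignments.

    Each subject lands in exactly one test fold; within a fold the remaining
    subjects are split into train/validation by count (validation gets
    ``round(val_fraction * n_subjects)``). Deterministic for a fixed seed.
    """
    subjects = list(subject_ids)
    n = len(subjects)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(n)]
    folds = [order[i::k] for i in range(k)]
    out = []
    n_val = int(round(val_fraction * n))
    for i, test in enumerate(folds):
        rest = [s for j, f in enumerate(folds) if j != i for s in f]
        out.append({"test": sorted(test), "val": sorted(rest[:n_val]),
                    "train": sorted(rest[n_val:])})
    return out


def stitch_windows(predictions: np.ndarray, starts, length: int) -> np.ndarray:
    """Average overlapping window predictions into one full-length waveform."""
    predictions = np.asarray(predictions, dtype=float)
    acc = np.zeros(length)
    cnt = np.zeros(length)
    for pred, s in zip(predictions, starts):
        acc[s:s + len(pred)] += pred
        cnt[s:s + len(pred)] += 1
    if np.any(cnt == 0):
        raise ValueError("windows do not cover the full signal length")
    return acc / cnt
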