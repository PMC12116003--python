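"""Recurrent sequence regressors (LSTM / BiLSTM / GRU) for VO2 prediction.

A compact NumPy implementation of the three recurrent architectures with
full backpropagation, Adam, dropout, and early stopping.  The layer stack
mirrors the deployed armband model:

    [samples, timestamps, features]
        -> recurrent x n_recurrent_layers (bidirectional variants run a
           forward and a backward pass and concatenate their outputs)
        -> dropout -> dense (ReLU) -> dropout -> linear scalar output

Weight conventions (so parameter-count oracles are unambiguous):

* LSTM — gates ordered i, f, g, o; one combined bias, forget-gate slice
  initialised to 1; parameter count ``4(dh + h² + h)`` per direction.
* GRU — gates ordered z, r, n with the reset gate applied *before* the
  candidate's recurrent matmul (``n = tanh(x Wn + (r∘h) Un + bn)``) and one
  combined bias; parameter count ``3(dh + h² + h)`` per direction.
* Input and recurrent kernels are Glorot-uniform; dense layers likewise.

Training minimises MSE with Adam; validation loss is monitored every epoch
and the weights from the best validation epoch are restored at the end.
All randomness (init, shuffling, dropout) flows from one seed, so training
is bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ModelConfig",
    "RecurrentVO2Regressor",
    "reshape_for_sequence",
    "rnn_layer_param_count",
    "build_model",
    "train",
    "predict",
    "grid_search",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters.

    Defaults are the desk-scale profile (units 32, dense 32) used throughout
    the test suite; ``full_profile`` selects the full-width deployment
    profile (1024-unit recurrent and dense layers).
    """

    arch: str = "bilstm"  # lstm | bilstm | gru
    recurrent_units: int = 32
    n_recurrent_layers: int = 2
    dropout: float = 0.3
    dense_units: int = 32
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seq_len: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("lstm", "bilstm", "gru"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.seq_len < 1 or self.max_epochs < 1:
            raise ValueError("seq_len and max_epochs must be >= 1")

    @classmethod
    def full_profile(cls, **overrides) -> "ModelConfig":
        kw = dict(recurrent_units=1024, dense_units=1024)
        kw.update(overrides)
        return cls(**kw)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# Layers


class _LSTMDirection:
    """One direction of an LSTM layer over a (B, T, d) input."""

    gates = 4

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.W = _glorot(rng, d, 4 * h)
        self.U = _glorot(rng, h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray):
        B, T, _ = X.shape
        h = self.h
        H = np.zeros((B, T, h))
        cache = []
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        for t in range(T):
            x = X[:, t, :]
            z = x @ self.W + h_t @ self.U + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x, h_t, c_t, i, f, g, o, c_new, tanh_c))
            h_t, c_t = h_new, c_new
            H[:, t, :] = h_new
        return H, cache

    def backward(self, dH: np.ndarray, cache) -> tuple[np.ndarray, list[np.ndarray]]:
        B, T, _ = dH.shape
        h = self.h
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros((B, T, self.d))
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tanh_c = cache[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += x.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dX, [dW, dU, db]


class _GRUDirection:
    """One direction of a GRU layer (reset-before, single combined bias)."""

    gates = 3

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.W = _glorot(rng, d, 3 * h)
        self.U = _glorot(rng, h, 3 * h)
        self.b = np.zeros(3 * h)

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray):
        B, T, _ = X.shape
        h = self.h
        H = np.zeros((B, T, h))
        cache = []
        h_t = np.zeros((B, h))
        for t in range(T):
            x = X[:, t, :]
            xz = x @ self.W + self.b
            hz = h_t @ self.U
            z = _sigmoid(xz[:, :h] + hz[:, :h])
            r = _sigmoid(xz[:, h : 2 * h] + hz[:, h : 2 * h])
            rh = r * h_t
            n = np.tanh(xz[:, 2 * h :] + rh @ self.U[:, 2 * h :])
            h_new = (1.0 - z) * n + z * h_t
            cache.append((x, h_t, z, r, rh, n))
            h_t = h_new
            H[:, t, :] = h_new
        return H, cache

    def backward(self, dH: np.ndarray, cache) -> tuple[np.ndarray, list[np.ndarray]]:
        B, T, _ = dH.shape
        h = self.h
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros((B, T, self.d))
        dh_next = np.zeros((B, h))
        Un = self.U[:, 2 * h :]
        for t in range(T - 1, -1, -1):
            x, h_prev, z, r, rh, n = cache[t]
            dh = dH[:, t, :] + dh_next
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dnn = dn * (1.0 - n**2)
            dU[:, 2 * h :] += rh.T @ dnn
            drh = dnn @ Un.T
            dr = drh * h_prev
            dh_prev += drh * r
            dzz = dz * z * (1 - z)
            drr = dr * r * (1 - r)
            dgates = np.concatenate([dzz, drr, dnn], axis=1)
            dW += x.T @ dgates
            db += dgates.sum(axis=0)
            dU[:, : 2 * h] += h_prev.T @ dgates[:, : 2 * h]
            dh_prev += dgates[:, : 2 * h] @ self.U[:, : 2 * h].T
            dX[:, t, :] = dgates @ self.W.T
            dh_next = dh_prev
        return dX, [dW, dU, db]


class _Recurrent:
    """A (possibly bidirectional) recurrent layer returning full sequences."""

    def __init__(self, cell: str, d: int, h: int, bidirectional: bool, rng):
        Direction = _LSTMDirection if cell == "lstm" else _GRUDirection
        self.bidirectional = bidirectional
        self.fwd = Direction(d, h, rng)
        self.bwd = Direction(d, h, rng) if bidirectional else None
        self.out_dim = h * (2 if bidirectional else 1)

    def params(self):
        p = self.fwd.params()
        if self.bwd is not None:
            p = p + self.bwd.params()
        return p

    def forward(self, X):
        Hf, cf = self.fwd.forward(X)
        if self.bwd is None:
            return Hf, (cf, None)
        Hb, cb = self.bwd.forward(X[:, ::-1, :])
        return np.concatenate([Hf, Hb[:, ::-1, :]], axis=2), (cf, cb)

    def backward(self, dH, cache):
        cf, cb = cache
        h = self.fwd.h
        dXf, gf = self.fwd.backward(dH[:, :, :h], cf)
        if self.bwd is None:
            return dXf, gf
        dXb, gb = self.bwd.backward(dH[:, ::-1, h:], cb)
        return dXf + dXb[:, ::-1, :], gf + gb


class _Dense:
    def __init__(self, d: int, m: int, rng, relu: bool):
        self.W = _glorot(rng, d, m)
        self.b = np.zeros(m)
        self.relu = relu

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        z = x @ self.W + self.b
        if self.relu:
            return np.maximum(z, 0.0), (x, z)
        return z, (x, z)

    def backward(self, dy, cache):
        x, z = cache
        if self.relu:
            dy = dy * (z > 0)
        return dy @ self.W.T, [x.T @ dy, dy.sum(axis=0)]


class _Network:
    """Recurrent stack -> last time step -> dropout -> dense -> dropout -> linear."""

    def __init__(self, config: ModelConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        cell = "gru" if config.arch == "gru" else "lstm"
        bidir = config.arch == "bilstm"
        self.recurrent = []
        d = n_features
        for _ in range(config.n_recurrent_layers):
            layer = _Recurrent(cell, d, config.recurrent_units, bidir, rng)
            self.recurrent.append(layer)
            d = layer.out_dim
        self.dense = _Dense(d, config.dense_units, rng, relu=True)
        self.head = _Dense(config.dense_units, 1, rng, relu=False)

    def layers(self):
        return [*self.recurrent, self.dense, self.head]

    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, X, dropout_rng=None):
        """X (B, T, d) -> predictions (B,).  Dropout active iff rng given."""
        caches = []
        H = X
        for layer in self.recurrent:
            H, c = layer.forward(H)
            caches.append(c)
        last = H[:, -1, :]
        last, mask1 = self._dropout(last, dropout_rng)
        hid, cd = self.dense.forward(last)
        hid, mask2 = self._dropout(hid, dropout_rng)
        out, ch = self.head.forward(hid)
        cache = (caches, mask1, cd, mask2, ch, X.shape)
        return out[:, 0], cache

    def _dropout(self, x, rng):
        p = self.config.dropout
        if rng is None or p == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * mask, mask

    def backward(self, dout, cache) -> list[np.ndarray]:
        caches, mask1, cd, mask2, ch, xshape = cache
        grads_rev = []
        dhid, gh = self.head.backward(dout[:, None], ch)
        grads_rev.append(gh)
        if mask2 is not None:
            dhid = dhid * mask2
        dlast, gd = self.dense.backward(dhid, cd)
        grads_rev.append(gd)
        if mask1 is not None:
            dlast = dlast * mask1
        B, T, _ = xshape
        dH = np.zeros((B, T, self.recurrent[-1].out_dim))
        dH[:, -1, :] = dlast
        for layer, c in zip(reversed(self.recurrent), reversed(caches)):
            dH, g = layer.backward(dH, c)
            grads_rev.append(g)
        grads: list[np.ndarray] = []
        for g in reversed(grads_rev):
            grads.extend(g)
        return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def rnn_layer_param_count(arch: str, d: int, h: int) -> int:
    """Weights in one recurrent layer: gates × (dh + h² + h), ×2 if bidirectional."""
    gates = 3 if arch == "gru" else 4
    per_direction = gates * (d * h + h * h + h)
    return per_direction * (2 if arch == "bilstm" else 1)


# ---------------------------------------------------------------------------
# Estimator


class RecurrentVO2Regressor(RegressorMixin, BaseEstimator):
    """Sklearn-style recurrent regressor mapping feature rows to 1 Hz VO2.

    ``fit`` accepts 2-D input ``(samples, features)`` — treated as length-1
    sequences — or 3-D ``(samples, timestamps, features)`` built by
    :func:`reshape_for_sequence`.  The chronologically last ``val_fraction``
    of samples (per group when ``groups`` is given) is held out to drive
    early stopping; the weights from the best validation epoch are restored.

    Attributes (after fit)
    ----------------------
    net_ : internal network with fitted weights
    history_ : DataFrame with per-epoch ``train_mse`` and ``val_mse``
    best_epoch_ : 0-based epoch whose weights were kept
    n_features_in_ : feature dimensionality
    """

    def __init__(
        self,
        arch: str = "bilstm",
        recurrent_units: int = 32,
        n_recurrent_layers: int = 2,
        dropout: float = 0.3,
        dense_units: int = 32,
        learning_rate: float = 0.001,
        batch_size: int = 64,
        max_epochs: int = 100,
        patience: int = 10,
        val_fraction: float = 0.1,
        seq_len: int = 1,
        seed: int = 0,
    ):
        self.arch = arch
        self.recurrent_units = recurrent_units
        self.n_recurrent_layers = n_recurrent_layers
        self.dropout = dropout
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seq_len = seq_len
        self.seed = seed

    # -- plumbing

    def _config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k) for k in ModelConfig.__dataclass_fields__})

    def _as_3d(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 2:
            return X[:, None, :]
        if X.ndim == 3:
            return X
        raise ValueError(f"X must be 2-D or 3-D, got shape {X.shape}")

    # -- API

    def fit(self, X, y, groups=None):
        config = self._config()
        X3 = self._as_3d(X)
        y = np.asarray(y, float).ravel()
        if X3.shape[0] != len(y):
            raise ValueError("X and y sample counts differ")
        if not 0.0 < config.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        train_idx, val_idx = _chronological_split(len(y), config.val_fraction, groups)
        Xtr, ytr = X3[train_idx], y[train_idx]
        Xval, yval = X3[val_idx], y[val_idx]

        # optimise on a standardised target so the output layer starts on
        # scale; losses are recorded and predictions returned on the raw
        # mL·kg⁻¹·min⁻¹ scale
        self._y_center = float(ytr.mean())
        scale = float(ytr.std())
        self._y_scale = scale if scale > 0 else 1.0
        ytr = (ytr - self._y_center) / self._y_scale
        yval = (yval - self._y_center) / self._y_scale

        net = _Network(config, X3.shape[2])
        opt = _Adam(net.params(), config.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        best_val = np.inf
        best_epoch = -1
        best_weights = None
        bad_epochs = 0
        history = []
        n = len(ytr)
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                yhat, cache = net.forward(Xtr[idx], dropout_rng=rng)
                err = yhat - ytr[idx]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {epoch}; reduce the "
                        "learning rate or check the inputs"
                    )
                losses.append(loss)
                grads = net.backward(2.0 * err / len(idx), cache)
                opt.step(grads)
            val_pred, _ = net.forward(Xval)
            val_mse = float(np.mean((val_pred - yval) ** 2))
            raw = self._y_scale**2
            history.append((float(np.mean(losses)) * raw, val_mse * raw))
            if val_mse * raw < best_val - 1e-12:
                best_val = val_mse * raw
                best_epoch = epoch
                best_weights = [p.copy() for p in net.params()]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    break
        if best_weights is not None:
            for p, bw in zip(net.params(), best_weights):
                p[...] = bw
        self.net_ = net
        self.history_ = pd.DataFrame(history, columns=["train_mse", "val_mse"])
        self.history_.insert(0, "epoch", np.arange(len(history)))
        self.best_epoch_ = best_epoch
        self.n_features_in_ = X3.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted")
        X3 = self._as_3d(X)
        if X3.shape[2] != self.n_features_in_:
            raise ValueError(
                f"X has {X3.shape[2]} features, model expects {self.n_features_in_}"
            )
        # inference is deterministic: dropout disabled
        out = np.empty(X3.shape[0])
        step = max(self.batch_size * 8, 256)
        for lo in range(0, X3.shape[0], step):
            out[lo : lo + step] = self.net_.forward(X3[lo : lo + step])[0]
        return out * getattr(self, "_y_scale", 1.0) + getattr(self, "_y_center", 0.0)

    def n_params(self) -> int:
        if hasattr(self, "net_"):
            return self.net_.n_params()
        return _Network(self._config(), 1).n_params()


def _chronological_split(n: int, val_fraction: float, groups):
    """Last val_fraction of rows (per group if given) become validation."""
    if groups is None:
        n_val = max(1, int(round(n * val_fraction)))
        idx = np.arange(n)
        return idx[: n - n_val], idx[n - n_val :]
    groups = np.asarray(groups)
    train_idx, val_idx = [], []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        train_idx.append(idx[: len(idx) - n_val])
        val_idx.append(idx[len(idx) - n_val :])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def reshape_for_sequence(
    X, y, subject_ids, seq_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack rows into non-overlapping ``[samples, timestamps, features]`` blocks.

    Rows must be time-ordered within each subject.  Each sample is
    ``seq_len`` consecutive rows of one subject; the target is the last
    row's VO2.  Sequences never span subjects; each subject contributes
    ``floor(rows / seq_len)`` samples.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    subject_ids = np.asarray(subject_ids)
    xs, ys, sids = [], [], []
    for sid in pd.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == sid)
        if seq_len > len(idx):
            raise ValueError(
                f"seq_len {seq_len} exceeds subject {sid!r}'s {len(idx)} rows"
            )
        m = len(idx) // seq_len
        keep = idx[: m * seq_len]
        xs.append(X[keep].reshape(m, seq_len, X.shape[1]))
        ys.append(y[keep].reshape(m, seq_len)[:, -1])
        sids.extend([sid] * m)
    return np.concatenate(xs), np.concatenate(ys), np.asarray(sids)


# ---------------------------------------------------------------------------
# Thin functional wrappers and checkpointing


def build_model(config: ModelConfig, n_features: int) -> RecurrentVO2Regressor:
    """An untrained regressor with the given architecture (weights initialised)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    est = RecurrentVO2Regressor(**asdict(config))
    est.net_ = _Network(config, n_features)
    est.n_features_in_ = n_features
    est.history_ = pd.DataFrame(columns=["epoch", "train_mse", "val_mse"])
    est.best_epoch_ = -1
    return est


def train(model: RecurrentVO2Regressor, X, y, groups=None) -> RecurrentVO2Regressor:
    return model.fit(X, y, groups=groups)


def predict(model: RecurrentVO2Regressor, X) -> np.ndarray:
    return model.predict(X)


def grid_search(
    configs: list[ModelConfig], X, y, groups=None
) -> tuple[RecurrentVO2Regressor, pd.DataFrame]:
    """Small exhaustive hyperparameter search (<= 8 candidate configs).

    Each candidate is trained with its own early-stopping validation split;
    the model with the lowest best-epoch validation MSE wins.  Returns the
    winning fitted model and a per-candidate summary frame.
    """
    if not 1 <= len(configs) <= 8:
        raise ValueError("grid_search takes between 1 and 8 candidate configs")
    rows = []
    best = None
    best_val = np.inf
    for i, cfg in enumerate(configs):
        model = RecurrentVO2Regressor(**asdict(cfg))
        model.fit(X, y, groups=groups)
        val = float(model.history_["val_mse"].iloc[model.best_epoch_])
        rows.append(
            {"candidate": i, "arch": cfg.arch, "recurrent_units": cfg.recurrent_units,
             "seq_len": cfg.seq_len, "best_epoch": model.best_epoch_, "val_mse": val}
        )
        if val < best_val:
            best_val = val
            best = model
    return best, pd.DataFrame(rows)


def save_model(model: RecurrentVO2Regressor, outdir: str | Path) -> Path:
    """Checkpoint: key-value config, npz weights, history CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.txt", "w") as fh:
        for k, v in model.get_params().items():
            fh.write(f"{k} {v}\n")
        fh.write(f"n_features {model.n_features_in_}\n")
        fh.write(f"y_center {getattr(model, '_y_center', 0.0)!r}\n")
        fh.write(f"y_scale {getattr(model, '_y_scale', 1.0)!r}\n")
    np.savez(outdir / "weights.npz", *model.net_.params())
    model.history_.to_csv(outdir / "history.csv", index=False)
    return outdir


def load_model(indir: str | Path) -> RecurrentVO2Regressor:
    indir = Path(indir)
    raw = {}
    with open(indir / "config.txt") as fh:
        for line in fh:
            k, v = line.split(None, 1)
            raw[k] = v.strip()
    n_features = int(raw.pop("n_features"))
    y_center = float(raw.pop("y_center", 0.0))
    y_scale = float(raw.pop("y_scale", 1.0))
    kwargs = {}
    for k, v in raw.items():
        if k == "arch":
            kwargs[k] = v
        elif k in ("dropout", "learning_rate", "val_fraction"):
            kwargs[k] = float(v)
        else:
            kwargs[k] = int(v)
    model = build_model(ModelConfig(**kwargs), n_features)
    model._y_center = y_center
    model._y_scale = y_scale
    with np.load(indir / "weights.npz") as data:
        keys = sorted(data.files, key=lambda s: int(s.split("_")[1]))
        for p, key in zip(model.net_.params(), keys):
            p[...] = data[key]
    model.history_ = pd.read_csv(indir / "history.csv")
    return model
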