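"""Multi-branch 1-D convolutional classifier, implemented in numpy.

One convolutional branch per enabled feature block (S = sequence L x 4,
F = structure L x 3, C = conservation L x 1), each built from three
conv/relu/max-pool stages.  Branch outputs are flattened, concatenated and
fed to a dense head ending in a single logistic unit.

The network is small enough that a hand-rolled numpy implementation (im2col
convolutions, Adam, weighted binary cross-entropy) trains in seconds on one
CPU, keeps the package free of deep-learning framework dependencies, and is
bit-for-bit reproducible given a seed.
"""
from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodedWindow

log = logging.getLogger(__name__)

BRANCH_CHANNELS = {"S": 4, "F": 3, "C": 1}
_FORMAT_VERSION = 1

__all__ = [
    "ModelConfig",
    "Model",
    "ConfigError",
    "ShapeError",
    "NotTrainedError",
    "ModelIOError",
    "build_model",
    "class_weights",
    "train",
    "predict",
    "save_model",
    "load_model",
    "read_model_config",
    "stack_blocks",
]


class ConfigError(ValueError):
    pass


class ShapeError(ValueError):
    pass


class NotTrainedError(RuntimeError):
    pass


class ModelIOError(IOError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one classifier.

    ``branches`` selects the feature blocks; every enabled branch gets three
    convolutional stages with ``conv_filters`` output channels, shared
    ``kernel`` size (odd, "same" padding) and ``pool`` max-pooling.
    """

    branches: tuple[str, ...] = ("S", "F", "C")
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 5
    pool: int = 2
    dense_units: tuple[int, ...] = (64,)
    class_weighting: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 20
    patience: int = 5
    input_length: int = 100
    seed: int = 0

    def __post_init__(self):
        branches = tuple(self.branches)
        if not branches:
            raise ConfigError("at least one branch must be enabled")
        for b in branches:
            if b not in BRANCH_CHANNELS:
                raise ConfigError(f"unknown branch {b!r}")
        if len(set(branches)) != len(branches):
            raise ConfigError("duplicate branch")
        if len(self.conv_filters) != 3:
            raise ConfigError("exactly 3 convolutional layers per branch")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ConfigError("kernel must be a positive odd integer")
        object.__setattr__(self, "branches", branches)
        object.__setattr__(self, "conv_filters", tuple(self.conv_filters))
        object.__setattr__(self, "dense_units", tuple(self.dense_units))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for k in ("branches", "conv_filters", "dense_units"):
            d[k] = tuple(d[k])
        return cls(**d)


# -- numpy layers ------------------------------------------------------------


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-D convolution.  x: (N, L, Cin), W: (k, Cin, F)."""
    k = W.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    # (N, L, Cin, k) -> (N, L, k, Cin) -> (N, L, k*Cin)
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1], k * x.shape[2]
    )
    y = cols @ W.reshape(k * x.shape[2], -1) + b
    return y, cols


def _conv1d_backward(dy: np.ndarray, cols: np.ndarray, W: np.ndarray, x_shape):
    N, L, Cin = x_shape
    k, F = W.shape[0], W.shape[2]
    Wmat = W.reshape(k * Cin, F)
    dW = np.tensordot(cols, dy, axes=([0, 1], [0, 1])).reshape(W.shape)
    db = dy.sum(axis=(0, 1))
    dcols = (dy @ Wmat.T).reshape(N, L, k, Cin)
    pad = k // 2
    dxp = np.zeros((N, L + 2 * pad, Cin), dtype=dy.dtype)
    for t in range(k):
        dxp[:, t : t + L, :] += dcols[:, :, t, :]
    return dxp[:, pad : pad + L, :], dW, db


def _maxpool_forward(x: np.ndarray, p: int, need_idx: bool = True):
    N, L, C = x.shape
    Lp = L // p
    xt = x[:, : Lp * p, :].reshape(N, Lp, p, C)
    if not need_idx:  # inference path: argmax indices are only for backprop
        return xt.max(axis=2), None
    idx = xt.argmax(axis=2)
    out = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (idx, x.shape)


def _maxpool_backward(dy: np.ndarray, cache, p: int):
    idx, x_shape = cache
    N, L, C = x_shape
    Lp = L // p
    dxt = np.zeros((N, Lp, p, C), dtype=dy.dtype)
    np.put_along_axis(dxt, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, : Lp * p, :] = dxt.reshape(N, Lp * p, C)
    return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Model:
    """Parameter store + forward/backward passes for one ModelConfig."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.trained = False
        self.history: list[dict] = []
        self._init_params()

    # parameter names: {branch}_conv{i}_{W,b}, dense{i}_{W,b}, out_{W,b}
    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        flat_total = 0
        for br in cfg.branches:
            cin = BRANCH_CHANNELS[br]
            L = cfg.input_length
            for i, f in enumerate(cfg.conv_filters):
                fan_in = cfg.kernel * cin
                self.params[f"{br}_conv{i}_W"] = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), (cfg.kernel, cin, f)
                )
                self.params[f"{br}_conv{i}_b"] = np.zeros(f)
                cin = f
                L = L // cfg.pool
            flat_total += L * cfg.conv_filters[-1]
        units_in = flat_total
        for i, u in enumerate(cfg.dense_units):
            self.params[f"dense{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / units_in), (units_in, u)
            )
            self.params[f"dense{i}_b"] = np.zeros(u)
            units_in = u
        self.params["out_W"] = rng.normal(0.0, np.sqrt(1.0 / units_in), (units_in, 1))
        self.params["out_b"] = np.zeros(1)

    def forward(self, xs: Sequence[np.ndarray], want_cache: bool = False):
        cfg = self.config
        if len(xs) != len(cfg.branches):
            raise ShapeError(
                f"model expects {len(cfg.branches)} input blocks, got {len(xs)}"
            )
        cache = {"branches": []}
        flats = []
        for br, x in zip(cfg.branches, xs):
            if x.ndim != 3 or x.shape[2] != BRANCH_CHANNELS[br]:
                raise ShapeError(
                    f"branch {br} expects (N, L, {BRANCH_CHANNELS[br]}) input, "
                    f"got {x.shape}"
                )
            h = x.astype(np.float64, copy=False)
            stages = []
            for i in range(3):
                z, cols = _conv1d_forward(
                    h, self.params[f"{br}_conv{i}_W"], self.params[f"{br}_conv{i}_b"]
                )
                a = np.maximum(z, 0.0)
                pooled, pc = _maxpool_forward(a, cfg.pool, need_idx=want_cache)
                stages.append((cols, z, h.shape, pc) if want_cache else None)
                h = pooled
            cache["branches"].append((stages, h.shape))
            flats.append(h.reshape(h.shape[0], -1))
        concat = np.concatenate(flats, axis=1) if len(flats) > 1 else flats[0]
        cache["flat_widths"] = [f.shape[1] for f in flats]
        h = concat
        dense = []
        for i in range(len(cfg.dense_units)):
            z = h @ self.params[f"dense{i}_W"] + self.params[f"dense{i}_b"]
            a = np.maximum(z, 0.0)
            dense.append((h, z))
            h = a
        zo = h @ self.params["out_W"] + self.params["out_b"]
        p = _sigmoid(zo)[:, 0]
        if not want_cache:
            return p
        cache["dense"] = dense
        cache["head_in"] = h
        return p, cache

    def backward(self, cache, dzo: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients given d(loss)/d(pre-sigmoid output), shape (N, 1)."""
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        grads["out_W"] = cache["head_in"].T @ dzo
        grads["out_b"] = dzo.sum(axis=0)
        dh = dzo @ self.params["out_W"].T
        for i in range(len(cfg.dense_units) - 1, -1, -1):
            h_in, z = cache["dense"][i]
            dz = dh * (z > 0)
            grads[f"dense{i}_W"] = h_in.T @ dz
            grads[f"dense{i}_b"] = dz.sum(axis=0)
            dh = dz @ self.params[f"dense{i}_W"].T
        offset = 0
        for br, width, (stages, out_shape) in zip(
            cfg.branches, cache["flat_widths"], cache["branches"]
        ):
            dflat = dh[:, offset : offset + width]
            offset += width
            d = dflat.reshape(out_shape)
            for i in range(2, -1, -1):
                cols, z, x_shape, pc = stages[i]
                da = _maxpool_backward(d, pc, cfg.pool)
                dz = da * (z > 0)
                dxi, dW, db = _conv1d_backward(
                    dz, cols, self.params[f"{br}_conv{i}_W"], x_shape
                )
                grads[f"{br}_conv{i}_W"] = dW
                grads[f"{br}_conv{i}_b"] = db
                d = dxi
        return grads


def build_model(config: ModelConfig) -> Model:
    """Fresh, untrained model with seeded weight initialization."""
    return Model(config)


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Inverse-frequency class weights: ``w_c = N_total / (2 * N_c)``."""
    labels = list(labels)
    n1 = sum(1 for y in labels if y == 1)
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    total = n0 + n1
    return {0: total / (2.0 * n0), 1: total / (2.0 * n1)}


def stack_blocks(
    examples: Sequence[EncodedWindow], branches: Sequence[str]
) -> list[np.ndarray]:
    """Stack per-window blocks into one (N, L, C) array per enabled branch."""
    attr = {"S": "seq_block", "F": "struct_block", "C": "cons_block"}
    out = []
    for br in branches:
        blocks = [getattr(w, attr[br]) for w in examples]
        if any(b is None for b in blocks):
            raise ShapeError(f"branch {br} enabled but some windows lack that block")
        out.append(np.stack(blocks))
    return out


def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    return float(np.mean(w * -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))


def train(
    model: Model,
    examples: Sequence[EncodedWindow],
    val_examples: Sequence[EncodedWindow] | None = None,
    config: ModelConfig | None = None,
) -> Model:
    """Train in place with Adam on (optionally class-weighted) binary
    cross-entropy; returns the same model.

    With validation examples and ``patience >= 1``, training stops early on
    stalled validation loss and the best-validation weights are restored.
    History records one dict per completed epoch.
    """
    cfg = config or model.config
    if not examples:
        raise ValueError("no training examples")
    labels = [w.label for w in examples]
    if any(y not in (0, 1) for y in labels):
        raise ValueError("every training example needs a 0/1 label")
    y = np.array(labels, dtype=np.float64)
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    xs = stack_blocks(examples, cfg.branches)
    cw = class_weights(labels) if cfg.class_weighting else {0: 1.0, 1: 1.0}
    w = np.where(y == 1, cw[1], cw[0])

    val = None
    if val_examples:
        yv = np.array([e.label for e in val_examples], dtype=np.float64)
        val = (stack_blocks(val_examples, cfg.branches), yv)

    rng = np.random.default_rng(cfg.seed + 1)
    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v2 = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = np.inf
    best_params = None
    stale = 0
    model.history = []
    n = len(examples)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            xb = [x[idx] for x in xs]
            yb, wb = y[idx], w[idx]
            p, cache = model.forward(xb, want_cache=True)
            loss = _weighted_bce(p, yb, wb)
            dzo = (wb * (p - yb) / len(idx))[:, None]
            grads = model.backward(cache, dzo)
            t += 1
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v2[k] = b2 * v2[k] + (1 - b2) * g * g
                mh = m[k] / (1 - b1**t)
                vh = v2[k] / (1 - b2**t)
                model.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if val is not None:
            pv = model.forward(val[0])
            record["val_loss"] = _weighted_bce(pv, val[1], np.ones_like(val[1]))
            record["val_acc"] = float(np.mean((pv >= 0.5) == val[1]))
        model.history.append(record)
        if val is not None and cfg.patience >= 1:
            if record["val_loss"] < best_val - 1e-6:
                best_val = record["val_loss"]
                best_params = {k: p.copy() for k, p in model.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    log.info("early stop at epoch %d (patience %d)", epoch, cfg.patience)
                    break
    if best_params is not None:
        model.params = best_params
    model.trained = True
    return model


def predict(
    model: Model,
    windows: Sequence[EncodedWindow] | Sequence[np.ndarray],
    batch_size: int = 512,
) -> np.ndarray:
    """Scores in [0, 1], one per window, order preserved; deterministic."""
    if not model.trained:
        raise NotTrainedError("model has not been trained")
    if len(windows) == 0:
        return np.zeros(0)
    if isinstance(windows[0], EncodedWindow):
        xs = stack_blocks(windows, model.config.branches)  # type: ignore[arg-type]
    else:
        xs = list(windows)  # pre-stacked arrays
    n = xs[0].shape[0]
    out = np.empty(n)
    for lo in range(0, n, batch_size):
        out[lo : lo + batch_size] = model.forward([x[lo : lo + batch_size] for x in xs])
    return out


def write_history_tsv(model: Model, path: str | Path) -> None:
    cols = ["epoch", "train_loss", "val_loss", "val_acc"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in model.history:
            fh.write("\t".join(str(rec.get(c, "")) for c in cols) + "\n")


# -- serialization -----------------------------------------------------------


def save_model(model: Model, path: str | Path) -> None:
    """Single-file checkpoint: config JSON + weights (npz archive)."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": json.loads(model.config.to_json()),
        "trained": model.trained,
        "history": model.history,
    }
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    with open(path, "wb") as fh:  # np.savez would append ".npz" to a bare path
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def _read_meta(archive) -> dict:
    if "__meta__" not in archive:
        raise ModelIOError("not a model checkpoint (missing metadata)")
    return json.loads(bytes(archive["__meta__"]).decode())


def read_model_config(path: str | Path) -> ModelConfig:
    """Retrieve the embedded ModelConfig without materializing weights."""
    try:
        with np.load(path) as archive:
            meta = _read_meta(archive)
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    return ModelConfig.from_json(json.dumps(meta["config"]))


def load_model(path: str | Path) -> Model:
    try:
        with np.load(path) as archive:
            meta = _read_meta(archive)
            if meta.get("format_version") != _FORMAT_VERSION:
                raise ModelIOError(
                    f"unsupported checkpoint version {meta.get('format_version')!r}"
                )
            config = ModelConfig.from_json(json.dumps(meta["config"]))
            model = Model(config)
            expected = set(model.params)
            stored = {k[len("param::"):] for k in archive.files if k.startswith("param::")}
            if stored != expected:
                raise ModelIOError(
                    f"checkpoint parameters do not match config: "
                    f"missing {sorted(expected - stored)}, extra {sorted(stored - expected)}"
                )
            for k in expected:
                arr = archive[f"param::{k}"]
                if arr.shape != model.params[k].shape:
                    raise ModelIOError(f"shape mismatch for parameter {k}")
                model.params[k] = arr
    except ModelIOError:
        raise
    except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile) as exc:
        raise ModelIOError(f"cannot load model file {path}: {exc}") from exc
    model.trained = bool(meta.get("trained", True))
    model.history = meta.get("history", [])
    return model
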