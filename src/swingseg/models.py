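"""The two learned segmentation models and their training protocol.

* BLSTM method: five bidirectional LSTM layers (32 hidden units each), a
  shared per-timestep fully connected layer and a softmax output assigning
  one of the five phase classes to every time sample; dividing points are
  recovered where the (cleaned) class sequence changes.
* CNN method: two convolution blocks (convolution, tanh, max-pooling, tanh),
  a fully connected layer and a linear regression head that emits the four
  dividing points directly as window fractions.

Both train with Adam on a 90/10 swing-level train/validation split
(stratified by subject) and stop when validation loss fails to improve for
``patience`` epochs, restoring the best-validation checkpoint.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .errors import IncompletePhaseSequence, OrderViolation, TrainingDiverged
from .preprocess import WindowDataset, decode_cnn_label
from .swingdata import (
    DividingPoints,
    PhaseSequence,
    clean_phase_sequence,
    points_from_phases,
)

clean_sequence = clean_phase_sequence  # canonical post-processing entry point


@dataclass
class BlstmSpec:
    n_layers: int = 5
    hidden_units: int = 32
    n_classes: int = 5
    input_features: int = 7


@dataclass
class CnnSpec:
    kernel: int = 9
    filters: Tuple[int, int] = (16, 32)
    pool: int = 4
    fc_width: int = 64
    n_outputs: int = 4
    input_features: int = 7


@dataclass
class TrainConfig:
    lr: float = 3e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    batch_size: int = 8
    max_epochs: int = 200
    val_fraction: float = 0.10
    patience: int = 10
    lr_reduce_factor: float = 0.3  # on validation plateau (half the patience)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")


class BlstmModel(nn.Sequential):
    """(B, F, T) input -> (B, C, T) class logits."""

    def __init__(self, spec: BlstmSpec, rng: np.random.Generator):
        self.spec = spec
        H = spec.hidden_units
        mods: List[nn.Module] = []
        in_dim = spec.input_features
        for _ in range(spec.n_layers):
            mods.append(nn.BiLSTM(in_dim, H, rng))
            in_dim = 2 * H
        self.head = nn.Dense(in_dim, spec.n_classes, rng)
        super().__init__(mods + [self.head])

    def forward(self, x):
        # (B, F, T) -> time-major (T, B, F)
        tm = np.ascontiguousarray(np.transpose(x, (2, 0, 1)).astype(np.float32))
        for m in self.modules[:-1]:
            tm = m.forward(tm)
        T, B, D = tm.shape
        self._TB = (T, B, D)
        logits = self.head.forward(tm.reshape(T * B, D)).reshape(T, B, -1)
        return np.transpose(logits, (1, 2, 0))  # (B, C, T)

    def backward(self, dout):
        T, B, D = self._TB
        d = np.ascontiguousarray(np.transpose(dout, (2, 0, 1)))  # (T, B, C)
        d = self.head.backward(d.reshape(T * B, -1)).reshape(T, B, D)
        for m in reversed(self.modules[:-1]):
            d = m.backward(d)
        return d

    def predict_proba(self, x):
        """Per-timestep class probabilities, (B, C, T); columns sum to 1."""
        return nn.softmax(self.forward(x), axis=1)


class CnnModel(nn.Sequential):
    """(B, F, T) input -> (B, 4) dividing-point fractions."""

    def __init__(self, spec: CnnSpec, rng: np.random.Generator, input_len: int = 700):
        self.spec = spec
        f1, f2 = spec.filters
        t_out = (input_len // spec.pool) // spec.pool
        mods: List[nn.Module] = [
            nn.Conv1d(spec.input_features, f1, spec.kernel, rng),
            nn.Tanh(),
            nn.MaxPool1d(spec.pool),
            nn.Tanh(),
            nn.Conv1d(f1, f2, spec.kernel, rng),
            nn.Tanh(),
            nn.MaxPool1d(spec.pool),
            nn.Tanh(),
            nn.Flatten(),
            nn.Dense(f2 * t_out, spec.fc_width, rng),
            nn.Tanh(),
            nn.Dense(spec.fc_width, spec.n_outputs, rng),
        ]
        super().__init__(mods)

    def forward(self, x):
        return super().forward(np.ascontiguousarray(x, dtype=np.float32))


def build_blstm(spec: Optional[BlstmSpec] = None, seed: int = 0) -> BlstmModel:
    return BlstmModel(spec or BlstmSpec(), np.random.default_rng(seed))


def build_cnn(spec: Optional[CnnSpec] = None, seed: int = 0, input_len: int = 700) -> CnnModel:
    return CnnModel(spec or CnnSpec(), np.random.default_rng(seed), input_len)


# ---------------------------------------------------------------------------
# training


def _stratified_split(subject_ids: np.ndarray, val_fraction: float, rng):
    """90/10 swing-level split, stratified by subject (>=1 val swing per
    subject when the subject has >=2 swings)."""
    train_idx, val_idx = [], []
    for sid in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == sid)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        if idx.size >= 2:
            n_val = max(n_val, 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _batch_loss(model, X, windows: WindowDataset, idx, task: str):
    if task == "blstm":
        logits = model.forward(X)  # (B, C, T)
        labels = windows.seq_labels[idx]  # (B, T)
        loss, d = nn.cross_entropy_loss(
            np.transpose(logits, (0, 2, 1)), labels
        )
        dlogits = np.transpose(d, (0, 2, 1)).astype(np.float32)
        return loss, dlogits
    pred = model.forward(X)  # (B, 4)
    loss, d = nn.mse_loss(pred, windows.point_labels[idx])
    return loss, d.astype(np.float32)


def train_model(
    model: nn.Sequential,
    windows: WindowDataset,
    config: Optional[TrainConfig] = None,
    task: str = "cnn",
) -> Dict:
    """Train in place; returns the history dict.

    Validation loss is evaluated before training (epoch-0 baseline) and after
    every epoch; training stops once validation fails to improve for
    ``patience`` consecutive epochs and the best-validation parameters are
    restored.  Raises ``training_diverged`` on non-finite loss.
    """
    if task not in ("blstm", "cnn"):
        raise ValueError("task must be 'blstm' or 'cnn'")
    config = config or TrainConfig()
    if len(windows) < 2:
        raise ValueError("need at least 2 swings to train")
    rng = np.random.default_rng(config.seed)
    tr, va = _stratified_split(windows.subject_ids, config.val_fraction, rng)
    opt = nn.Adam(model, lr=config.lr, betas=config.betas)
    X = windows.inputs.astype(np.float32)

    def val_loss():
        loss, _ = _batch_loss(model, X[va], windows, va, task)
        return loss

    best = val_loss()
    if not np.isfinite(best):
        raise TrainingDiverged("non-finite validation loss before training")
    best_state = model.state()
    history = {"train_loss": [], "val_loss": [best], "best_epoch": 0}
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr)
        ep_losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            loss, dout = _batch_loss(model, X[idx], windows, idx, task)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite training loss at epoch {epoch}")
            model.backward(dout)
            opt.step()
            ep_losses.append(loss)
        vl = val_loss()
        if not np.isfinite(vl):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(vl)
        if vl < best - 1e-12:
            best = vl
            best_state = model.state()
            history["best_epoch"] = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
            if stale == max(1, config.patience // 2):
                # validation plateau: back to the best checkpoint, lower rate
                opt.lr *= config.lr_reduce_factor
                model.load_state(best_state)
    model.load_state(best_state)
    history["stopped_epoch"] = len(history["train_loss"])
    return history


# ---------------------------------------------------------------------------
# prediction


def predict_points(
    model: nn.Sequential,
    matrix: np.ndarray,
    t0_s: float,
    method: str,
    sample_rate_hz: float = 200.0,
    median_width: int = 5,
    min_run: int = 10,
) -> DividingPoints:
    """Dividing points from one assembled window matrix (F, T).

    blstm: per-column argmax -> sequence cleanup -> boundary extraction (the
    persistence threshold is relaxed to one sample if a phase lacks a
    persistent run, so marginal predictions still decode).  cnn: de-normalize
    the four outputs to seconds and clamp into the window; an unordered
    result raises ``order_violation`` rather than being silently fixed.
    """
    x = np.asarray(matrix, dtype=np.float32)[None]
    n = x.shape[2]
    dur = n / sample_rate_hz
    t = t0_s + np.arange(n) / sample_rate_hz
    if method == "blstm":
        logits = model.forward(x)[0]  # (C, T)
        raw = PhaseSequence(np.argmax(logits, axis=0))
        try:
            return points_from_phases(raw, t, median_width=median_width, min_run=min_run)
        except IncompletePhaseSequence:
            return points_from_phases(raw, t, median_width=median_width, min_run=1)
    if method == "cnn":
        frac = np.clip(model.forward(x)[0].astype(float), 0.0, (n - 1) / n)
        times = t0_s + frac * dur
        if not np.all(np.diff(times) > 0):
            raise OrderViolation(f"regressed points unordered: {times}")
        return decode_cnn_label(frac, t0_s, dur)
    raise ValueError("method must be 'blstm' or 'cnn'")


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model, spec, train_config, history, path) -> None:
    """Persist parameters + spec + training config in one file."""
    payload = {
        "kind": type(model).__name__,
        "spec": spec,
        "train_config": train_config,
        "history": history,
        "state": model.state(),
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    spec = payload["spec"]
    if payload["kind"] == "BlstmModel":
        model = build_blstm(spec)
    else:
        model = build_cnn(spec)
    model.load_state(payload["state"])
    return model, payload
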