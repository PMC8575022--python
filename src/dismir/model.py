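"""The per-read classifier (d-score model) and its ensemble protocol.

The network follows a DanQ-style hybrid: a 1D convolution over the L x 5
read encoding, max-pooling, a bidirectional LSTM, a second 1D convolution,
a flatten layer and three dense layers, with a sigmoid output squashing the
score into [0, 1].  The output — the d-score — is read as the probability
that the read is tumor-derived (healthy plasma = 0, tumor tissue = 1).

Because single trainings are stochastic, the standard protocol trains the
model several times (default 10) on the same data and averages the per-read
d-scores of the members; the mean is the final d-score.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoding import EncodedRead, stack_labels, stack_matrices

__all__ = [
    "ModelConfig",
    "DScoreModel",
    "EnsembleModel",
    "build_model",
    "train_model",
    "predict_dscore",
    "train_ensemble",
    "ensemble_dscore",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one ensemble member.

    Defaults are DanQ-scale values sized for a desk CPU; all are tunable.
    """

    input_length: int = 66
    conv1_filters: int = 64
    conv1_width: int = 8
    pool_width: int = 2
    lstm_units: int = 32
    conv2_filters: int = 32
    conv2_width: int = 4
    dense_units: tuple[int, int, int] = (64, 16, 1)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 20
    patience: int = 3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        positive = (
            "input_length", "conv1_filters", "conv1_width", "pool_width",
            "lstm_units", "conv2_filters", "conv2_width", "batch_size", "epochs",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dense_units[-1] != 1:
            raise ValueError("final dense layer must have width 1 (single d-score)")
        if self.conv1_width > self.input_length:
            raise ValueError("conv1_width exceeds input length")
        pooled = (self.input_length - self.conv1_width + 1) // self.pool_width
        if pooled < self.conv2_width:
            raise ValueError("conv2_width exceeds pooled sequence length")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


SMALL_CONFIG = ModelConfig(
    conv1_filters=16, lstm_units=8, conv2_filters=8,
    dense_units=(32, 8, 1), epochs=8,
)
"""Reduced profile for quick CPU runs (simulation studies, examples, tests)."""


@dataclass
class DScoreModel:
    """A built (possibly trained) network plus its configuration."""

    network: nn.Network
    cfg: ModelConfig
    rng: np.random.Generator

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(x)


@dataclass
class EnsembleModel:
    """>= 1 trained members; the final d-score is their per-read mean."""

    members: list[DScoreModel]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")


def build_model(cfg: ModelConfig = ModelConfig()) -> DScoreModel:
    """Build the conv/pool/BiLSTM/conv/flatten/3-dense network, seeded."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.input_length
    conv1_out = L - cfg.conv1_width + 1
    pooled = conv1_out // cfg.pool_width
    conv2_out = pooled - cfg.conv2_width + 1
    layers = [
        nn.Conv1D(5, cfg.conv1_filters, cfg.conv1_width, "relu", rng=rng),
        nn.MaxPool1D(cfg.pool_width),
        nn.Dropout(cfg.dropout, rng=rng),
        nn.BiLSTM(cfg.conv1_filters, cfg.lstm_units, rng=rng),
        nn.Dropout(cfg.dropout, rng=rng),
        nn.Conv1D(2 * cfg.lstm_units, cfg.conv2_filters, cfg.conv2_width,
                  "relu", rng=rng),
        nn.Flatten(),
        nn.Dense(conv2_out * cfg.conv2_filters, cfg.dense_units[0], "relu", rng=rng),
        nn.Dense(cfg.dense_units[0], cfg.dense_units[1], "relu", rng=rng),
        nn.Dense(cfg.dense_units[1], 1, None, rng=rng),  # sigmoid fused in loss
    ]
    return DScoreModel(network=nn.Network(layers), cfg=cfg, rng=rng)


def _as_arrays(train_set) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(train_set, tuple):
        x, y = train_set
        return np.asarray(x, np.float32), np.asarray(y, np.float32)
    encoded: Sequence[EncodedRead] = train_set
    return stack_matrices(encoded), stack_labels(encoded)


def train_model(model: DScoreModel, train_set) -> list[dict]:
    """Train one member with Adam on binary cross-entropy.

    ``train_set`` is either a list of labeled EncodedReads or an ``(X, y)``
    pair with X of shape (N, L, 5).  A validation split (default 10%) drives
    early stopping; the best-validation weights are restored.  Returns the
    per-epoch log (train/validation loss and accuracy).
    """
    cfg = model.cfg
    x, y = _as_arrays(train_set)
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = model.rng
    n_val = int(round(cfg.validation_fraction * len(x)))
    perm = rng.permutation(len(x))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = nn.Adam(model.network, lr=cfg.learning_rate)
    log: list[dict] = []
    best_val = np.inf
    best_weights = None
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            model.network.zero_grad()
            logits = model.network.forward(x_tr[idx], train=True)
            loss, grad = nn.bce_with_logits(logits, y_tr[idx])
            model.network.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        p_tr = model.predict(x_tr)
        entry["train_acc"] = float(np.mean((p_tr >= 0.5) == (y_tr >= 0.5)))
        if len(x_val):
            logits_val = model.network.forward(x_val, train=False)
            val_loss, _ = nn.bce_with_logits(logits_val, y_val)
            entry["val_loss"] = float(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.network.get_weights()
                stale = 0
            else:
                stale += 1
        log.append(entry)
        if len(x_val) and stale > cfg.patience:
            break
    if best_weights is not None:
        model.network.set_weights(best_weights)
    return log


def predict_dscore(model: DScoreModel, reads) -> np.ndarray:
    """d-score in [0, 1] for each encoded read, order preserved."""
    if isinstance(reads, np.ndarray):
        x = reads.astype(np.float32)
    else:
        x = stack_matrices(reads)
    if x.ndim != 3 or x.shape[1:] != (model.cfg.input_length, 5):
        raise ValueError(
            f"expected (N, {model.cfg.input_length}, 5) input, got {x.shape}"
        )
    return model.predict(x)


def train_ensemble(train_set, cfg: ModelConfig = ModelConfig(),
                   n_members: int = 10) -> tuple[EnsembleModel, list[list[dict]]]:
    """Train ``n_members`` models on the same data with seeds seed+0..n-1."""
    members, logs = [], []
    for k in range(n_members):
        member_cfg = ModelConfig(**{**asdict(cfg), "seed": cfg.seed + k})
        model = build_model(member_cfg)
        logs.append(train_model(model, train_set))
        members.append(model)
    return EnsembleModel(members=members), logs


def ensemble_dscore(ensemble: EnsembleModel, reads) -> np.ndarray:
    """Arithmetic mean of member d-scores per read — the final d-score."""
    scores = np.stack([predict_dscore(m, reads) for m in ensemble.members])
    return scores.mean(axis=0)


# ---------------------------------------------------------------------------
# Serialization: one .npz per member plus a JSON manifest
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_members": len(ensemble.members),
        "config": asdict(ensemble.members[0].cfg),
        "config_hash": ensemble.members[0].cfg.config_hash(),
        "seeds": [m.cfg.seed for m in ensemble.members],
    }
    manifest["config"]["dense_units"] = list(manifest["config"]["dense_units"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, m in enumerate(ensemble.members):
        arrays = {}
        for li, layer in enumerate(m.network.layers):
            for k, v in layer.params.items():
                arrays[f"layer{li}_{k}"] = v
        np.savez(out / f"member{i}.npz", **arrays)


def load_ensemble(model_dir: str | Path) -> EnsembleModel:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["dense_units"] = tuple(cfg_dict["dense_units"])
    members = []
    for i, seed in enumerate(manifest["seeds"]):
        cfg = ModelConfig(**{**cfg_dict, "seed": seed})
        model = build_model(cfg)
        with np.load(model_dir / f"member{i}.npz") as data:
            for li, layer in enumerate(model.network.layers):
                for k in layer.params:
                    layer.params[k] = data[f"layer{li}_{k}"].copy()
        members.append(model)
    return EnsembleModel(members=members)
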