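"""Final neural classifier on the enriched feature matrix.

A small fully connected network — two to four ReLU hidden layers and a
sigmoid output — maps the enriched (8 + t)-column matrix to the final
4mC probability.  Windows with probability >= threshold (default 0.5)
are called positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn


@dataclass(frozen=True)
class FinalNetConfig:
    hidden_layers: int = 2
    hidden_units: tuple[int, ...] = (32, 16)
    threshold: float = 0.5
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.hidden_layers <= 4:
            raise ValueError("hidden_layers must be in 2..4")
        if len(self.hidden_units) != self.hidden_layers:
            raise ValueError(
                f"hidden_units has {len(self.hidden_units)} entries for "
                f"{self.hidden_layers} hidden layers"
            )
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 <= self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5)")


class FinalModel:
    """Trained final network; remembers its input width and threshold."""

    def __init__(self, net: nn.SequentialClassifier, n_features: int,
                 config: FinalNetConfig):
        self.net = net
        self.n_features = n_features
        self.config = config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected matrix with {self.n_features} columns, got shape {X.shape}"
            )
        return self.net.predict_proba(X)


def _build_net(config: FinalNetConfig, n_features: int,
               rng: np.random.Generator) -> nn.SequentialClassifier:
    layers: list[nn.Layer] = []
    width = n_features
    for units in config.hidden_units:
        layers.append(nn.Dense(width, units, rng))
        layers.append(nn.ReLU())
        width = units
    layers.append(nn.Dense(width, 1, rng))
    return nn.SequentialClassifier(layers, learning_rate=config.learning_rate)


def train_final(matrix: np.ndarray, labels: np.ndarray,
                config: FinalNetConfig = FinalNetConfig()) -> FinalModel:
    """Train the final classifier with early stopping on a validation slice."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(X) != len(y):
        raise ValueError("matrix rows must match labels")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (a single class)")
    rng = np.random.default_rng(config.seed)
    net = _build_net(config, X.shape[1], rng)
    validation = None
    Xtr, ytr = X, y
    if config.validation_fraction > 0 and len(X) >= 20:
        order = rng.permutation(len(X))
        n_val = max(1, int(round(config.validation_fraction * len(X))))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(np.unique(y[tr_idx])) == 2:
            validation = (X[val_idx], y[val_idx])
            Xtr, ytr = X[tr_idx], y[tr_idx]
    net.fit(Xtr, ytr, epochs=config.epochs, batch_size=config.batch_size,
            rng=rng, validation=validation,
            patience=config.patience if validation else None)
    return FinalModel(net, X.shape[1], config)


def predict(model: FinalModel, matrix: np.ndarray,
            threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard calls; a probability equal to the threshold
    is called positive (the >= convention)."""
    if threshold is None:
        threshold = model.config.threshold
    X = np.asarray(matrix, dtype=float)
    if len(X) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    probs = model.predict_proba(X)
    return probs, (probs >= threshold).astype(int)


def save_final(model: FinalModel, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = model.config.__dict__ | {
        "hidden_units": list(model.config.hidden_units),
        "n_features": model.n_features,
    }
    (out / "final.json").write_text(json.dumps(meta, indent=2) + "\n")
    arrays = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(out / "final_weights.npz", **arrays)


def load_final(in_dir) -> FinalModel:
    src = Path(in_dir)
    meta = json.loads((src / "final.json").read_text())
    n_features = meta.pop("n_features")
    meta["hidden_units"] = tuple(meta["hidden_units"])
    config = FinalNetConfig(**meta)
    net = _build_net(config, n_features, np.random.default_rng(config.seed))
    data = np.load(src / "final_weights.npz")
    net.set_weights([data[f"w{i}"] for i in range(len(net.get_weights()))])
    return FinalModel(net, n_features, config)
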