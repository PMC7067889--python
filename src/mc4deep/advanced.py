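"""Per-encoding CNN+BLSTM extractors and the 8-D advanced feature matrix.

One small network per encoding scheme: a stack of [conv -> ReLU ->
max-pool] blocks over the feature vector (treated as a length-N,
1-channel signal), a bidirectional LSTM over the pooled sequence, a
flatten, a fully connected layer and a single sigmoid output.  The
sigmoid probability of each scheme's network is that scheme's *advanced
feature*; stacking the eight columns gives the n x 8 advanced feature
matrix consumed by the iterative stacking ensemble.

Training follows the k-fold protocol: for each fold a network is
trained on the other folds and predicts the held-out fold, so every row
of the advanced matrix is an out-of-fold probability.  A final network
per scheme is refit on all rows for predicting new windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoders import (
    DEFAULT_PARAMS,
    EncodedMatrix,
    EncoderParams,
    SCHEME_ORDER,
    Scheme,
    encode_dataset,
    encode_knn_batch,
    encode,
)
from .folds import FoldAssignment
from .samples import DnaSample


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one CNN+BLSTM extractor.

    Defaults follow the published protocol: three convolution layers
    with 16/32/64 filters of length 8, max-pool 2, and 5 training
    epochs (the observed convergence point of the accuracy/loss
    curves).  LSTM width, dense width, optimizer settings and dropout
    are package defaults drawn from the published sweep lists.
    """

    n_conv_layers: int = 3
    nb_filter: tuple[int, ...] = (16, 32, 64)
    filter_length: tuple[int, ...] = (8, 8, 8)
    pool_size: int = 2
    lstm_units: int = 32
    dense_units: int = 16
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if len(self.nb_filter) != self.n_conv_layers:
            raise ValueError(
                f"nb_filter has {len(self.nb_filter)} entries for "
                f"{self.n_conv_layers} conv layers"
            )
        if len(self.filter_length) != self.n_conv_layers:
            raise ValueError(
                f"filter_length has {len(self.filter_length)} entries for "
                f"{self.n_conv_layers} conv layers"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def min_input_length(config: NetworkConfig) -> int:
    """Smallest input length the strict conv stack accepts."""
    need = 1
    for k in reversed(config.filter_length):
        need = need * config.pool_size  # pool: floor(t/p) >= need  <=>  t >= need*p
        need = need + k - 1             # valid conv: t_out = t_in - k + 1
    return need


def conv_shape_table(config: NetworkConfig, input_length: int,
                     adapt: bool = False) -> list[tuple[int, int]]:
    """(length, channels) after each conv block; used for planning and docs."""
    t, shapes = input_length, []
    for k, f in zip(config.filter_length, config.nb_filter):
        keff = min(k, t) if adapt else k
        if t < keff:
            raise ValueError(
                f"input length {input_length} too short; minimum is "
                f"{min_input_length(config)}"
            )
        t = t - keff + 1
        if t >= config.pool_size:
            t //= config.pool_size
        elif not adapt:
            raise ValueError(
                f"input length {input_length} too short; minimum is "
                f"{min_input_length(config)}"
            )
        shapes.append((t, f))
    return shapes


def build_network(
    config: NetworkConfig,
    input_length: int,
    rng: np.random.Generator | None = None,
    adapt: bool = False,
) -> nn.SequentialClassifier:
    """Assemble the conv/BLSTM/dense stack for one feature vector length.

    With ``adapt=False`` (the strict published stack) an input shorter
    than the receptive footprint raises, reporting the minimum length.
    With ``adapt=True`` each kernel is clipped to the current length and
    pooling is skipped once the sequence is shorter than the pool, so
    short encodings (e.g. the 10-value KNN feature) still get the same
    three-block architecture.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shapes = conv_shape_table(config, input_length, adapt=adapt)

    layers: list[nn.Layer] = []
    t, channels = input_length, 1
    for k, f in zip(config.filter_length, config.nb_filter):
        keff = min(k, t) if adapt else k
        layers.append(nn.Conv1D(channels, f, keff, rng))
        layers.append(nn.ReLU())
        t = t - keff + 1
        if t >= config.pool_size:
            layers.append(nn.MaxPool1D(config.pool_size))
            t //= config.pool_size
        channels = f
    if config.dropout > 0:
        layers.append(nn.Dropout(config.dropout, rng))
    layers.append(nn.BiLSTM(channels, config.lstm_units, rng))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(t * 2 * config.lstm_units, config.dense_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(config.dense_units, 1, rng))
    model = nn.SequentialClassifier(layers, learning_rate=config.learning_rate)
    model.conv_shapes = shapes
    return model


class ExtractorModel:
    """A trained network plus the feature standardization fitted with it."""

    def __init__(self, net: nn.SequentialClassifier, mean: np.ndarray, std: np.ndarray,
                 config: NetworkConfig, input_length: int, adapt: bool):
        self.net = net
        self.mean = mean
        self.std = std
        self.config = config
        self.input_length = input_length
        self.adapt = adapt

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.input_length:
            raise ValueError(
                f"expected {self.input_length} features, got {X.shape[1]}"
            )
        Z = (X - self.mean) / self.std
        return Z[:, :, None]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._prepare(X))


@dataclass
class ExtractorCV:
    """k-fold training result for one scheme."""

    fold_models: list[ExtractorModel]
    final_model: ExtractorModel
    oof_probs: np.ndarray
    histories: list[dict[str, list[float]]]
    # leakage provenance: trained_rows[f] = rows used to train fold f's
    # model; producer_fold[i] = fold whose model produced row i's value
    trained_rows: list[np.ndarray]
    producer_fold: np.ndarray


def _fit_one(X: np.ndarray, y: np.ndarray, config: NetworkConfig,
             seed_key: list[int], adapt: bool) -> tuple[ExtractorModel, dict]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-8] = 1.0
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    net = build_network(config, X.shape[1], rng=rng, adapt=adapt)
    Z = ((X - mean) / std)[:, :, None]
    history = net.fit(Z, y, epochs=config.epochs, batch_size=config.batch_size,
                      rng=rng)
    model = ExtractorModel(net, mean, std, config, X.shape[1], adapt)
    return model, history


def train_extractor(
    encoded: EncodedMatrix | np.ndarray,
    labels: np.ndarray,
    folds: FoldAssignment,
    config: NetworkConfig,
    adapt: bool = False,
) -> ExtractorCV:
    """k-fold training of one scheme's extractor with out-of-fold outputs.

    For each fold a network is trained on the remaining folds and
    predicts the held-out fold; ``oof_probs[i]`` therefore comes from a
    model that never saw row i's fold.  A final model is refit on all
    rows for use on new data.
    """
    X = encoded.matrix if isinstance(encoded, EncodedMatrix) else np.asarray(encoded)
    y = np.asarray(labels, dtype=float)
    if len(X) != len(y):
        raise ValueError("matrix rows must match labels")
    oof = np.full(len(X), np.nan)
    fold_models, histories, trained_rows = [], [], []
    producer = np.full(len(X), -1, dtype=int)
    for fold in range(folds.k):
        tr = folds.rows_not_in_fold(fold)
        te = folds.rows_in_fold(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training split for fold {fold} has a single class")
        model, history = _fit_one(X[tr], y[tr], config, [config.seed, fold], adapt)
        oof[te] = model.predict_proba(X[te])
        fold_models.append(model)
        histories.append(history)
        trained_rows.append(tr)
        producer[te] = fold
    final_model, _ = _fit_one(X, y, config, [config.seed, folds.k], adapt)
    return ExtractorCV(fold_models, final_model, oof, histories, trained_rows, producer)


@dataclass
class AdvancedFeatureMatrix:
    """n x 8 matrix of per-scheme sigmoid probabilities (fixed column order)."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    schemes: tuple[Scheme, ...] = SCHEME_ORDER

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.schemes):
            raise ValueError(
                f"expected {len(self.schemes)} columns, got {self.matrix.shape}"
            )
        if self.matrix.size and not (
            (self.matrix >= 0).all() and (self.matrix <= 1).all()
        ):
            raise ValueError("advanced features must lie in [0, 1]")


class AdvancedFeatureBundle:
    """The eight trained extractors plus everything needed to encode new data."""

    def __init__(self, config: NetworkConfig,
                 encoder_params: EncoderParams = DEFAULT_PARAMS,
                 schemes: tuple[Scheme, ...] = SCHEME_ORDER,
                 adapt: bool = True):
        self.config = config
        self.encoder_params = encoder_params
        self.schemes = schemes
        self.adapt = adapt
        self.extractors: dict[Scheme, ExtractorCV] = {}
        self.knn_references: list[DnaSample] | None = None
        self.oof: AdvancedFeatureMatrix | None = None

    def fit(self, samples: Sequence[DnaSample], folds: FoldAssignment,
            verbose: bool = False) -> "AdvancedFeatureBundle":
        labels = np.asarray([s.label for s in samples], dtype=float)
        ids = tuple(s.id for s in samples)
        cols = []
        for j, scheme in enumerate(self.schemes):
            encoded = encode_dataset(samples, scheme, folds=folds,
                                     params=self.encoder_params)
            cfg = NetworkConfig(**{**self.config.__dict__,
                                   "seed": _subseed(self.config.seed, j)})
            cv = train_extractor(encoded, labels, folds, cfg, adapt=self.adapt)
            self.extractors[scheme] = cv
            cols.append(cv.oof_probs)
            if verbose:
                print(f"  [{scheme.value}] oof mean prob "
                      f"{np.nanmean(cv.oof_probs):.3f}")
        self.knn_references = list(samples)
        self.oof = AdvancedFeatureMatrix(ids, np.column_stack(cols), self.schemes)
        return self

    def transform(self, samples: Sequence[DnaSample]) -> AdvancedFeatureMatrix:
        """Advanced features for new windows, via the refit-on-all models."""
        missing = [s.value for s in self.schemes if s not in self.extractors]
        if missing:
            raise ValueError(f"bundle missing trained scheme(s): {missing}")
        ids = tuple(s.id for s in samples)
        if not samples:
            return AdvancedFeatureMatrix(ids, np.empty((0, len(self.schemes))),
                                         self.schemes)
        cols = []
        for scheme in self.schemes:
            if scheme is Scheme.KNN:
                X = encode_knn_batch(samples, self.knn_references,
                                     self.encoder_params)
            else:
                X = np.stack([encode(s, scheme, self.encoder_params)
                              for s in samples])
            cols.append(self.extractors[scheme].final_model.predict_proba(X))
        return AdvancedFeatureMatrix(ids, np.column_stack(cols), self.schemes)


def _subseed(seed: int, index: int) -> int:
    # Deterministic per-scheme seed below 2**31.
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def extract_advanced(samples: Sequence[DnaSample],
                     trained_bundle: AdvancedFeatureBundle) -> AdvancedFeatureMatrix:
    """Apply a trained bundle to windows, yielding the n x 8 matrix."""
    return trained_bundle.transform(samples)


def write_advanced_tsv(adv: AdvancedFeatureMatrix, tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("id\t" + "\t".join(s.value for s in adv.schemes) + "\n")
        for sid, row in zip(adv.ids, adv.matrix):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_advanced_tsv(tsv_path) -> AdvancedFeatureMatrix:
    lines = Path(tsv_path).read_text().splitlines()
    header = lines[0].split("\t")
    schemes = tuple(Scheme(h) for h in header[1:])
    ids, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    mat = np.asarray(rows) if rows else np.empty((0, len(schemes)))
    return AdvancedFeatureMatrix(tuple(ids), mat, schemes)


# ---------------------------------------------------------------------------
# Persistence: one weights file per scheme plus a JSON manifest.

def save_bundle(bundle: AdvancedFeatureBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": bundle.config.__dict__ | {
            "nb_filter": list(bundle.config.nb_filter),
            "filter_length": list(bundle.config.filter_length),
        },
        "adapt": bundle.adapt,
        "schemes": [s.value for s in bundle.schemes],
        "encoder_params": {
            "kmer_ks": list(bundle.encoder_params.kmer_ks),
            "pse_lambda": bundle.encoder_params.pse_lambda,
            "pse_weight": bundle.encoder_params.pse_weight,
            "knn_fractions": list(bundle.encoder_params.knn_fractions),
        },
        "input_lengths": {
            s.value: bundle.extractors[s].final_model.input_length
            for s in bundle.schemes
        },
    }
    (out / "bundle.json").write_text(json.dumps(meta, indent=2) + "\n")
    for scheme in bundle.schemes:
        model = bundle.extractors[scheme].final_model
        arrays = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
        np.savez(out / f"{scheme.value}.npz", mean=model.mean, std=model.std,
                 **arrays)
    if bundle.knn_references is not None:
        refs = [{"id": s.id, "sequence": s.sequence, "label": s.label}
                for s in bundle.knn_references]
        (out / "knn_references.json").write_text(json.dumps(refs) + "\n")


def load_bundle(in_dir) -> AdvancedFeatureBundle:
    src = Path(in_dir)
    meta = json.loads((src / "bundle.json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["nb_filter"] = tuple(cfg_dict["nb_filter"])
    cfg_dict["filter_length"] = tuple(cfg_dict["filter_length"])
    config = NetworkConfig(**cfg_dict)
    ep = meta["encoder_params"]
    params = EncoderParams(
        kmer_ks=tuple(ep["kmer_ks"]), pse_lambda=ep["pse_lambda"],
        pse_weight=ep["pse_weight"], knn_fractions=tuple(ep["knn_fractions"]),
    )
    schemes = tuple(Scheme(s) for s in meta["schemes"])
    bundle = AdvancedFeatureBundle(config, params, schemes, adapt=meta["adapt"])
    for j, scheme in enumerate(schemes):
        data = np.load(src / f"{scheme.value}.npz")
        input_length = meta["input_lengths"][scheme.value]
        cfg = NetworkConfig(**{**config.__dict__, "seed": _subseed(config.seed, j)})
        net = build_network(cfg, input_length, adapt=meta["adapt"])
        weights = [data[f"w{i}"] for i in range(len(net.get_weights()))]
        net.set_weights(weights)
        model = ExtractorModel(net, data["mean"], data["std"], cfg, input_length,
                               meta["adapt"])
        bundle.extractors[scheme] = ExtractorCV(
            fold_models=[], final_model=model, oof_probs=np.empty(0),
            histories=[], trained_rows=[], producer_fold=np.empty(0, dtype=int),
        )
    ref_file = src / "knn_references.json"
    if ref_file.exists():
        bundle.knn_references = [
            DnaSample(r["id"], r["sequence"], r["label"])
            for r in json.loads(ref_file.read_text())
        ]
    return bundle
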