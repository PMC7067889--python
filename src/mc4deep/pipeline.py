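"""End-to-end orchestration: filter -> encode -> advanced -> stack -> final.

:class:`Mc4Pipeline` is the fit/predict object; :func:`run_pipeline`
wraps it with file I/O, a train/test split, a metric report and a
reproducibility manifest.  One master seed pins the fold split, every
network initialisation, the stacking learners and the final classifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .advanced import (
    AdvancedFeatureBundle,
    NetworkConfig,
    load_bundle,
    save_bundle,
    write_advanced_tsv,
)
from .encoders import DEFAULT_PARAMS, EncoderParams
from .final import FinalModel, FinalNetConfig, load_final, predict, save_final, train_final
from .folds import FoldAssignment, stratified_folds
from .metrics import MetricReport, confusion, report, write_report_json
from .samples import DnaSample, dedup_exact, filter_by_modqv, read_samples, write_samples
from .simulate import GeneratorConfig, generate
from .stacking import EnrichedMatrix, default_learners, iterate, write_enriched_tsv


def compact_network_config(seed: int = 0) -> NetworkConfig:
    """A reduced extractor for CPU-scale runs on larger sample sizes:
    same three-block conv + BLSTM architecture, narrower everywhere."""
    return NetworkConfig(
        n_conv_layers=3, nb_filter=(4, 8, 16), filter_length=(5, 5, 5),
        pool_size=2, lstm_units=8, dense_units=8, dropout=0.2,
        learning_rate=1e-3, batch_size=64, epochs=5, seed=seed,
    )


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, under a single master seed."""

    generator: GeneratorConfig | None = None
    fasta: str | None = None
    labels: str | None = None
    metadata: str | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    final: FinalNetConfig = field(default_factory=FinalNetConfig)
    encoder_params: EncoderParams = field(default_factory=EncoderParams)
    k: int = 3
    max_iter: int = 10
    tol: float = 1e-4
    modqv_threshold: float | None = 30.0
    modqv_mode: str = "drop_above"
    dedup: str = "exact"
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = asdict(self.generator) if self.generator else None
        return d


def _seeded(run_seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([run_seed, tag]).generate_state(1)[0] % (2**31))


class Mc4Pipeline:
    """Fit the whole model family on labelled windows, predict new ones."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.folds: FoldAssignment | None = None
        self.bundle: AdvancedFeatureBundle | None = None
        self.enriched: EnrichedMatrix | None = None
        self.final_model: FinalModel | None = None

    def fit(self, samples: Sequence[DnaSample], verbose: bool = False) -> "Mc4Pipeline":
        cfg = self.config
        labels = np.asarray([s.label for s in samples], dtype=int)
        self.folds = stratified_folds(list(samples), k=cfg.k,
                                      seed=_seeded(cfg.seed, 1))
        net_cfg = NetworkConfig(**{**cfg.network.__dict__,
                                   "seed": _seeded(cfg.seed, 2)})
        self.bundle = AdvancedFeatureBundle(
            net_cfg, cfg.encoder_params, adapt=True
        ).fit(samples, self.folds, verbose=verbose)
        learners = default_learners(seed=_seeded(cfg.seed, 3))
        self.enriched = iterate(
            self.bundle.oof.matrix, labels, self.folds, learners=learners,
            max_iter=cfg.max_iter, tol=cfg.tol, ids=self.bundle.oof.ids,
        )
        fin_cfg = FinalNetConfig(**{**cfg.final.__dict__,
                                    "seed": _seeded(cfg.seed, 4)})
        self.final_model = train_final(self.enriched.matrix, labels, fin_cfg)
        return self

    def _require_fitted(self):
        if self.final_model is None:
            raise RuntimeError("pipeline is not fitted")

    def predict(self, samples: Sequence[DnaSample],
                threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        self._require_fitted()
        adv = self.bundle.transform(samples)
        X = self.enriched.transform(adv.matrix)
        return predict(self.final_model, X, threshold)

    def evaluate(self, samples: Sequence[DnaSample]) -> MetricReport:
        probs, calls = self.predict(samples)
        y = np.asarray([s.label for s in samples], dtype=int)
        return report(confusion(y, calls), scores=probs, labels_true=y)

    # -- persistence ----------------------------------------------------
    def save(self, out_dir) -> None:
        self._require_fitted()
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_bundle(self.bundle, out / "extractors")
        save_final(self.final_model, out / "final")
        joblib.dump(
            {"refit_models": self.enriched.refit_models,
             "base_columns": self.enriched.base_columns,
             "provenance": self.enriched.provenance},
            out / "stacking.joblib",
        )
        (out / "run_config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, default=str) + "\n"
        )

    @classmethod
    def load(cls, in_dir) -> "Mc4Pipeline":
        src = Path(in_dir)
        raw = json.loads((src / "run_config.json").read_text())
        config = _runconfig_from_dict(raw)
        pipe = cls(config)
        pipe.bundle = load_bundle(src / "extractors")
        pipe.final_model = load_final(src / "final")
        stack = joblib.load(src / "stacking.joblib")
        n = 0
        pipe.enriched = EnrichedMatrix(
            ids=(), matrix=np.empty((n, stack["base_columns"])),
            base_columns=stack["base_columns"],
            provenance=stack["provenance"],
            refit_models=stack["refit_models"],
        )
        return pipe


def _runconfig_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    gen = d.pop("generator", None)
    if gen:
        for key in ("background", "modqv_range"):
            if key in gen:
                gen[key] = tuple(gen[key])
        gen = GeneratorConfig(**gen)
    net = d.pop("network")
    net["nb_filter"] = tuple(net["nb_filter"])
    net["filter_length"] = tuple(net["filter_length"])
    fin = d.pop("final")
    fin["hidden_units"] = tuple(fin["hidden_units"])
    enc = d.pop("encoder_params")
    enc["kmer_ks"] = tuple(enc["kmer_ks"])
    enc["knn_fractions"] = tuple(enc["knn_fractions"])
    return RunConfig(
        generator=gen, network=NetworkConfig(**net), final=FinalNetConfig(**fin),
        encoder_params=EncoderParams(**enc), **d,
    )


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML (or JSON); missing sections use defaults."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, default in (("network", NetworkConfig()),
                             ("final", FinalNetConfig()),
                             ("encoder_params", EncoderParams())):
        merged = asdict(default) | (raw.get(section) or {})
        raw[section] = merged
    raw.setdefault("generator", None)
    return _runconfig_from_dict(raw)


def save_run_config(config: RunConfig, path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def train_test_split(samples: Sequence[DnaSample], test_fraction: float,
                     seed: int) -> tuple[list[DnaSample], list[DnaSample]]:
    """Stratified split, deterministic per seed."""
    if test_fraction == 0:
        return list(samples), []
    rng = np.random.default_rng(seed)
    labels = np.asarray([s.label for s in samples])
    test_idx: list[int] = []
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        n_test = int(round(test_fraction * len(rows)))
        test_idx.extend(rng.permutation(rows)[:n_test].tolist())
    test_set = set(test_idx)
    train = [s for i, s in enumerate(samples) if i not in test_set]
    test = [s for i, s in enumerate(samples) if i in test_set]
    return train, test


@dataclass
class PipelineResult:
    pipeline: Mc4Pipeline
    report: MetricReport | None
    out_dir: Path | None
    n_train: int
    n_test: int


def run_pipeline(config: RunConfig, out_dir=None,
                 verbose: bool = False) -> PipelineResult:
    """Execute the full protocol and (optionally) write all artifacts.

    Input windows either come from ``config.fasta``/``labels``/
    ``metadata`` or are generated from ``config.generator``.  After
    quality filtering and deduplication, a stratified ``test_fraction``
    of the windows is held out; the pipeline is fitted on the rest and
    the report measures the held-out windows.
    """
    stage = "input"
    try:
        if config.generator is not None:
            samples = generate(config.generator)
        elif config.fasta is not None:
            samples = read_samples(config.fasta, config.labels,
                                   modqv_source=config.metadata)
        else:
            raise ValueError("config needs either a generator or a fasta path")

        stage = "filter"
        if config.modqv_threshold is not None:
            samples = filter_by_modqv(samples, config.modqv_threshold,
                                      config.modqv_mode)
        if config.dedup == "exact":
            samples = dedup_exact(samples)

        stage = "split"
        train, test = train_test_split(samples, config.test_fraction,
                                       _seeded(config.seed, 0))

        stage = "fit"
        pipe = Mc4Pipeline(config).fit(train, verbose=verbose)

        stage = "evaluate"
        rep = pipe.evaluate(test) if test else None
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(pipe, rep, None, len(train), len(test))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_samples(train, out / "train.fasta", out / "train_labels.tsv")
        if test:
            write_samples(test, out / "test.fasta", out / "test_labels.tsv")
        write_advanced_tsv(pipe.bundle.oof, out / "advanced.tsv")
        write_enriched_tsv(pipe.enriched, out / "enriched.tsv",
                           out / "stacking_provenance.json")
        if rep is not None:
            y = np.asarray([s.label for s in test], dtype=int)
            probs, calls = pipe.predict(test)
            with open(out / "calls.tsv", "w") as fh:
                for s, p, c in zip(test, probs, calls):
                    fh.write(f"{s.id}\t{p:.6f}\t{c}\n")
            write_report_json(rep, confusion(y, calls), out / "report.json")
        (out / "manifest.json").write_text(
            json.dumps(build_manifest(config, pipe), indent=2) + "\n"
        )
        result.out_dir = out
    return result


def build_manifest(config: RunConfig, pipe: Mc4Pipeline | None = None) -> dict:
    import sklearn

    # JSON round trip so the in-memory manifest equals the on-disk one
    cfg = json.loads(json.dumps(config.to_dict(), default=str))
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": digest,
        "versions": {
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if pipe is not None and pipe.folds is not None:
        manifest["fold_sizes"] = pipe.folds.fold_sizes().tolist()
        manifest["enriched_shape"] = list(pipe.enriched.matrix.shape)
        manifest["stacking"] = pipe.enriched.provenance
        manifest["stop_reason"] = pipe.enriched.stop_reason
    return manifest
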