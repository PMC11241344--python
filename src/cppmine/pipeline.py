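"""End-to-end training pipeline with a structured, serializable config.

Stages: load/generate sequences -> curate -> (per-class) redundancy
clustering -> featurize -> correlation pruning -> L1 selection -> 85:15
split -> per-model grid search -> stacking -> evaluation.  All artifacts
(feature matrix, selection report, model, metrics, manifest) are written to
the output directory; the manifest records the seed, a config hash and
library versions so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ensemble import (
    CPPEnsemble,
    EnsembleConfig,
    EnsembleResults,
    apply_grid_result,
    grid_search,
    split_train_validation,
)
from .feature_selection import select_features
from .descriptors import featurize
from .sequence_io import (
    CPP_LABEL,
    NON_CPP_LABEL,
    SequenceSet,
    curate,
    greedy_identity_cluster,
    read_fasta,
    read_table,
    relabel,
    write_table,
)
from .synthetic import GeneratorConfig, generate_labeled_set

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict):
    """Build a (possibly nested) dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get((cls.__name__, name))
        if target is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(target, value)
        elif name == "length_range" and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class DataConfig:
    table: str | None = None          # labeled TSV (id, sequence, label)
    cpp_fasta: str | None = None      # FASTA of positives
    non_cpp_fasta: str | None = None  # FASTA of negatives
    synthetic: GeneratorConfig | None = None


@dataclass
class CurateConfig:
    min_len: int = 5
    max_len: int = 61
    cluster_identity: float | None = 0.45
    cluster_classes: list[int] = field(default_factory=lambda: [NON_CPP_LABEL])


@dataclass
class SelectionConfig:
    corr_threshold: float = 0.9
    folds: int = 10
    max_features: int = 20
    logistic: bool = False


@dataclass
class RunConfig:
    data: DataConfig = field(default_factory=DataConfig)
    curation: CurateConfig = field(default_factory=CurateConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: EnsembleConfig = field(default_factory=EnsembleConfig)
    grids: dict = field(default_factory=dict)  # optional per-model parameter grids
    seed: int = 40
    out_dir: str = "cppmine_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["data"]["synthetic"] is not None:
            d["data"]["synthetic"]["length_range"] = list(d["data"]["synthetic"]["length_range"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_NESTED = {
    ("RunConfig", "data"): DataConfig,
    ("RunConfig", "curation"): CurateConfig,
    ("RunConfig", "selection"): SelectionConfig,
    ("RunConfig", "model"): EnsembleConfig,
    ("DataConfig", "synthetic"): GeneratorConfig,
    ("EnsembleConfig", "knn"): None,
    ("EnsembleConfig", "boosting"): None,
    ("EnsembleConfig", "forest"): None,
}
from .ensemble import BoostingConfig, ForestConfig, KNNConfig  # noqa: E402

_NESTED[("EnsembleConfig", "knn")] = KNNConfig
_NESTED[("EnsembleConfig", "boosting")] = BoostingConfig
_NESTED[("EnsembleConfig", "forest")] = ForestConfig


def load_training_set(cfg: RunConfig) -> SequenceSet:
    data = cfg.data
    sources = [s for s in (data.table, data.cpp_fasta, data.synthetic) if s is not None]
    if not sources:
        raise ConfigError("no input: set data.table, data.cpp_fasta/non_cpp_fasta or data.synthetic")
    if data.table is not None:
        return read_table(data.table)
    if data.cpp_fasta is not None:
        if data.non_cpp_fasta is None:
            raise ConfigError("cpp_fasta requires non_cpp_fasta")
        pos = relabel(read_fasta(data.cpp_fasta), CPP_LABEL)
        neg = relabel(read_fasta(data.non_cpp_fasta), NON_CPP_LABEL)
        return SequenceSet(pos.records + neg.records, provenance="fasta-pair")
    return generate_labeled_set(data.synthetic)


def prepare_sequences(s: SequenceSet, cfg: RunConfig) -> SequenceSet:
    cur = cfg.curation
    curated, _report = curate(s, cur.min_len, cur.max_len)
    if cur.cluster_identity is None:
        return curated
    out: list = []
    for label in sorted({p.label for p in curated}, key=lambda x: (x is None, x)):
        part = curated.subset(lambda p, l=label: p.label == l)
        if label in cur.cluster_classes:
            part = greedy_identity_cluster(part, cur.cluster_identity)
        out.extend(part.records)
    return SequenceSet(out, provenance=curated.provenance)


def run_pipeline(cfg: RunConfig) -> EnsembleResults:
    """Execute every stage and write artifacts under ``cfg.out_dir``."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    raw = load_training_set(cfg)
    prepared = prepare_sequences(raw, cfg)
    counts = prepared.class_counts()
    logger.info("training set: %s", counts)
    write_table(prepared, out / "training_sequences.tsv")

    features = featurize(prepared)
    features.write_tsv(out / "features.tsv")

    sel = cfg.selection
    selected, report = select_features(
        features,
        corr_threshold=sel.corr_threshold,
        folds=sel.folds,
        max_features=sel.max_features,
        seed=cfg.seed,
        logistic=sel.logistic,
    )
    report.to_json(out / "selection_report.json")
    report.write_feature_list(out / "selected_features.txt")

    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)
    model = CPPEnsemble(selected, model_cfg)
    if cfg.grids:
        train, _ = split_train_validation(selected, model_cfg)
        best = grid_search(train, cfg.grids, model_cfg)
        model_cfg = apply_grid_result(model_cfg, best)
        model = CPPEnsemble(selected, model_cfg)
        (out / "grid_search.json").write_text(json.dumps(best, indent=2))

    results = model.fit()
    results.save(out / "model.pkl", out / "model.json")
    results.validation_metrics.to_json(out / "metrics.json")
    (out / "summary.txt").write_text(results.summary() + "\n")

    config_blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "class_counts": {str(k): v for k, v in counts.items()},
        "n_features_selected": len(results.feature_manifest),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
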