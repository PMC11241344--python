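"""Stacked three-model classifier for CPP prediction.

The model stacks k-nearest neighbors, gradient-boosted trees and a random
forest; an L2-regularized logistic meta-learner is fitted on the base
learners' out-of-fold class-1 probabilities (internal seeded 5-fold).  The
default hyperparameters are the grid-search optima for the CPP task:

* k-NN: 18 neighbours, Manhattan metric, inverse-distance weighting
* gradient boosting: 250 rounds, depth 8, learning rate 0.0567, tree booster
* random forest: 20 trees, log2 feature subsampling, Gini criterion

Usage follows the model/results idiom::

    model = CPPEnsemble(feature_matrix, config)
    res = model.fit()
    print(res.summary())
    proba, klass = res.predict(new_features)
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier, StackingClassifier, VotingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_validate, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .descriptors import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class KNNConfig:
    neighbor_count: int = 18
    distance_metric: str = "manhattan"
    weighting: str = "distance"


@dataclass
class BoostingConfig:
    round_count: int = 250
    max_depth: int = 8
    learning_rate: float = 0.0567
    base_learner: str = "gbtree"


@dataclass
class ForestConfig:
    tree_count: int = 20
    feature_subsample: str = "log2"
    split_criterion: str = "gini"


@dataclass
class EnsembleConfig:
    knn: KNNConfig = field(default_factory=KNNConfig)
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    train_fraction: float = 0.85
    shuffle: bool = True
    seed: int = 40
    cv_folds: int = 10
    stack_cv_folds: int = 5
    threshold: float = 0.5
    soft_voting: bool = False  # ablation: average base probabilities instead of meta-learning

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0 < self.boosting.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        for count in (self.knn.neighbor_count, self.boosting.round_count, self.forest.tree_count):
            if count < 1:
                raise ValueError("model size parameters must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float | None
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def evaluate(truth, proba, predicted=None, threshold: float = 0.5) -> MetricsReport:
    """Confusion-count metrics plus rank-based ROC AUC (midrank ties).

    ROC AUC is reported as ``None`` with a warning when the truth vector is
    single-class.
    """
    truth = np.asarray(truth, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if len(truth) != len(proba):
        raise ValueError("truth and probability vectors differ in length")
    pred = np.asarray(predicted, dtype=int) if predicted is not None else (proba >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(truth)) < 2:
        logger.warning("evaluate: single-class truth, ROC AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(truth, proba))
    return MetricsReport(
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        roc_auc=auc,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def build_base_learners(cfg: EnsembleConfig) -> list[tuple[str, object]]:
    # Descriptors live on wildly different scales (fractions vs Daltons), so
    # the distance-based learner gets a standardizer in its pipeline.
    return [
        ("knn", Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(
                n_neighbors=cfg.knn.neighbor_count,
                metric=cfg.knn.distance_metric,
                weights=cfg.knn.weighting,
            )),
        ])),
        ("gbt", XGBClassifier(
            n_estimators=cfg.boosting.round_count,
            max_depth=cfg.boosting.max_depth,
            learning_rate=cfg.boosting.learning_rate,
            booster=cfg.boosting.base_learner,
            random_state=cfg.seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
        )),
        ("rf", RandomForestClassifier(
            n_estimators=cfg.forest.tree_count,
            max_features=cfg.forest.feature_subsample,
            criterion=cfg.forest.split_criterion,
            random_state=cfg.seed,
        )),
    ]


def build_stack(cfg: EnsembleConfig):
    base = build_base_learners(cfg)
    if cfg.soft_voting:
        return VotingClassifier(base, voting="soft")
    return StackingClassifier(
        estimators=base,
        final_estimator=LogisticRegression(max_iter=1000, random_state=cfg.seed),  # default L2
        cv=StratifiedKFold(cfg.stack_cv_folds, shuffle=True, random_state=cfg.seed),
        stack_method="predict_proba",
        n_jobs=1,
    )


def split_train_validation(m: FeatureMatrix, cfg: EnsembleConfig) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded shuffled 85:15 split (train rows = floor(train_fraction * n))."""
    if m.y is None:
        raise ValueError("split requires labels")
    idx_train, idx_val = train_test_split(
        np.arange(len(m)),
        train_size=cfg.train_fraction,
        shuffle=cfg.shuffle,
        random_state=cfg.seed,
    )
    for name, idx in (("train", idx_train), ("validation", idx_val)):
        if len(np.unique(m.y.iloc[idx])) < 2:
            logger.warning("split: %s side contains a single class (small n?)", name)
    train = FeatureMatrix(m.X.iloc[idx_train].copy(), m.y.iloc[idx_train].copy())
    val = FeatureMatrix(m.X.iloc[idx_val].copy(), m.y.iloc[idx_val].copy())
    return train, val


def grid_search(train: FeatureMatrix, grids: dict[str, dict[str, list]], cfg: EnsembleConfig) -> dict[str, dict]:
    """Exhaustive per-model grid search by seeded stratified 10-fold CV.

    The winning point maximizes mean CV precision; ties break by higher mean
    accuracy, then by grid order.  ``grids`` maps base-learner name
    ('knn'/'gbt'/'rf') to a sklearn-style parameter grid.
    """
    y = np.asarray(train.y, dtype=int)
    _, class_counts = np.unique(y, return_counts=True)
    if cfg.cv_folds > class_counts.min():
        raise ValueError(
            f"cv_folds={cfg.cv_folds} exceeds the smallest class count "
            f"({class_counts.min()}); reduce folds or enlarge the data"
        )
    estimators = dict(build_base_learners(cfg))
    cv = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    X = train.X.to_numpy()
    best: dict[str, dict] = {}
    for name, grid in grids.items():
        if name not in estimators:
            raise KeyError(f"unknown model {name!r}; expected one of {sorted(estimators)}")
        points = list(ParameterGrid(grid))
        if not points:
            raise ValueError(f"empty grid for model {name!r}")
        scored = []
        for i, params in enumerate(points):
            est = clone(estimators[name])
            if isinstance(est, Pipeline):  # address the final step of wrapped learners
                step = est.steps[-1][0]
                params_applied = {f"{step}__{k}": v for k, v in params.items()}
            else:
                params_applied = params
            est.set_params(**params_applied)
            scores = cross_validate(est, X, y, cv=cv, scoring=("precision", "accuracy"), n_jobs=1)
            scored.append((scores["test_precision"].mean(), scores["test_accuracy"].mean(), -i, params))
        prec, acc, negi, params = max(scored)
        logger.info("grid_search[%s]: best %r (precision %.4f, accuracy %.4f)", name, params, prec, acc)
        best[name] = params
    return best


def apply_grid_result(cfg: EnsembleConfig, best: dict[str, dict]) -> EnsembleConfig:
    """Fold grid-search winners back into a config."""
    mapping = {
        "knn": ("knn", {"n_neighbors": "neighbor_count", "metric": "distance_metric", "weights": "weighting"}),
        "gbt": ("boosting", {"n_estimators": "round_count", "max_depth": "max_depth",
                             "learning_rate": "learning_rate", "booster": "base_learner"}),
        "rf": ("forest", {"n_estimators": "tree_count", "max_features": "feature_subsample",
                          "criterion": "split_criterion"}),
    }
    out = cfg
    for model, params in best.items():
        attr, names = mapping[model]
        sub = replace(getattr(out, attr), **{names[k]: v for k, v in params.items()})
        out = replace(out, **{attr: sub})
    return out


class CPPEnsemble:
    """Stacked CPP/non-CPP classifier built from a labeled feature matrix."""

    def __init__(self, data: FeatureMatrix, config: EnsembleConfig | None = None):
        if data.y is None:
            raise ValueError("CPPEnsemble requires a labeled feature matrix")
        if len(np.unique(np.asarray(data.y))) < 2:
            raise ValueError("both classes must be present to fit the ensemble")
        self.data = data
        self.config = config or EnsembleConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       config: EnsembleConfig | None = None) -> "CPPEnsemble":
        y = df[label_column]
        X = df.drop(columns=[label_column])
        return cls(FeatureMatrix(X, y), config)

    def fit(self) -> "EnsembleResults":
        """Split, fit the stack on the training side, evaluate on both sides."""
        train, val = split_train_validation(self.data, self.config)
        stack = build_stack(self.config)
        stack.fit(train.X.to_numpy(), np.asarray(train.y, dtype=int))
        return EnsembleResults(self, stack, train, val)


class EnsembleResults:
    """Fitted stacked ensemble with its split, metrics and feature manifest."""

    def __init__(self, model: CPPEnsemble, stack, train: FeatureMatrix, validation: FeatureMatrix):
        self.model = model
        self.config = model.config
        self.stack = stack
        self.train = train
        self.validation = validation
        self.feature_manifest: list[str] = list(train.feature_names)
        self.train_metrics = self._score(train)
        self.validation_metrics = self._score(validation)

    def _score(self, m: FeatureMatrix) -> MetricsReport:
        proba, pred = self.predict(m)
        return evaluate(np.asarray(m.y, dtype=int), proba, pred, self.config.threshold)

    def predict(self, m: FeatureMatrix | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-row (probability of class 1, hard class at the threshold).

        Refuses inputs whose feature-name set differs from the training
        manifest; identically named columns in a different order are
        realigned.
        """
        X = m.X if isinstance(m, FeatureMatrix) else m
        missing = [c for c in self.feature_manifest if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_manifest]
        if missing or extra:
            raise ValueError(
                f"feature manifest mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
            )
        proba = self.stack.predict_proba(X[self.feature_manifest].to_numpy())[:, 1]
        return proba, (proba >= self.config.threshold).astype(int)

    def predict_base_learners(self, m: FeatureMatrix) -> dict[str, np.ndarray]:
        """Class-1 probabilities of each fitted base learner (diagnostics)."""
        X = m.X[self.feature_manifest].to_numpy()
        if isinstance(self.stack, StackingClassifier):
            named = zip([n for n, _ in self.stack.estimators], self.stack.estimators_)
        else:
            named = zip([n for n, _ in self.stack.estimators], self.stack.estimators_)
        return {name: est.predict_proba(X)[:, 1] for name, est in named}

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Stacked CPP classifier (kNN + gradient boosting + random forest)",
            "=" * 64,
            f"observations: {len(self.model.data)}  "
            f"(train {len(self.train)} / validation {len(self.validation)}, "
            f"fraction {cfg.train_fraction}, seed {cfg.seed})",
            f"features ({len(self.feature_manifest)}): "
            + ", ".join(self.feature_manifest[:6])
            + (", ..." if len(self.feature_manifest) > 6 else ""),
            f"kNN: k={cfg.knn.neighbor_count}, {cfg.knn.distance_metric}, {cfg.knn.weighting}-weighted",
            f"boosting: {cfg.boosting.round_count} rounds, depth {cfg.boosting.max_depth}, "
            f"lr {cfg.boosting.learning_rate}",
            f"forest: {cfg.forest.tree_count} trees, {cfg.forest.feature_subsample} features, "
            f"{cfg.forest.split_criterion}",
            f"combiner: {'soft voting' if cfg.soft_voting else 'logistic meta-learner (L2), 5-fold out-of-fold'}",
            "-" * 64,
            f"{'metric':<12}{'train':>10}{'validation':>12}",
        ]
        for name in ("accuracy", "precision", "recall", "f1", "roc_auc"):
            t = getattr(self.train_metrics, name)
            v = getattr(self.validation_metrics, name)
            fmt = lambda x: "   n/a" if x is None else f"{x:.4f}"
            lines.append(f"{name:<12}{fmt(t):>10}{fmt(v):>12}")
        return "\n".join(lines)

    def save(self, model_path, sidecar_path=None) -> None:
        """Persist the fitted stack (pickle) plus a JSON sidecar with the
        config, manifest and library versions."""
        import sklearn
        import xgboost

        with open(model_path, "wb") as fh:
            pickle.dump(self.stack, fh)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "config": self.config.as_dict(),
                        "feature_manifest": self.feature_manifest,
                        "seed": self.config.seed,
                        "versions": {"sklearn": sklearn.__version__, "xgboost": xgboost.__version__},
                        "train_metrics": self.train_metrics.as_dict(),
                        "validation_metrics": self.validation_metrics.as_dict(),
                    },
                    fh,
                    indent=2,
                )
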