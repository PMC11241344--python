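"""Descriptor-space reduction: correlation pruning + cross-validated lasso.

The two-stage scheme first removes redundancy (any column with |Pearson r|
above a threshold against an already-kept column is dropped, scanning in
input order), then ranks the survivors with an L1-penalized least-squares
fit of the 0/1 label (lasso) over a geometric penalty grid chosen by k-fold
cross-validation, keeping at most ``max_features`` nonzero-coefficient
descriptors.  Columns are standardized internally, so the selected set is
invariant to affine rescaling of any input column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .descriptors import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    kept: list[str] = field(default_factory=list)
    dropped_correlated: dict[str, str] = field(default_factory=dict)  # dropped -> partner
    dropped_zero_variance: list[str] = field(default_factory=list)
    l1_coefficients: dict[str, float] = field(default_factory=dict)
    penalty: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kept": self.kept,
                    "dropped_correlated": self.dropped_correlated,
                    "dropped_zero_variance": self.dropped_zero_variance,
                    "l1_coefficients": self.l1_coefficients,
                    "penalty": self.penalty,
                },
                fh,
                indent=2,
            )

    def write_feature_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.kept) + "\n")


def correlation_prune(m: FeatureMatrix, threshold: float = 0.9) -> tuple[FeatureMatrix, SelectionReport]:
    """Drop zero-variance columns, then any column with |r| > threshold
    against an already-kept column (input order, keep-first)."""
    if len(m) < 2:
        raise ValueError("correlation is undefined on fewer than 2 rows")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    report = SelectionReport()
    X = m.X
    std = X.std(axis=0, ddof=0)
    nonconstant = [c for c in X.columns if std[c] > 0]
    report.dropped_zero_variance = [c for c in X.columns if std[c] == 0]
    corr = X[nonconstant].corr().abs()
    kept: list[str] = []
    for col in nonconstant:
        partner = next((k for k in kept if corr.loc[col, k] > threshold), None)
        if partner is None:
            kept.append(col)
        else:
            report.dropped_correlated[col] = partner
    report.kept = kept
    logger.info(
        "correlation_prune: %d -> %d columns (|r| > %.2f; %d zero-variance)",
        X.shape[1], len(kept), threshold, len(report.dropped_zero_variance),
    )
    return m.select(kept), report


def l1_select(
    m: FeatureMatrix,
    labels: pd.Series | np.ndarray | None = None,
    folds: int = 10,
    max_features: int = 20,
    seed: int = 40,
    logistic: bool = False,
) -> SelectionReport:
    """Cross-validated L1 selection of at most ``max_features`` descriptors.

    A linear lasso on the 0/1 label is the default; ``logistic=True`` swaps
    in an L1-penalized logistic fit.  If more than ``max_features`` survive
    at the CV-optimal penalty, those with largest |coefficient| are kept.
    """
    y = np.asarray(m.y if labels is None else labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("l1_select requires both classes present")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")

    std = m.X.std(axis=0, ddof=0)
    cols = [c for c in m.X.columns if std[c] > 0]
    X = StandardScaler().fit_transform(m.X[cols].to_numpy())
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)

    report = SelectionReport()
    if logistic:
        model = LogisticRegressionCV(
            l1_ratios=[1.0], solver="liblinear", Cs=30, cv=cv, random_state=seed,
            max_iter=5000, scoring="neg_log_loss",
        ).fit(X, y.astype(int))
        coefs = model.coef_.ravel()
        report.penalty = float(1.0 / model.C_[0])
    else:
        model = LassoCV(alphas=50, cv=cv, random_state=seed, max_iter=50000).fit(X, y)
        coefs = model.coef_
        report.penalty = float(model.alpha_)

    nonzero = [(c, float(w)) for c, w in zip(cols, coefs) if w != 0.0]
    if not nonzero:
        # Degenerate (typically signal-free) input: the CV-optimal penalty
        # zeroes every coefficient.  Keep the single column most correlated
        # with the label so downstream models still have an input.
        r = np.abs([np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])])
        fallback = cols[int(np.nanargmax(r))]
        logger.warning("l1_select: no nonzero coefficients; falling back to %r", fallback)
        nonzero = [(fallback, 0.0)]
    nonzero.sort(key=lambda cw: -abs(cw[1]))
    chosen = nonzero[:max_features]
    # report in original column order for determinism
    chosen_names = {c for c, _ in chosen}
    report.kept = [c for c in cols if c in chosen_names]
    report.l1_coefficients = {c: w for c, w in nonzero}
    logger.info(
        "l1_select: %d nonzero at penalty %.4g, keeping %d (cap %d)",
        len(nonzero), report.penalty, len(report.kept), max_features,
    )
    return report


def select_features(
    m: FeatureMatrix,
    corr_threshold: float = 0.9,
    folds: int = 10,
    max_features: int = 20,
    seed: int = 40,
    logistic: bool = False,
) -> tuple[FeatureMatrix, SelectionReport]:
    """Correlation pruning followed by L1 selection; returns the reduced matrix."""
    pruned, prune_report = correlation_prune(m, corr_threshold)
    report = l1_select(pruned, folds=folds, max_features=max_features, seed=seed, logistic=logistic)
    report.dropped_correlated = prune_report.dropped_correlated
    report.dropped_zero_variance = prune_report.dropped_zero_variance
    return m.select(report.kept), report
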