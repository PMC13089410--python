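"""Random-forest prediction of gene dispensability and LoF tolerance.

Per-gene features (LoF frequency, tissue breadth, normalized histone-mark
means, sequence-composition scalars) predict a binary label — pan-genome
dispensability or population LoF tolerance.  Training uses 10-fold
cross-validation with class-balanced training sets: in each fold the
majority class is randomly downsampled to the minority class size, the
held-out fold is left untouched, and out-of-fold scores are aggregated
into a single ROC.  Feature importance is the Mean Decrease in Gini
averaged across folds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

DEFAULT_NTREE = 500
DEFAULT_FOLDS = 10

DISPENSABILITY_LABEL_MAPS = {
    # default: only core genes count as indispensable
    "core_only": {"core": 0, "softcore": 1, "dispensable": 1, "private": 1},
    # robustness alternative: softcore grouped with core
    "core_softcore": {"core": 0, "softcore": 0, "dispensable": 1, "private": 1},
}


def normalize_histone(track: np.ndarray | pd.Series) -> np.ndarray:
    """Min-max scale a raw signal track to [0, 1].

    Affine-invariant: shifting or scaling the raw track leaves the output
    unchanged.  A constant track carries no information and maps to zeros
    with a warning.
    """
    x = np.asarray(track, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("histone signal contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant histone track normalized to all zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def gene_mean_signal(normalized_track: np.ndarray,
                     gene_intervals: Dict[str, Tuple[int, int]]) -> pd.Series:
    """Average a normalized per-bp track over each gene's genomic region."""
    out = {g: float(np.mean(normalized_track[s:e])) for g, (s, e) in gene_intervals.items()}
    return pd.Series(out)


def label_tolerance(frequency_table: pd.DataFrame) -> pd.Series:
    """LoF-tolerant (1) iff the gene's population LoF frequency exceeds zero."""
    return (frequency_table["lof_frequency"] > 0).astype(int)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC via the rank statistic (Mann-Whitney with midrank ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CVReport:
    """Out-of-fold scores, AUC, Gini importances, fold assignments, seeds."""

    oof_scores: pd.Series  # per-gene out-of-fold positive-class probability
    labels: pd.Series
    auc: float
    gini_importance: pd.Series  # mean decrease Gini averaged across folds
    fold_assignment: pd.Series
    seed: int
    rf_params: Dict = field(default_factory=dict)

    def summary(self) -> str:
        top = self.gini_importance.sort_values(ascending=False).head(10)
        lines = [
            "Balanced cross-validated random forest",
            "=" * 48,
            f"genes:      {len(self.labels)}",
            f"positives:  {int(self.labels.sum())}",
            f"folds:      {int(self.fold_assignment.max()) + 1}",
            f"AUC-ROC:    {self.auc:.3f}",
            "-" * 48,
            "top features by Mean Decrease Gini:",
            top.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def _downsample_balanced(idx: np.ndarray, y: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Indices of a training subset with exactly equal class counts."""
    classes, counts = np.unique(y[idx], return_counts=True)
    if len(classes) < 2:
        raise ValueError("training fold lost a class; cannot balance")
    n_min = counts.min()
    keep = []
    for c in classes:
        members = idx[y[idx] == c]
        keep.append(rng.choice(members, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def balanced_cv_rf(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: int = DEFAULT_FOLDS,
    ntree: int = DEFAULT_NTREE,
    seed: int = 0,
) -> CVReport:
    """Balanced 10-fold cross-validated random forest.

    Stratified folds guarantee both classes in every training split; the
    majority class is downsampled (training only) to match the minority.
    Every gene is held out exactly once; out-of-fold scores are pooled
    into one ROC curve.
    """
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index).to_numpy()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if pd.isna(y).any():
        raise ValueError("missing labels")
    y = y.astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    importances = np.zeros((folds, X.shape[1]))
    rf_params = dict(n_estimators=ntree, random_state=seed)
    for k, (train, test) in enumerate(skf.split(X, y)):
        bal = _downsample_balanced(train, y, rng)
        clf = RandomForestClassifier(n_estimators=ntree, random_state=seed + k,
                                     n_jobs=1)
        clf.fit(X[bal], y[bal])
        pos = list(clf.classes_).index(1)
        oof[test] = clf.predict_proba(X[test])[:, pos]
        fold_of[test] = k
        importances[k] = clf.feature_importances_
    assert not np.isnan(oof).any()
    auc = roc_auc(oof, y)
    return CVReport(
        oof_scores=pd.Series(oof, index=features.index),
        labels=pd.Series(y, index=features.index),
        auc=auc,
        gini_importance=pd.Series(importances.mean(axis=0), index=features.columns),
        fold_assignment=pd.Series(fold_of, index=features.index),
        seed=seed,
        rf_params=rf_params,
    )


@dataclass
class ModelBundle:
    """A forest trained on one species' full (balanced) data."""

    classifier: RandomForestClassifier
    feature_names: list


def train_full_balanced(
    features: pd.DataFrame,
    labels: pd.Series,
    ntree: int = DEFAULT_NTREE,
    seed: int = 0,
) -> ModelBundle:
    """Train on all available data after balancing (for cross-species use)."""
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index).to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    bal = _downsample_balanced(np.arange(len(y)), y, rng)
    clf = RandomForestClassifier(n_estimators=ntree, random_state=seed, n_jobs=1)
    clf.fit(X[bal], y[bal])
    return ModelBundle(classifier=clf, feature_names=list(features.columns))


def cross_species_apply(
    bundle: ModelBundle,
    features_b: pd.DataFrame,
    labels_b: Optional[pd.Series] = None,
) -> Tuple[pd.Series, Optional[float]]:
    """Score a second species' genes with a model trained on the first.

    Features are aligned by name; a mismatch raises with the differing
    columns listed.  Returns per-gene scores and, when labels are given,
    the cross-species AUC.
    """
    missing = set(bundle.feature_names) - set(features_b.columns)
    extra = set(features_b.columns) - set(bundle.feature_names)
    if missing:
        raise ValueError(f"feature mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
    X = features_b[bundle.feature_names].to_numpy(dtype=float)
    pos = list(bundle.classifier.classes_).index(1)
    scores = pd.Series(bundle.classifier.predict_proba(X)[:, pos],
                       index=features_b.index)
    auc = None
    if labels_b is not None:
        auc = roc_auc(scores.to_numpy(), labels_b.reindex(features_b.index).to_numpy())
    return scores, auc
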