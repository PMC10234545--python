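"""Random-forest training/prediction and rank-based evaluation metrics.

lncRNA is the positive class throughout. The AUC uses the rank-sum form

    AUC = (sum of positive ranks - 0.5*M*(1+M)) / (M*N)

with ascending midranks over all scores (ties get the average rank), M
positives and N negatives, which equals the Mann-Whitney pair-counting
statistic with half credit for ties. ACC/SEN/SPE/MCC come from the
confusion counts at a probability threshold (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .feature_assembly import PipelineConfig

POSITIVE_LABEL = "lncRNA"
NEGATIVE_LABEL = "pcRNA"
SCHEMA_VERSION = "lncwave-features-1"

FOREST_DEFAULTS = dict(n_estimators=500, max_features="sqrt")


class SchemaMismatchError(ValueError):
    """Feature table or config does not match the trained bundle's snapshot."""


@dataclass
class ModelBundle:
    """Trained forest plus the exact preprocessing state for reproducible use."""

    forest: RandomForestClassifier
    feature_names: list[str]
    pipeline_config: dict
    seed: int
    schema_version: str = SCHEMA_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path, compress=0)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise SchemaMismatchError(f"{path} is not a lncwave model bundle")
        return bundle

    def check_features(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise SchemaMismatchError(f"feature table missing columns {missing}")

    def check_config(self, config: PipelineConfig) -> None:
        snap = config.snapshot()
        for key, val in self.pipeline_config.items():
            if snap.get(key) != val:
                raise SchemaMismatchError(
                    f"pipeline config field {key!r} differs from the trained "
                    f"bundle ({snap.get(key)!r} != {val!r})"
                )


def _binary_labels(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    known = np.isin(arr, (POSITIVE_LABEL, NEGATIVE_LABEL))
    if not known.all():
        bad = sorted(set(arr[~known]))
        raise ValueError(f"labels must be lncRNA/pcRNA, got {bad}")
    return (arr == POSITIVE_LABEL).astype(int)


def train(table: pd.DataFrame, labels: Sequence[str],
          feature_names: Optional[list[str]] = None,
          config: Optional[PipelineConfig] = None,
          seed: int = 0, **forest_params) -> ModelBundle:
    """Fit the forest on an (already screened) feature table.

    ``feature_names`` is the retained set from the correlation screen; it is
    frozen into the bundle and reused verbatim at prediction time.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    config = config or PipelineConfig()
    feature_names = list(feature_names if feature_names is not None
                         else (c for c in table.columns if c != "label"))
    params = {**FOREST_DEFAULTS, **forest_params}
    forest = RandomForestClassifier(random_state=seed, **params)
    forest.fit(table[feature_names].to_numpy(dtype=float), y)
    return ModelBundle(forest, feature_names, config.snapshot(), seed)


def predict(model: ModelBundle, table: pd.DataFrame,
            threshold: float = 0.5) -> pd.DataFrame:
    """Per-row lncRNA probability and thresholded label."""
    model.check_features(table)
    X = table[model.feature_names].to_numpy(dtype=float)
    pos_col = list(model.forest.classes_).index(1)
    prob = model.forest.predict_proba(X)[:, pos_col]
    label = np.where(prob >= threshold, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame({"prob_lncRNA": prob, "label": label},
                        index=table.index)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    mcc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "acc": self.acc, "sen": self.sen, "spe": self.spe,
                "mcc": self.mcc, "auc": self.auc}


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-sum AUC with midranks for tied scores; NaN if a class is absent."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    m = int(y_true.sum())
    n = len(y_true) - m
    if m == 0 or n == 0:
        warnings.warn("AUC undefined: one class absent", stacklevel=2)
        return float("nan")
    ranks = rankdata(scores)  # ascending midranks
    pos_rank_sum = ranks[y_true == 1].sum()
    return float((pos_rank_sum - 0.5 * m * (1 + m)) / (m * n))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """ACC, SEN, SPE, MCC from confusion counts (NaN where undefined)."""
    total = tp + fn + tn + fp
    acc = (tp + tn) / total if total else float("nan")
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC undefined: degenerate confusion matrix", stacklevel=2)
        mcc = float("nan")
    else:
        mcc = float((tp * tn - fp * fn) / np.sqrt(float(denom)))
    return {"acc": acc, "sen": sen, "spe": spe, "mcc": mcc}


def evaluate(labels: Sequence[str] | np.ndarray, scores: Sequence[float],
             threshold: float = 0.5) -> EvalMetrics:
    """All five metrics from true labels and lncRNA probabilities."""
    arr = np.asarray(labels)
    y = _binary_labels(arr) if arr.dtype.kind in "UOS" else arr.astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    cm = confusion_metrics(tp, fn, tn, fp)
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn, auc=rank_auc(y, scores), **cm)


def cross_validate(table: pd.DataFrame, labels: Sequence[str],
                   feature_names: Optional[list[str]] = None,
                   n_splits: int = 5, seed: int = 0,
                   **forest_params) -> tuple[EvalMetrics, np.ndarray]:
    """Stratified k-fold CV; returns pooled out-of-fold metrics and scores."""
    from sklearn.model_selection import StratifiedKFold

    y = _binary_labels(labels)
    feature_names = list(feature_names if feature_names is not None
                         else (c for c in table.columns if c != "label"))
    X = table[feature_names].to_numpy(dtype=float)
    oof = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    params = {**FOREST_DEFAULTS, **forest_params}
    for train_idx, test_idx in skf.split(X, y):
        forest = RandomForestClassifier(random_state=seed, **params)
        forest.fit(X[train_idx], y[train_idx])
        pos_col = list(forest.classes_).index(1)
        oof[test_idx] = forest.predict_proba(X[test_idx])[:, pos_col]
    return evaluate(y, oof), oof
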