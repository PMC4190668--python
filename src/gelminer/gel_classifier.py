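"""Random-forest gel-segment classifier with a threshold cascade.

A single 75-tree forest is trained once; the three operating points are
read off the same forest by thresholding the fraction of trees that vote
"gel": 0.15 (high recall, used to expand panel groups), 0.30 (balanced)
and 0.60 (high precision, used to seed panel groups). Class imbalance is
handled by thresholding only — no resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "GelClassifier",
    "EvalReport",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_N_TREES",
    "train",
    "evaluate",
    "save_model",
    "load_model",
]

DEFAULT_N_TREES = 75
DEFAULT_THRESHOLDS = {"high_recall": 0.15, "balanced": 0.30, "high_precision": 0.60}
_MODEL_FORMAT_VERSION = 1


@dataclass
class GelClassifier:
    """A forest of fitted binary trees plus calibrated vote thresholds.

    Trees must predict integer class labels where 1 means "gel"; the
    score of a sample is the fraction of trees voting 1, which makes the
    printed thresholds directly meaningful.
    """

    trees: list[DecisionTreeClassifier]
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    training_meta: dict = field(default_factory=dict)
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        t = self.thresholds
        if not 0.0 < t["high_recall"] < t["balanced"] < t["high_precision"] < 1.0:
            raise ValueError(f"thresholds must satisfy 0 < HR < balanced < HP < 1: {t}")
        if not self.trees:
            raise ValueError("empty forest")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def threshold(self, operating_point: str) -> float:
        try:
            return self.thresholds[operating_point]
        except KeyError:
            raise ValueError(
                f"unknown operating point {operating_point!r}; "
                f"expected one of {sorted(self.thresholds)}"
            ) from None

    def score_many(self, X: np.ndarray) -> np.ndarray:
        """Vote fraction per row: fraction of trees predicting gel."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        votes = np.zeros(X.shape[0])
        for tree in self.trees:
            votes += (tree.predict(X) == 1).astype(float)
        return votes / self.n_trees

    def score(self, fv) -> float:
        """Vote fraction in [0, 1] for a single feature vector."""
        return float(self.score_many(_as_row(fv))[0])

    def classify(self, fv, operating_point: str = "balanced") -> bool:
        """True iff score(fv) >= the operating point's threshold."""
        return self.score(fv) >= self.threshold(operating_point)

    def classify_many(self, X: np.ndarray, operating_point: str = "balanced") -> np.ndarray:
        return self.score_many(X) >= self.threshold(operating_point)


def _as_row(fv) -> np.ndarray:
    arr = fv.to_array() if hasattr(fv, "to_array") else np.asarray(fv, dtype=np.float64)
    return arr.reshape(1, -1)


def train(
    X: np.ndarray,
    y: Sequence[bool | int],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    thresholds: dict[str, float] | None = None,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> GelClassifier:
    """Fit the forest on labeled feature vectors.

    Deterministic given ``seed``. Raises on single-class input. Forest
    hyperparameters beyond the tree count are scikit-learn defaults and
    are recorded in ``training_meta``.
    """
    X = np.asarray(X, dtype=np.float64)
    y_arr = np.asarray(y).astype(int)
    classes = np.unique(y_arr)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if not np.all(np.isin(classes, [0, 1])):
        raise ValueError("labels must be binary (0/1 or bool)")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y_arr)
    # forest.classes_ == [0, 1] because labels are coerced to 0/1 ints,
    # so each estimator predicts gel as class 1 directly.
    meta = {
        "n_samples": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "class_balance": float(y_arr.mean()),
        "seed": int(seed),
        "n_trees": int(n_trees),
        "forest_params": {
            k: v
            for k, v in forest.get_params().items()
            if k in ("criterion", "max_depth", "max_features", "min_samples_split")
        },
    }
    return GelClassifier(
        trees=list(forest.estimators_),
        thresholds=dict(thresholds or DEFAULT_THRESHOLDS),
        training_meta=meta,
        feature_names=tuple(feature_names),
    )


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f_score: float
    roc_auc: float | None
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "roc_auc": self.roc_auc,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
        }


def evaluate(
    clf: GelClassifier,
    X: np.ndarray,
    y: Sequence[bool | int],
    operating_point: str = "balanced",
) -> EvalReport:
    """Precision/recall/F and ROC-AUC on a labeled test set.

    The confusion counts use the requested operating point; the ROC
    curve sweeps all thresholds over the vote-fraction scores. AUC is
    None when the test set is single-class.
    """
    X = np.asarray(X, dtype=np.float64)
    y_arr = np.asarray(y).astype(bool)
    if y_arr.size == 0:
        raise ValueError("empty test set")
    scores = clf.score_many(X)
    pred = scores >= clf.threshold(operating_point)
    tp = int(np.sum(pred & y_arr))
    fp = int(np.sum(pred & ~y_arr))
    fn = int(np.sum(~pred & y_arr))
    tn = int(np.sum(~pred & ~y_arr))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc = float(roc_auc_score(y_arr, scores)) if 0 < y_arr.sum() < y_arr.size else None
    return EvalReport(
        precision=precision,
        recall=recall,
        f_score=f_score,
        roc_auc=auc,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def save_model(clf: GelClassifier, path: str | Path) -> None:
    """Persist forest (joblib binary) + JSON sidecar with metadata."""
    path = Path(path)
    joblib.dump(clf.trees, path)
    sidecar = {
        "format_version": _MODEL_FORMAT_VERSION,
        "feature_names": list(clf.feature_names),
        "thresholds": clf.thresholds,
        "training_meta": clf.training_meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
    )


def load_model(path: str | Path, feature_names: Sequence[str] = FEATURE_NAMES) -> GelClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text("utf-8"))
    if sidecar.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {sidecar.get('format_version')}")
    if list(sidecar["feature_names"]) != list(feature_names):
        raise ValueError("model feature schema does not match current feature set")
    trees = joblib.load(path)
    return GelClassifier(
        trees=trees,
        thresholds={k: float(v) for k, v in sidecar["thresholds"].items()},
        training_meta=sidecar["training_meta"],
        feature_names=tuple(sidecar["feature_names"]),
    )
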