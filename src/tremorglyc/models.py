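"""Window-level classifiers, majority-vote ensemble and sequence aggregation.

Three classifiers at fixed hyperparameters — a 100-tree random forest of
depth 5 with Gini splits, k-nearest neighbours with K=27 and Euclidean
distance, and an RBF-kernel SVM with C=1 — each thresholded at probability
0.5, combined by majority vote.  Consecutive window predictions are
aggregated into a sequence decision (default 9 windows, about 15 s):
hypoglycemic when at least half the windows are predicted hypoglycemic.

Distance- and kernel-based members (KNN, SVM) standardise features with
training-set statistics; the features mix units (g, g^2, g^2/Hz, Hz,
counts) and would otherwise be dominated by scale.  The SVM exposes Platt-
calibrated probabilities so that the single 0.5 threshold applies to all
three members.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .labeling import HYPO, NONHYPO

log = logging.getLogger(__name__)

MODEL_KINDS = ("random_forest", "knn", "svm")


@dataclass(frozen=True)
class ModelSpec:
    """One member classifier and its fixed hyperparameters."""

    kind: str
    n_trees: int = 100
    max_depth: int = 5
    criterion: str = "gini"
    k: int = 27
    C: float = 1.0
    standardize: bool | None = None   # default: True for knn/svm, False for RF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if not self.C > 0:
            raise ValueError("C must be positive")

    @property
    def wants_scaling(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.kind in ("knn", "svm")


def default_member_specs(seed: int = 0) -> list[ModelSpec]:
    """The three default ensemble members."""
    return [ModelSpec("random_forest", seed=seed),
            ModelSpec("knn", seed=seed),
            ModelSpec("svm", seed=seed)]


@dataclass(frozen=True)
class EnsembleSpec:
    """Majority-vote ensemble over an odd number of members."""

    members: tuple[ModelSpec, ...] = field(
        default_factory=lambda: tuple(default_member_specs()))
    rule: str = "majority"

    def __post_init__(self) -> None:
        if len(self.members) % 2 == 0:
            raise ValueError("majority voting needs an odd member count")


@dataclass(frozen=True)
class SequenceSpec:
    """Sequence aggregation: hypo when >= `fraction` of windows are hypo."""

    seq_len: int = 9
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")

    @property
    def min_hypo(self) -> int:
        """Smallest hypo count that triggers a hypo sequence decision."""
        return math.ceil(self.fraction * self.seq_len)


def _build_estimator(spec: ModelSpec):
    if spec.kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=spec.n_trees, max_depth=spec.max_depth,
            criterion=spec.criterion, random_state=spec.seed, n_jobs=1)
    elif spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    else:
        # Platt-calibrated probabilities so the 0.5 threshold applies
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", C=spec.C, random_state=spec.seed),
            method="sigmoid", cv=5, ensemble=False)
    if spec.wants_scaling:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class FittedModel:
    """A trained member with its feature catalog and spec."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]

    @property
    def forest(self) -> RandomForestClassifier:
        """The underlying random forest (for impurity-based importance)."""
        est = self.estimator
        if isinstance(est, Pipeline):
            est = est.named_steps["clf"]
        if not isinstance(est, RandomForestClassifier):
            raise TypeError(f"{self.spec.kind} is not a random forest")
        return est


def train(spec: ModelSpec, features: pd.DataFrame | np.ndarray,
          labels: np.ndarray) -> FittedModel:
    """Fit one member on a (possibly oversampled) training partition.

    Refuses single-class training sets.  Deterministic given the spec seed.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    est = _build_estimator(spec)
    est.fit(X, labels)
    return FittedModel(spec, est, names)


def predict_window(fitted: FittedModel, features: pd.DataFrame | np.ndarray,
                   threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-window classes and hypo-probability scores.

    A window is called hypoglycemic when its score is >= the threshold
    (the boundary score of exactly 0.5 counts as hypo).  Raises
    ``ValueError`` on a feature-column mismatch.
    """
    if isinstance(features, pd.DataFrame):
        if list(features.columns) != fitted.feature_names:
            raise ValueError("feature columns do not match the training catalog")
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(fitted.feature_names):
            raise ValueError("feature width does not match the training catalog")
    proba = fitted.estimator.predict_proba(X)
    hypo_col = list(fitted.estimator.classes_).index(HYPO)
    scores = proba[:, hypo_col]
    classes = np.where(scores >= threshold, HYPO, NONHYPO)
    return classes, scores


def majority_vote(votes: np.ndarray) -> np.ndarray | int:
    """Majority class over an odd number of member votes.

    ``votes`` is either a 1-D vector (one instance) or a 2-D array of
    shape (n_instances, n_members); raises ``ValueError`` for an even
    member count.
    """
    votes = np.asarray(votes)
    n = votes.shape[-1]
    if n % 2 == 0:
        raise ValueError("majority voting needs an odd number of votes")
    hypo_votes = (votes == HYPO).sum(axis=-1)
    out = np.where(hypo_votes > n / 2, HYPO, NONHYPO)
    return int(out) if votes.ndim == 1 else out


def sequential_classify(window_preds: np.ndarray,
                        spec: SequenceSpec | None = None) -> int:
    """Aggregate an ordered run of window predictions into one decision.

    Hypo iff at least ``ceil(fraction * seq_len)`` windows are predicted
    hypo — for the default 9-window sequences, at least 5.
    """
    spec = spec or SequenceSpec()
    window_preds = np.asarray(window_preds)
    if window_preds.shape[0] != spec.seq_len:
        raise ValueError(
            f"expected {spec.seq_len} window predictions, got {window_preds.shape[0]}")
    return HYPO if int((window_preds == HYPO).sum()) >= spec.min_hypo else NONHYPO


def save_model(fitted: FittedModel, path) -> None:
    """Persist a fitted member with its spec and feature catalog."""
    joblib.dump({"spec": fitted.spec, "feature_names": fitted.feature_names,
                 "estimator": fitted.estimator}, path)


def load_model(path) -> FittedModel:
    obj = joblib.load(path)
    return FittedModel(obj["spec"], obj["estimator"], obj["feature_names"])
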