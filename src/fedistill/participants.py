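"""Heterogeneous local models and their class-probability outputs.

Five model kinds, each matched to a participant's resource profile:
random forest (large hospital), k-nearest neighbours (kiosk),
gradient-boosted trees (regional clinic), decision tree (community
clinic) and a linear-kernel SVM (wearable tracker).  All kinds emit a
soft-label matrix — one probability-simplex row per instance — which is
the only artifact exchanged between participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from fedistill.synthetic_cohort import ParticipantProfile


class NotFittedError(RuntimeError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass
class SoftLabelMatrix:
    """Per-instance class-probability rows from one participant at one round."""

    participant_id: int
    round: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D matrix")
        if (self.probs < -1e-12).any():
            raise ValueError("probabilities must be nonnegative")
        if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each row must sum to 1")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class LocalModel:
    profile: ParticipantProfile
    fitted_state: object | None = None
    last_validation_accuracy: float | None = None

    @property
    def is_fitted(self) -> bool:
        return self.fitted_state is not None


def _make_estimator(profile: ParticipantProfile, seed: int = 0):
    hp = dict(profile.hyperparameters)
    kind = profile.model_kind
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 130)),
            max_depth=hp.get("max_depth", 15),
            max_features=hp.get("max_features", 0.75),
            random_state=seed, n_jobs=1)
    if kind == "knn":
        return KNeighborsClassifier(
            n_neighbors=int(hp.get("n_neighbors", 5)),
            algorithm=hp.get("algorithm", "auto"))
    if kind == "gradient_boosted_trees":
        return XGBClassifier(
            learning_rate=float(hp.get("learning_rate", 0.01)),
            max_depth=int(hp.get("max_depth", 10)),
            n_estimators=int(hp.get("n_estimators", 180)),
            random_state=seed, n_jobs=1, eval_metric="logloss")
    if kind == "decision_tree":
        return DecisionTreeClassifier(
            max_depth=hp.get("max_depth", None),
            criterion=hp.get("criterion", "gini"),
            random_state=seed)
    if kind == "linear_svm":
        # no native probabilities: soft labels come from a logistic squashing
        # of the signed margin, which is deterministic, unlike sklearn's
        # internal Platt cross-validation.
        return SVC(kernel="linear", C=float(hp.get("C", 1.0)), random_state=seed)
    raise ValueError(f"unknown model_kind: {kind!r}")


def build_model(profile: ParticipantProfile) -> LocalModel:
    """Configure (but do not fit) the local model for a roster profile."""
    _make_estimator(profile)  # validate kind and hyperparameters eagerly
    return LocalModel(profile=profile)


def train_local(model: LocalModel, shard_features: np.ndarray, shard_labels: np.ndarray,
                pseudo_features: np.ndarray | None = None,
                pseudo_labels: np.ndarray | None = None,
                seed: int = 0) -> LocalModel:
    """Fit the local model on its private shard plus current pseudo-labels.

    The pseudo-labeled pool (confident global predictions on the shared
    unlabeled set) is appended to the shard for this fit only; it is
    replaced, not accumulated, across rounds by the orchestrator.
    """
    X = np.asarray(shard_features, dtype=float)
    y = np.asarray(shard_labels, dtype=np.int64)
    if len(X) == 0:
        raise TrainingError("training shard is empty")
    if pseudo_features is not None and pseudo_labels is not None and len(pseudo_labels) > 0:
        X = np.vstack([X, np.asarray(pseudo_features, dtype=float)])
        y = np.concatenate([y, np.asarray(pseudo_labels, dtype=np.int64)])
    if len(np.unique(y)) < 2:
        raise TrainingError(
            f"participant {model.profile.id}: training labels contain a single "
            f"class ({y[0]}); a binary classifier cannot be fitted")
    est = _make_estimator(model.profile, seed=seed)
    est.fit(X, y)
    model.fitted_state = est
    return model


def predict_soft(model: LocalModel, features: np.ndarray) -> SoftLabelMatrix:
    """Class-probability rows for each instance (binary: columns 0, 1).

    The linear SVM has no native probabilities; its signed decision margin
    is squashed through a logistic sigmoid, which is a monotone calibrated
    mapping onto the simplex.
    """
    if not model.is_fitted:
        raise NotFittedError(f"participant {model.profile.id} model is not fitted")
    X = np.asarray(features, dtype=float)
    est = model.fitted_state
    if model.profile.model_kind == "linear_svm":
        margin = est.decision_function(X)
        p1 = expit(margin)
        probs = np.column_stack([1.0 - p1, p1])
    else:
        probs = np.asarray(est.predict_proba(X), dtype=float)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return SoftLabelMatrix(participant_id=model.profile.id, round=-1, probs=probs)


def evaluate(model_or_preds, features_or_truth, labels=None) -> dict:
    """Accuracy, precision, recall and F1 with the diabetic class (label 1)
    as positive.

    Accepts either ``evaluate(model, features, labels)`` or
    ``evaluate(predictions, truth)``.  A zero denominator (no predicted or
    no actual positives) reports the metric as 0 and sets ``degenerate``.
    """
    if labels is None:
        preds = np.asarray(model_or_preds, dtype=np.int64)
        truth = np.asarray(features_or_truth, dtype=np.int64)
    else:
        model = model_or_preds
        if not model.is_fitted:
            raise NotFittedError("model is not fitted")
        soft = predict_soft(model, features_or_truth)
        preds = soft.probs.argmax(axis=1)
        truth = np.asarray(labels, dtype=np.int64)
    if preds.shape != truth.shape:
        raise ValueError("predictions and labels must have the same length")

    tp = int(((preds == 1) & (truth == 1)).sum())
    fp = int(((preds == 1) & (truth == 0)).sum())
    fn = int(((preds == 0) & (truth == 1)).sum())
    tn = int(((preds == 0) & (truth == 0)).sum())
    degenerate = False
    accuracy = (tp + tn) / len(truth)
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if degenerate:
        warnings.warn("zero-denominator metric reported as 0", UserWarning)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "degenerate": degenerate}
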