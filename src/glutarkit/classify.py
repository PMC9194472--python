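"""Training, scoring and persistence of the five classifier families.

The comparison grid covers gradient-boosted trees (XGBoost), AdaBoost,
RBF-kernel SVM, random forest and a multilayer perceptron.  Each is used
with its library defaults plus a fixed seed — no hyperparameter search —
and all expose scores as positive-class probabilities in [0, 1] so the
evaluation protocols treat them interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

#: On-disk model format version; bumped on any incompatible change.
MODEL_FORMAT_VERSION = 1

ALGORITHMS = ("gbt", "adaboost", "svm-rbf", "rf", "mlp")


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice, hyperparameter overrides and seed."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {', '.join(ALGORITHMS)}")


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "gbt":
        return XGBClassifier(random_state=spec.seed, n_jobs=1,
                             eval_metric="logloss", **hp)
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "svm-rbf":
        # margins are mapped through a sigmoid in predict_scores, keeping
        # the fit deterministic (no internal Platt-scaling CV)
        return SVC(kernel="rbf", random_state=spec.seed, **hp)
    if spec.algorithm == "rf":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.algorithm == "mlp":
        return MLPClassifier(random_state=spec.seed, **hp)
    raise AssertionError(spec.algorithm)


@dataclass
class TrainedModel:
    """A fitted predictor plus the feature-name fingerprint it was trained on."""

    estimator: object
    feature_names: tuple[str, ...]
    spec: ModelSpec

    def _check_fingerprint(self, feature_names) -> None:
        if feature_names is not None and tuple(feature_names) != self.feature_names:
            got, want = set(feature_names), set(self.feature_names)
            missing = sorted(want - got)[:5]
            extra = sorted(got - want)[:5]
            detail = []
            if missing:
                detail.append(f"missing {missing}")
            if extra:
                detail.append(f"unexpected {extra}")
            if not detail:
                detail.append("same columns in a different order")
            raise ValueError("feature fingerprint mismatch: " + "; ".join(detail))


def train(features: np.ndarray, labels, spec: ModelSpec,
          feature_names=None) -> TrainedModel:
    """Fit one classifier; deterministic under the spec's seed.

    Features must be a finite (n, d) matrix with both classes present in
    ``labels``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError(f"feature matrix {X.shape} does not match {len(y)} labels")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains NaN or infinite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _build_estimator(spec)
    est.fit(X, y)
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"f{i}" for i in range(X.shape[1]))
    return TrainedModel(est, names, spec)


def predict_scores(model: TrainedModel, features: np.ndarray,
                   feature_names=None) -> np.ndarray:
    """Positive-class scores in [0, 1], one per row.

    SVM margins are passed through a logistic sigmoid (a strictly
    monotone map, so ranking metrics are unaffected and thresholding at
    0.5 corresponds to the margin's sign).
    """
    model._check_fingerprint(feature_names)
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return np.empty(0)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"{X.shape[1]} feature columns, model expects {len(model.feature_names)}")
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return expit(est.decision_function(X))


def predict_labels(model: TrainedModel, features, feature_names=None,
                   threshold: float = 0.5) -> np.ndarray:
    """Hard 0/1 labels by thresholding the scores (default 0.5)."""
    return (predict_scores(model, features, feature_names) >= threshold).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model with an embedded spec manifest."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": model.spec,
        "feature_names": model.feature_names,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; refuses other versions."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / not a joblib file
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a glutarkit model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(this build reads version {MODEL_FORMAT_VERSION})")
    return TrainedModel(payload["estimator"], tuple(payload["feature_names"]),
                        payload["spec"])
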