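"""Neural-network classifiers for maneuver class and injury grade.

Two classifier kinds share one implementation:

* ``class`` — predicts the maneuver execution class (1..8) from the
  class feature set of a test;
* ``grade`` — predicts the ACL injury grade (0..3) from the grade feature
  set, with one model fitted per maneuver class (classes 2..7).  Classes 1
  and 8 are executions furthest from the standardized maneuver and are
  excluded from grading altogether.

Architecture: feed-forward MLP with two hidden layers (32, 16), ReLU,
softmax output, cross-entropy loss, Adam (lr 1e-3, batch 32, <= 500
epochs), early stopping on a 20% validation split (patience 25).  Inputs
are z-scored with statistics of the training set only.  A fixed seed
governs initialization, shuffling and the validation split, so training is
reproducible: identical (data, seed) gives identical predictions.

Training is delegated to scikit-learn's MLPClassifier; inference runs an
explicit forward pass over the serialized weights, so a model restored
from JSON is a pure function independent of the training stack (the two
paths are asserted equal in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPClassifier

from .features import CLASS_FEATURES, GRADE_FEATURES

__all__ = [
    "TrainConfig",
    "ClassifierModel",
    "fit_class_model",
    "fit_grade_model",
    "predict_class",
    "predict_grade",
    "gradable_mask",
    "GRADABLE_CLASSES",
]

GRADABLE_CLASSES = frozenset(range(2, 8))


@dataclass(frozen=True)
class TrainConfig:
    hidden_layers: tuple[int, ...] = (32, 16)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    validation_fraction: float = 0.2
    patience: int = 25
    seed: int = 0


@dataclass
class ClassifierModel:
    """A trained classifier: scaler statistics + MLP weights + metadata.

    ``kind`` is ``"class"`` or ``"grade"``; grade models additionally
    record the maneuver class they were fitted for (``klass``).
    """

    kind: str
    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    seed: int
    klass: int | None = None
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = CLASS_FEATURES if self.kind == "class" else GRADE_FEATURES
        if tuple(self.feature_names) != tuple(expected):
            raise ValueError(f"feature names do not match the registered {self.kind} set")
        if np.any(self.scaler_sd <= 0):
            raise ValueError("standardization sds must be positive")

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Forward pass: z-score, ReLU hidden layers, softmax output."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        a = (X - self.scaler_mean) / self.scaler_sd
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        logits = a @ self.coefs[-1] + self.intercepts[-1]
        if logits.shape[1] == 1:  # binary model: single logistic output
            p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            return np.column_stack([1 - p1, p1])
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Label = argmax probability; ties break to the lowest class index."""
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        payload = {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "classes": [int(c) for c in self.classes],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "coefs": [W.tolist() for W in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "seed": self.seed,
            "klass": self.klass,
            "training_log": self.training_log,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            feature_names=tuple(d["feature_names"]),
            classes=tuple(d["classes"]),
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_sd=np.array(d["scaler_sd"]),
            coefs=[np.array(W) for W in d["coefs"]],
            intercepts=[np.array(b) for b in d["intercepts"]],
            seed=d["seed"],
            klass=d.get("klass"),
            training_log=d.get("training_log", {}),
        )


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    feature_names: tuple[str, ...],
    cfg: TrainConfig,
    klass: int | None = None,
) -> ClassifierModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D feature matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 distinct labels to fit a classifier")
    if X.shape[1] != len(feature_names):
        raise ValueError(f"expected {len(feature_names)} feature columns")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant feature carries no information; leave centered
    Xz = (X - mean) / sd

    # Early stopping needs a validation split large enough to rank epochs
    # reliably; on small per-class datasets it stops prematurely, so those
    # train the full epoch budget instead.
    use_early_stop = X.shape[0] * cfg.validation_fraction >= 50
    net = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layers,
        activation="relu",
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, X.shape[0]),
        max_iter=cfg.max_epochs,
        early_stopping=use_early_stop,
        validation_fraction=cfg.validation_fraction,
        n_iter_no_change=cfg.patience,
        random_state=cfg.seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fits
        net.fit(Xz, y)

    log = {
        "n_train": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "epochs_run": int(net.n_iter_),
        "final_loss": float(net.loss_),
    }
    if use_early_stop and net.validation_scores_ is not None:
        log["best_validation_accuracy"] = float(net.best_validation_score_)

    return ClassifierModel(
        kind=kind,
        feature_names=feature_names,
        classes=tuple(int(c) for c in net.classes_),
        scaler_mean=mean,
        scaler_sd=sd,
        coefs=[np.asarray(W) for W in net.coefs_],
        intercepts=[np.asarray(b) for b in net.intercepts_],
        seed=cfg.seed,
        klass=klass,
        training_log=log,
    )


def fit_class_model(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None) -> ClassifierModel:
    """Fit the 8-way maneuver-class model on class features."""
    return _fit(X, y, "class", CLASS_FEATURES, cfg or TrainConfig())


def fit_grade_model(
    X: np.ndarray, y: np.ndarray, klass: int, cfg: TrainConfig | None = None
) -> ClassifierModel:
    """Fit the injury-grade model for one maneuver class (2..7)."""
    if klass not in GRADABLE_CLASSES:
        raise ValueError(f"grade models exist only for classes 2..7, got {klass}")
    return _fit(X, y, "grade", GRADE_FEATURES, cfg or TrainConfig(), klass=klass)


def predict_class(model: ClassifierModel, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Predict the maneuver class of one test.

    Returns the label and the probability vector over the model's classes.
    """
    if model.kind != "class":
        raise ValueError("model is not a class model")
    proba = model.predict_proba(np.atleast_2d(x))[0]
    return int(model.classes[int(np.argmax(proba))]), proba


def predict_grade(model: ClassifierModel, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Predict the injury grade of one test with a per-class grade model."""
    if model.kind != "grade":
        raise ValueError("model is not a grade model")
    proba = model.predict_proba(np.atleast_2d(x))[0]
    return int(model.classes[int(np.argmax(proba))]), proba


def gradable_mask(labels: np.ndarray) -> np.ndarray:
    """True where a maneuver class is eligible for grading (classes 2..7).

    Classes 1 and 8 are the executions furthest from the standardized
    maneuver; their grade assignments are discarded.
    """
    labels = np.asarray(labels, dtype=int)
    return (labels >= 2) & (labels <= 7)
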