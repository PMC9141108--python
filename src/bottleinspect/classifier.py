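"""Impurity-vs-bubble discrimination: HOG features + RBF-kernel SVM.

Detected target crops vary in size and the two classes differ mainly in
shape and edge structure (bubbles are bright-rim ellipses; impurities are
compact dark specks, hair-like segments or irregular chips), so a
soft-margin SVM with the radial basis kernel k(x, y) = exp(-||x-y||^2 /
2 sigma^2) on HOG descriptors separates them well even from small samples.
The penalty C and kernel width sigma are selected by seeded stratified
k-fold grid search; the sigma grid is centred on the median pairwise
descriptor distance (one decade either way) and class weights are inversely
proportional to class frequency, since training sets are typically
imbalanced toward impurities (about 3:1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import joblib
import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .hog import HOGConfig, HOGDescriptor
from .synthetic import ConfigurationError

LABELS = ("impurity", "bubble")
_MODEL_VERSION = 1


@dataclass
class ConfusionMatrix:
    """Two-class counts and accuracies; counts sum to the evaluated sample count."""

    counts: Dict[str, Dict[str, int]]  # counts[true][pred]
    per_class_accuracy: Dict[str, float]
    overall_accuracy: float
    n_samples: int


class ImpurityBubbleClassifier:
    """sklearn-style classifier over raw grayscale crops.

    ``fit(crops, labels)`` computes HOG descriptors and grid-searches an
    RBF-kernel SVC; ``predict``/``decision_function`` accept crops directly.
    Same data and seed give identical selected hyperparameters and
    predictions.  Fitted attributes: ``svc_`` (the refit SVC), ``sigma_``
    (selected kernel width), ``C_``, ``classes_``.
    """

    def __init__(self, hog_config: HOGConfig | None = None,
                 C_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
                 n_folds: int = 5, seed: int = 0):
        self.hog_config = hog_config or HOGConfig()
        self.C_grid = tuple(C_grid)
        self.n_folds = n_folds
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"hog_config": self.hog_config, "C_grid": self.C_grid,
                "n_folds": self.n_folds, "seed": self.seed}

    def set_params(self, **kwargs) -> "ImpurityBubbleClassifier":
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, crops: Sequence[np.ndarray], labels: Sequence[str]) -> "ImpurityBubbleClassifier":
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        unknown = set(classes) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels {unknown}; expected {LABELS}")
        X = HOGDescriptor(self.hog_config).fit_transform(crops)

        # sigma grid: median pairwise distance, one decade either way
        rng = np.random.default_rng(self.seed)
        idx = rng.choice(len(X), size=min(len(X), 200), replace=False)
        d = pdist(X[idx])
        sigma_med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        sigma_grid = sigma_med * np.array([0.1, 10**-0.5, 1.0, 10**0.5, 10.0])
        gamma_grid = 1.0 / (2.0 * sigma_grid**2)

        cv = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(
            SVC(kernel="rbf", class_weight="balanced"),
            {"C": list(self.C_grid), "gamma": list(gamma_grid)},
            cv=cv, n_jobs=1)
        search.fit(X, labels)
        self.svc_ = search.best_estimator_
        self.C_ = float(search.best_params_["C"])
        self.sigma_ = float(np.sqrt(1.0 / (2.0 * search.best_params_["gamma"])))
        self.classes_ = self.svc_.classes_
        self.config_hash_ = self.hog_config.hash()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "svc_"):
            raise ValueError("classifier is not fitted")

    def transform_crops(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        return HOGDescriptor(self.hog_config).fit_transform(crops)

    def predict(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        self._check_fitted()
        return self.svc_.predict(self.transform_crops(crops))

    def decision_function(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        self._check_fitted()
        return self.svc_.decision_function(self.transform_crops(crops))

    def predict_one(self, crop: np.ndarray, hog_config: HOGConfig | None = None) -> Tuple[str, float]:
        """(label, signed distance to the separating surface) for one crop.

        Refuses to run when the supplied HOG config does not hash-match the
        training config, since descriptors would be incomparable.
        """
        self._check_fitted()
        if hog_config is not None and hog_config.hash() != self.config_hash_:
            raise ConfigurationError("HOG config does not match the one used in training")
        X = self.transform_crops([crop])
        label = str(self.svc_.predict(X)[0])
        value = float(self.svc_.decision_function(X)[0])
        return label, value

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Single portable model file with a version tag and the HOG config embedded."""
        self._check_fitted()
        joblib.dump({
            "version": _MODEL_VERSION,
            "hog_config": self.hog_config,
            "config_hash": self.config_hash_,
            "svc": self.svc_,
            "C": self.C_,
            "sigma": self.sigma_,
            "seed": self.seed,
            "C_grid": self.C_grid,
            "n_folds": self.n_folds,
        }, path)

    @classmethod
    def load(cls, path) -> "ImpurityBubbleClassifier":
        payload = joblib.load(path)
        if payload.get("version") != _MODEL_VERSION:
            raise ConfigurationError(f"unsupported model version {payload.get('version')}")
        obj = cls(hog_config=payload["hog_config"], C_grid=payload["C_grid"],
                  n_folds=payload["n_folds"], seed=payload["seed"])
        obj.svc_ = payload["svc"]
        obj.C_ = payload["C"]
        obj.sigma_ = payload["sigma"]
        obj.classes_ = obj.svc_.classes_
        obj.config_hash_ = payload["config_hash"]
        return obj


def train(crops: Sequence[np.ndarray], labels: Sequence[str],
          hog_config: HOGConfig | None = None, seed: int = 0) -> ImpurityBubbleClassifier:
    """Thin functional wrapper over :class:`ImpurityBubbleClassifier.fit`."""
    return ImpurityBubbleClassifier(hog_config=hog_config, seed=seed).fit(crops, labels)


def evaluate_classifier(classifier: ImpurityBubbleClassifier,
                        crops: Sequence[np.ndarray],
                        labels: Sequence[str]) -> ConfusionMatrix:
    """Confusion matrix with per-class and overall accuracy on a labelled test set."""
    if len(crops) == 0:
        raise ValueError("empty test set")
    labels = np.asarray(labels)
    pred = classifier.predict(crops)
    counts = {t: {p: int(np.sum((labels == t) & (pred == p))) for p in LABELS}
              for t in LABELS}
    per_class = {}
    for t in LABELS:
        n_t = sum(counts[t].values())
        per_class[t] = counts[t][t] / n_t if n_t else float("nan")
    overall = float(np.mean(pred == labels))
    return ConfusionMatrix(counts=counts, per_class_accuracy=per_class,
                           overall_accuracy=overall, n_samples=len(labels))
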