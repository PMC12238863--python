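"""Fatigue classification: normalization, RBF-SVM, cross-validation, PCA check.

The binary Fatigue / Non-Fatigue task is learned by a support vector machine
with a radial-basis-function kernel on the five normalized window features.
The signed distance from the separating hyperplane (the *decision value*) is
the controller's input: positive values lie on the Non-Fatigue side, so
large positive values mean low fatigue.

Normalization uses the population convention (ddof=0): training columns are
transformed to mean 0, sd 1, and the same statistics are applied to new data
(no leakage). Cross-validation is stratified k-fold with the normalizer
re-fit inside every training fold.

Persistence stores the support vectors, dual coefficients, intercept,
hyperparameters and normalization statistics in a versioned JSON file; the
decision function is evaluated from those arrays directly, so a loaded model
reproduces the trained one exactly.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DataError, StratificationError, TrainingError
from .features import FATIGUE, FEATURE_NAMES, NON_FATIGUE

__all__ = [
    "MODEL_FORMAT_VERSION",
    "NormalizationParams",
    "SvmModel",
    "CVResult",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
    "train_svm",
    "cross_validate",
    "pca_project",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class NormalizationParams:
    """Per-feature location/scale fitted on training data (population sd)."""

    mean: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


def fit_normalizer(
    X: np.ndarray, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> NormalizationParams:
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("need a 2-D feature matrix with at least 2 rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    for j, s in enumerate(scale):
        if s <= 0:
            name = feature_names[j] if j < len(feature_names) else f"column {j}"
            raise DataError(f"feature {name!r} is constant; cannot normalize")
    return NormalizationParams(mean=mean, scale=scale, feature_names=tuple(feature_names))


def apply_normalizer(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, float) - params.mean) / params.scale


def invert_normalizer(params: NormalizationParams, Z: np.ndarray) -> np.ndarray:
    return np.asarray(Z, float) * params.scale + params.mean


@dataclass
class SvmModel:
    """Trained RBF-SVM with attached normalization.

    Decision values are computed from the stored support data:
    ``f(x) = sum_i dual_coef_i * exp(-gamma * ||sv_i - z||^2) + intercept``
    with ``z`` the normalized input. ``f > 0`` predicts Non-Fatigue.
    """

    C: float
    gamma: float
    normalizer: NormalizationParams
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    version: int = field(default=MODEL_FORMAT_VERSION)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(apply_normalizer(self.normalizer, X))
        K = rbf_kernel(Z, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coef.ravel() + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(X)
        return np.where(f > 0, NON_FATIGUE, FATIGUE)


def _resolve_gamma(gamma: float | str, Z: np.ndarray) -> float:
    if gamma == "scale":
        v = Z.var()
        return 1.0 / (Z.shape[1] * v) if v > 0 else 1.0
    return float(gamma)


def train_svm(
    X: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "scale",
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> SvmModel:
    """Fit normalizer + RBF-SVM; deterministic given the training set.

    ``labels`` are the strings Fatigue / NonFatigue. Internally Non-Fatigue
    is the positive class so that positive decision values mean low fatigue.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise DataError("X and labels disagree in length")
    if X.shape[0] < 4:
        raise TrainingError(f"need at least 4 samples, got {X.shape[0]}")
    classes = set(np.unique(labels))
    if not classes <= {FATIGUE, NON_FATIGUE}:
        raise DataError(f"unknown labels {classes - {FATIGUE, NON_FATIGUE}}")
    if len(classes) < 2:
        raise TrainingError("both Fatigue and Non-Fatigue samples are required")

    norm = fit_normalizer(X, feature_names)
    Z = apply_normalizer(norm, X)
    y = (labels == NON_FATIGUE).astype(int)  # class 1 = Non-Fatigue = positive side
    g = _resolve_gamma(gamma, Z)
    svc = SVC(C=C, kernel="rbf", gamma=g)
    svc.fit(Z, y)
    return SvmModel(
        C=float(C),
        gamma=g,
        normalizer=norm,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.copy(),
        intercept=float(svc.intercept_[0]),
    )


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    fold_normalizers: list[NormalizationParams]
    #: test-fold class counts, one {label: count} per fold
    fold_test_counts: list[dict]


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> CVResult:
    """Stratified k-fold CV with leakage-free, per-fold normalization."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() < k:
        raise StratificationError(
            f"every class needs at least k={k} members, got counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs: list[float] = []
    norms: list[NormalizationParams] = []
    counts_per_fold: list[dict] = []
    for train_idx, test_idx in skf.split(X, labels):
        model = train_svm(X[train_idx], labels[train_idx], C=C, gamma=gamma)
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == labels[test_idx])))
        norms.append(model.normalizer)
        cls, cnt = np.unique(labels[test_idx], return_counts=True)
        counts_per_fold.append({str(c): int(n) for c, n in zip(cls, cnt)})
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        fold_normalizers=norms,
        fold_test_counts=counts_per_fold,
    )


def pca_project(X: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA projection; returns (scores, explained_variance_ratio).

    Used as the visual/quantitative separability check of the feature space.
    Degenerate-rank input triggers a warning and returns fewer components.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise DataError("need at least 3 rows and 2 features")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if rank < n_components:
        warnings.warn(
            f"feature matrix has rank {rank} < {n_components}; returning {max(rank, 1)} "
            "component(s)",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = max(rank, 1)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def save_model(model: SvmModel, path: str | pathlib.Path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": model.version,
        "C": model.C,
        "gamma": model.gamma,
        "intercept": model.intercept,
        "normalizer": {
            "mean": model.normalizer.mean.tolist(),
            "scale": model.normalizer.scale.tolist(),
            "feature_names": list(model.normalizer.feature_names),
        },
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
    }
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def load_model(path: str | pathlib.Path) -> SvmModel:
    payload = json.loads(pathlib.Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise DataError(
            f"model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    norm = NormalizationParams(
        mean=np.array(payload["normalizer"]["mean"], float),
        scale=np.array(payload["normalizer"]["scale"], float),
        feature_names=tuple(payload["normalizer"]["feature_names"]),
    )
    return SvmModel(
        C=float(payload["C"]),
        gamma=float(payload["gamma"]),
        normalizer=norm,
        support_vectors=np.array(payload["support_vectors"], float),
        dual_coef=np.array(payload["dual_coef"], float),
        intercept=float(payload["intercept"]),
        version=version,
    )
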