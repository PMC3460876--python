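"""Per-family SVM training on PDT feature vectors.

Kernels are computed explicitly (quadratic (1 + x.y)^2, RBF, and plain
linear for diagnostics), optionally cosine-normalized, and handed to a
scikit-learn SVC with a precomputed Gram matrix.  Features are z-scored on
the training split before kernel evaluation.  The discriminant weight
vector w = sum_n alpha_n * M_n projects the signed dual solution back into
feature space for feature ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .pdt import FeatureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "TrainedModel",
    "DiscriminantWeights",
    "TrainingError",
    "kernel_matrix",
    "train_family",
    "decision_scores",
    "select_kernel",
    "discriminant_weights",
    "rank_features",
    "save_model",
    "load_model",
]

QUADRATIC = "quadratic"
RBF = "rbf"
LINEAR = "linear"


class TrainingError(ValueError):
    """Raised when a family cannot be trained (e.g. single-class input)."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration.

    ``rbf_width`` of None means the median pairwise-distance heuristic,
    resolved at fit time.  ``normalize`` applies cosine normalization to the
    kernel matrix.
    """

    kind: str = QUADRATIC
    rbf_width: float | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (QUADRATIC, RBF, LINEAR):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.rbf_width is not None and self.rbf_width <= 0:
            raise ValueError(f"rbf_width must be > 0, got {self.rbf_width}")


def median_width(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance; fallback 1.0 for degenerate data."""
    n = X.shape[0]
    if n < 2:
        return 1.0
    sq = np.sum(X * X, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    dists = np.sqrt(d2[np.triu_indices(n, k=1)])
    med = float(np.median(dists))
    return med if med > 0 else 1.0


def _raw_kernel(X: np.ndarray, Y: np.ndarray, kind: str, width: float) -> np.ndarray:
    if kind == QUADRATIC:
        return (1.0 + X @ Y.T) ** 2
    if kind == LINEAR:
        return X @ Y.T
    sqx = np.sum(X * X, axis=1)[:, None]
    sqy = np.sum(Y * Y, axis=1)[None, :]
    d2 = np.maximum(sqx + sqy - 2.0 * X @ Y.T, 0.0)
    return np.exp(-d2 / (2.0 * width * width))


def _self_kernel_diag(X: np.ndarray, kind: str, width: float) -> np.ndarray:
    if kind == QUADRATIC:
        return (1.0 + np.sum(X * X, axis=1)) ** 2
    if kind == LINEAR:
        return np.sum(X * X, axis=1)
    return np.ones(X.shape[0])


def kernel_matrix(
    X: np.ndarray, Y: np.ndarray, spec: KernelSpec, width: float = 1.0
) -> np.ndarray:
    """Kernel matrix between rows of X and rows of Y (cosine-normalized if
    the spec asks for it)."""
    K = _raw_kernel(X, Y, spec.kind, width)
    if spec.normalize:
        dx = np.sqrt(_self_kernel_diag(X, spec.kind, width))
        dy = np.sqrt(_self_kernel_diag(Y, spec.kind, width))
        with np.errstate(invalid="ignore", divide="ignore"):
            K = K / np.outer(dx, dy)
        K = np.nan_to_num(K, nan=0.0)
    return K


@dataclass
class TrainedModel:
    """A fitted per-family SVM in explicit (standardized) feature space.

    ``alpha`` is the signed, label-absorbed dual weight vector over all N
    training rows (zero off the support); ``train_matrix`` holds the
    standardized training feature vectors in training order.
    """

    family_id: str
    kernel: KernelSpec
    width: float
    alpha: np.ndarray
    intercept: float
    train_matrix: np.ndarray
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    annotations: list[FeatureAnnotation] = field(default_factory=list)

    @property
    def n_train(self) -> int:
        return self.train_matrix.shape[0]


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def train_family(
    pos: np.ndarray,
    neg: np.ndarray,
    kernel: KernelSpec | None = None,
    seed: int = 0,
    C: float = 10.0,
    family_id: str = "",
    annotations: Sequence[FeatureAnnotation] | None = None,
) -> TrainedModel:
    """Fit one family's SVM from positive and negative feature matrices.

    Deterministic for fixed inputs and seed.  Raises :class:`TrainingError`
    if either class is empty.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise TrainingError(
            f"family {family_id!r}: need both classes "
            f"(got {pos.shape[0]} positive, {neg.shape[0]} negative)"
        )
    if kernel is None:
        kernel = KernelSpec()
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(pos.shape[0]), -np.ones(neg.shape[0])])
    mean, std = _standardize_fit(X)
    Xs = (X - mean) / std
    width = kernel.rbf_width if kernel.rbf_width is not None else median_width(Xs)
    K = kernel_matrix(Xs, Xs, kernel, width)
    svc = SVC(kernel="precomputed", C=C, random_state=seed)
    svc.fit(K, y)
    alpha = np.zeros(X.shape[0])
    alpha[svc.support_] = svc.dual_coef_[0]
    return TrainedModel(
        family_id=family_id,
        kernel=kernel,
        width=width,
        alpha=alpha,
        intercept=float(svc.intercept_[0]),
        train_matrix=Xs,
        scaler_mean=mean,
        scaler_std=std,
        annotations=list(annotations or []),
    )


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """SVM decision values for raw (unstandardized) feature rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = (X - model.scaler_mean) / model.scaler_std
    K = kernel_matrix(Xs, model.train_matrix, model.kernel, model.width)
    return K @ model.alpha + model.intercept


def select_kernel(
    pos: np.ndarray,
    neg: np.ndarray,
    candidates: Sequence[KernelSpec],
    folds: int = 5,
    seed: int = 0,
    C: float = 10.0,
) -> KernelSpec:
    """Pick the candidate with the best mean cross-validated ROC.

    Stratified K-fold on the pooled training data; the fold count is capped
    at the smaller class size (>= 2).  Ties go to the earlier candidate.
    """
    from .evaluate import roc_score  # local import to avoid a cycle

    if not candidates:
        raise ValueError("no kernel candidates supplied")
    if len(candidates) == 1:
        return candidates[0]
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    n_min = min(pos.shape[0], neg.shape[0])
    if n_min < 2:
        logger.warning("select_kernel: too few samples for CV, using first candidate")
        return candidates[0]
    folds = max(2, min(folds, n_min))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(pos.shape[0]), -np.ones(neg.shape[0])])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_spec, best_score = candidates[0], -np.inf
    for spec in candidates:
        fold_scores = []
        for train_idx, val_idx in skf.split(X, y):
            y_tr, y_val = y[train_idx], y[val_idx]
            model = train_family(
                X[train_idx][y_tr > 0], X[train_idx][y_tr < 0],
                kernel=spec, seed=seed, C=C,
            )
            fold_scores.append(roc_score(decision_scores(model, X[val_idx]), y_val))
        mean_roc = float(np.mean(fold_scores))
        logger.info("select_kernel: %s mean CV ROC %.4f", spec.kind, mean_roc)
        if mean_roc > best_score:  # strict: ties keep the earlier candidate
            best_spec, best_score = spec, mean_roc
    return best_spec


@dataclass
class DiscriminantWeights:
    """Feature-space projection of the dual solution, aligned to the layout."""

    w: np.ndarray
    annotations: list[FeatureAnnotation]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.annotations and len(self.annotations) != self.w.shape[0]:
            raise ValueError("annotation count does not match weight length")


def discriminant_weights(model: TrainedModel) -> DiscriminantWeights:
    """w = sum_n alpha_n * M_n over the training representatives."""
    w = model.alpha @ model.train_matrix
    return DiscriminantWeights(w=w, annotations=list(model.annotations))


def rank_features(
    weights: DiscriminantWeights, top_k: int | None = None
) -> list[tuple[int, FeatureAnnotation | None, float]]:
    """Features sorted by |weight| descending; ties keep layout order.

    Returns (feature position, annotation, signed weight) triples.
    """
    order = sorted(range(weights.w.shape[0]), key=lambda i: (-abs(weights.w[i]), i))
    if top_k is not None:
        order = order[: max(top_k, 0)]
    ann = weights.annotations
    return [(i, ann[i] if ann else None, float(weights.w[i])) for i in order]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (single .npz archive with a JSON header)."""
    meta = {
        "family_id": model.family_id,
        "kernel": {
            "kind": model.kernel.kind,
            "rbf_width": model.kernel.rbf_width,
            "normalize": model.kernel.normalize,
        },
        "width": model.width,
        "intercept": model.intercept,
        "annotations": [list(a) for a in model.annotations],
    }
    np.savez(
        path,
        meta=np.array(json.dumps(meta)),
        alpha=model.alpha,
        train_matrix=model.train_matrix,
        scaler_mean=model.scaler_mean,
        scaler_std=model.scaler_std,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        kernel = KernelSpec(**meta["kernel"])
        return TrainedModel(
            family_id=meta["family_id"],
            kernel=kernel,
            width=float(meta["width"]),
            alpha=archive["alpha"],
            intercept=float(meta["intercept"]),
            train_matrix=archive["train_matrix"],
            scaler_mean=archive["scaler_mean"],
            scaler_std=archive["scaler_std"],
            annotations=[FeatureAnnotation(a, int(l), int(n))
                         for a, l, n in meta["annotations"]],
        )
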