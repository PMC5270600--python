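"""Gaussian kernels over an adaptive bandwidth grid and precomputed-kernel SVM.

Pseudo-distances are mapped through f(d) = exp(-d^2 / gamma).  The gamma
grid adapts to the observed distance range: 10 log-uniform values spanning
at least [e^-3, e^3], widened to cover the extreme log-distances of the
set.  Model selection is an exhaustive search over the gamma grid and the
penalty grid {2^n : n in -5..5}, scored by k-fold cross-validated accuracy.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .pairdist import PseudoDistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(2.0 ** n for n in range(-5, 6))
GAMMA_GRID_SIZE = 10


class DegenerateDistanceError(ValueError):
    """Raised when every off-diagonal pseudo-distance is zero."""


def gamma_grid(D: PseudoDistanceMatrix) -> list[float]:
    """Adaptive 10-point log-uniform Gaussian bandwidth grid.

    With L the natural logs of the positive off-diagonal distances:
    t = min(-3, min L), s = (max(3, max L) - t) / 9, grid = e^{s*i + t}
    for i = 0..9.  Zero off-diagonal distances are skipped with a warning
    (their log is undefined); an all-zero matrix is an error.
    """
    values = D.values
    n = values.shape[0]
    mask = ~np.eye(n, dtype=bool)
    off = values[mask]
    positive = off[off > 0]
    if positive.size == 0:
        raise DegenerateDistanceError("all off-diagonal pseudo-distances are zero")
    if positive.size < off.size:
        logger.warning(
            "%d zero off-diagonal distances skipped in gamma grid statistics",
            off.size - positive.size,
        )
    logs = np.log(positive)
    t = min(-3.0, float(logs.min()))
    s = (max(3.0, float(logs.max())) - t) / 9.0
    return [float(np.exp(s * i + t)) for i in range(GAMMA_GRID_SIZE)]


@dataclass
class KernelMatrix:
    """Symmetric Gaussian kernel matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def gaussian_kernel(D: PseudoDistanceMatrix, gamma: float) -> KernelMatrix:
    """Element-wise exp(-d^2 / gamma); the diagonal is exactly 1."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    values = np.exp(-(D.values ** 2) / gamma)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(list(D.ids), values, gamma)


def kernel_from_distances(distances: np.ndarray, gamma: float) -> np.ndarray:
    """exp(-d^2 / gamma) for raw (possibly rectangular) distance blocks."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.exp(-(np.asarray(distances, dtype=float) ** 2) / gamma)


def clip_negative_eigenvalues(values: np.ndarray) -> np.ndarray:
    """Project a symmetric kernel onto the PSD cone (optional repair)."""
    eigvals, eigvecs = np.linalg.eigh(values)
    eigvals = np.clip(eigvals, 0.0, None)
    return (eigvecs * eigvals) @ eigvecs.T


@dataclass
class SvmGridConfig:
    """Search grids and fold count for precomputed-kernel model selection."""

    gamma_grid: Optional[Sequence[float]] = None
    c_grid: Sequence[float] = DEFAULT_C_GRID
    cv_folds: int = 10
    psd_clip: bool = False

    def resolve_gammas(self, D: PseudoDistanceMatrix) -> list[float]:
        if self.gamma_grid is not None:
            return [float(g) for g in self.gamma_grid]
        return gamma_grid(D)


@dataclass
class TrainedModel:
    """A fitted precomputed-kernel SVM plus its selected grid point."""

    svc: SVC
    gamma: float
    C: float
    cv_accuracy: float
    train_ids: list[str]
    n_grid_points: int
    train_distances: np.ndarray = field(repr=False, default=None)

    def decision_scores(self, test_train_distances: np.ndarray) -> np.ndarray:
        """Decision values for test rows of pseudo-distances to the train set."""
        K = kernel_from_distances(test_train_distances, self.gamma)
        return self.svc.decision_function(K)


def _cv_accuracy(K: np.ndarray, y: np.ndarray, C: float, folds: int, seed: int = 0) -> float:
    n = len(y)
    n_splits = min(folds, int(np.bincount(y).min()), n)
    if n_splits < 2:
        svc = SVC(kernel="precomputed", C=C).fit(K, y)
        return float(np.mean(svc.predict(K) == y))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=False)
    correct = 0
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        svc = SVC(kernel="precomputed", C=C)
        svc.fit(K[np.ix_(train_idx, train_idx)], y[train_idx])
        pred = svc.predict(K[np.ix_(test_idx, train_idx)])
        correct += int(np.sum(pred == y[test_idx]))
    return correct / n


def train_select(
    D: PseudoDistanceMatrix,
    labels: Sequence[int],
    config: Optional[SvmGridConfig] = None,
) -> TrainedModel:
    """Exhaustive (gamma, C) grid search scored by cross-validated accuracy.

    Ties are broken towards the smaller C, then the smaller gamma.  The
    winning model is refitted on the full training kernel.
    """
    config = config or SvmGridConfig()
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    gammas = config.resolve_gammas(D)
    kernels = {}
    for g in gammas:
        K = gaussian_kernel(D, g).values
        if config.psd_clip:
            K = clip_negative_eigenvalues(K)
        kernels[g] = K

    best = None  # (accuracy, -C, -gamma) maximized
    n_grid_points = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in gammas:
            for C in config.c_grid:
                n_grid_points += 1
                acc = _cv_accuracy(kernels[g], y, C, config.cv_folds)
                key = (acc, -C, -g)
                if best is None or key > best[0]:
                    best = (key, g, C, acc)
    _, g_best, c_best, acc_best = best
    svc = SVC(kernel="precomputed", C=c_best)
    svc.fit(kernels[g_best], y)
    return TrainedModel(
        svc=svc,
        gamma=g_best,
        C=c_best,
        cv_accuracy=acc_best,
        train_ids=list(D.ids),
        n_grid_points=n_grid_points,
        train_distances=D.values,
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> Optional[float]:
    """Rank-based AUC with midrank handling of tied scores.

    Returns None when only one class is present (AUC undefined).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    order = np.argsort(s, kind="stable")
    ranks = np.empty(len(s))
    sorted_scores = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # midrank, 1-based
        i = j + 1
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def predict_and_auc(
    model: TrainedModel,
    test_train_distances: np.ndarray,
    test_labels: Sequence[int],
) -> tuple[np.ndarray, Optional[float]]:
    """Decision scores for the test block and the resulting AUC (or None)."""
    scores = model.decision_scores(test_train_distances)
    return scores, roc_auc(test_labels, scores)


def save_model(model: TrainedModel, fh: TextIO) -> None:
    """Persist support-vector ids, dual coefficients, bias, gamma and C."""
    sv_idx = model.svc.support_.tolist()
    payload = {
        "gamma": model.gamma,
        "C": model.C,
        "cv_accuracy": model.cv_accuracy,
        "train_ids": model.train_ids,
        "support_ids": [model.train_ids[i] for i in sv_idx],
        "support_indices": sv_idx,
        "dual_coef": model.svc.dual_coef_.ravel().tolist(),
        "intercept": float(model.svc.intercept_[0]),
    }
    json.dump(payload, fh, indent=1)
    fh.write("\n")
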