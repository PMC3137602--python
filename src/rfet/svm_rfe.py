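"""Linear SVM training, weight-based ranking criterion, and recursive
feature elimination.

The elimination criterion for gene i is c_i = w_i**2, the squared component
of the linear decision boundary's weight vector; each round retrains on the
surviving genes and removes the single minimum-criterion gene, so the last
survivor is the top-ranked gene.

Class labels arrive as {0, 1} and are encoded 1 -> +1, 0 -> -1 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from ._errors import ComputationError, ConfigError, DataError
from .io_core import ExpressionMatrix, RankedEntry, RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "SVMConfig",
    "LinearSVMModel",
    "encode_labels",
    "standardize_features",
    "train_linear_svm",
    "ranking_criterion",
    "svm_rfe_rank",
]

SOLVER_TOL = 1e-6  # pinned so elimination order reproduces across platforms


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters shared by every training in a run."""

    C: float = 1.0
    standardize: bool = True
    tol: float = SOLVER_TOL

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ConfigError(f"C must be positive, got {self.C}")
        if not (0 < self.tol <= 1e-2):
            raise ConfigError(f"solver tolerance out of range: {self.tol}")


@dataclass
class LinearSVMModel:
    """Soft-margin linear SVM solution.

    ``support_coefficients`` holds alpha_k * y_k per training sample
    (zero for non-support vectors), so weights == X.T @ support_coefficients.
    """

    weights: np.ndarray
    bias: float
    support_coefficients: np.ndarray
    cost_parameter: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels in {0, 1}."""
        return (self.decision_function(X) >= 0).astype(int)


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Map class labels {0,1} -> {-1,+1} (1 -> +1)."""
    labels = np.asarray(labels)
    if not set(np.unique(labels).tolist()) <= {0, 1}:
        raise DataError(f"labels must be 0/1, got {np.unique(labels)}")
    return np.where(labels == 1, 1.0, -1.0)


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score each column; zero-variance columns become all-zero (warned)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0.0
    if np.any(zero):
        logger.warning("standardize: %d zero-variance gene(s) set to 0", int(zero.sum()))
    sd_safe = np.where(zero, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, zero] = 0.0
    return Z


def _validate_training_input(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be samples x genes")
    if not np.all(np.isfinite(X)):
        raise DataError("X contains non-finite values")
    y01 = np.asarray(y01)
    if y01.shape[0] != X.shape[0]:
        raise DataError(f"{X.shape[0]} samples but {y01.shape[0]} labels")
    if len(np.unique(y01)) < 2:
        raise DataError("both classes must be present in y")
    return X, y01


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = SOLVER_TOL) -> LinearSVMModel:
    """Train a soft-margin linear SVM.

    ``y`` may be given as {0,1} or {-1,+1}; it is encoded to {-1,+1}
    internally. Deterministic given (X, y, C) up to solver tolerance.
    """
    if not (C > 0):
        raise ConfigError(f"C must be positive, got {C}")
    X, y = _validate_training_input(X, y)
    yf = encode_labels(np.where(np.asarray(y) <= 0, 0, 1))
    K = X @ X.T
    alpha = np.zeros(X.shape[0])
    f = _solver.smo_solve(K, yf, float(C), alpha, float(tol), _solver.MAX_SMO_ITER)
    bias = float(_solver.svm_bias(f, yf, alpha, float(C)))
    coeff = alpha * yf
    weights = X.T @ coeff
    if not np.all(np.isfinite(weights)):
        raise ComputationError("SVM training produced non-finite weights")
    return LinearSVMModel(weights=weights, bias=bias, support_coefficients=coeff, cost_parameter=float(C))


def ranking_criterion(model: LinearSVMModel) -> np.ndarray:
    """Per-gene elimination criterion c_i = w_i**2."""
    return model.weights**2


def svm_rfe_rank(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    config: SVMConfig = SVMConfig(),
) -> RankedList:
    """Full recursive feature elimination on an expression matrix.

    Trains on the surviving genes, removes the single gene with the smallest
    squared weight (ties: the gene later in the current order), records its
    criterion at elimination, and repeats until no genes remain. Rank 1 is
    the last-eliminated gene.
    """
    if matrix.n_genes < 2:
        raise DataError("RFE needs at least 2 genes")
    yf = encode_labels(labels)
    if len(yf) != matrix.n_samples:
        raise DataError(f"{matrix.n_samples} samples but {len(yf)} labels")
    if len(np.unique(yf)) < 2:
        raise DataError("both classes must be present")
    X = matrix.values.T.copy()  # samples x genes
    if not np.all(np.isfinite(X)):
        raise DataError("expression matrix contains non-finite values")
    if config.standardize:
        X = standardize_features(X)
    X = np.ascontiguousarray(X)
    elim_gene, elim_crit = _solver.rfe_core(
        X, yf, float(config.C), float(config.tol), _solver.MAX_SMO_ITER
    )
    entries = [
        RankedEntry(matrix.probe_ids[int(gi)], step + 1, float(c))
        for step, (gi, c) in enumerate(zip(elim_gene, elim_crit))
    ]
    return RankedList(entries)
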