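"""Soft-margin binary linear SVM training, prediction and introspection.

The classifier is defined by its objective,

    min_{w, b}  1/2 ||w||^2  +  C * sum_i max(0, 1 - y_i (w . x_i + b)),

with labels y in {-1, +1} and an unpenalised bias b. The regularisation
constant C is not tuned: it is fixed from the data as the reciprocal of
the mean squared example norm (the SVMlight default), which keeps the
margin term and the hinge term on comparable scales. The trained weight
vector w is what drives recursive feature elimination downstream, so the
model records which voxel (feature) indices its weights refer to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC


@dataclass
class LinearModel:
    """A trained soft-margin linear classifier.

    ``feature_indices`` are the voxel (column) indices, in the full
    feature space, that ``weights`` refer to; the decision value of an
    example x restricted to those columns is ``w . x + b``.
    """

    weights: np.ndarray
    bias: float
    c_param: float
    training_objective: float
    feature_indices: np.ndarray | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_indices is not None and X.shape[1] != self.weights.size:
            X = X[:, self.feature_indices]
        if X.shape[1] != self.weights.size:
            raise ValueError(
                f"feature mismatch: model has {self.weights.size} weights, "
                f"input has {X.shape[1]} columns"
            )
        return X @ self.weights + self.bias

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": float(self.bias),
                "C": float(self.c_param),
                "training_objective": float(self.training_objective),
                "feature_indices": (
                    None if self.feature_indices is None else self.feature_indices.tolist()
                ),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            c_param=float(d["C"]),
            training_objective=float(d["training_objective"]),
            feature_indices=(
                None
                if d["feature_indices"] is None
                else np.asarray(d["feature_indices"], dtype=np.intp)
            ),
        )


def default_C(X: np.ndarray) -> float:
    """Data-driven regularisation constant: 1 / mean(||x_i||^2)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty example matrix")
    mean_sq = float(np.mean(np.einsum("ij,ij->i", X, X)))
    if mean_sq == 0.0:
        raise ValueError("all-zero example matrix has no data-driven C")
    return 1.0 / mean_sq


def hinge_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Primal objective 1/2 ||w||^2 + C sum hinge(1 - y (Xw + b))."""
    margins = 1.0 - y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.clip(margins, 0.0, None).sum())


def _kkt_polish(X, y, C, clf, w, b):
    """Refine libsvm's solution to the exact optimum of its active set.

    Free support vectors (0 < alpha < C) sit exactly on the margin at
    the optimum, so given libsvm's free/bounded partition the optimal
    (w, b) solves a small linear system. The refined solution is kept
    only when it lowers the primal objective — any (w, b) scores a
    valid objective value, so this is monotone-safe even if the
    partition was misidentified.
    """
    alpha = np.abs(clf.dual_coef_.ravel())
    support = clf.support_
    free = support[alpha < C * (1.0 - 1e-9)]
    bound = support[alpha >= C * (1.0 - 1e-9)]
    if free.size == 0:
        return w, b
    w_bound = (C * y[bound]) @ X[bound] if bound.size else np.zeros(X.shape[1])
    K_ff = X[free] @ X[free].T
    rhs = np.concatenate([y[free] - X[free] @ w_bound, [-C * y[bound].sum()]])
    A = np.zeros((free.size + 1, free.size + 1))
    A[: free.size, : free.size] = K_ff
    A[: free.size, -1] = 1.0
    A[-1, : free.size] = 1.0
    try:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return w, b
    w_new = w_bound + sol[: free.size] @ X[free]
    b_new = float(sol[-1])
    if hinge_objective(w_new, b_new, X, y, C) < hinge_objective(w, b, X, y, C):
        return w_new, b_new
    return w, b


def train(
    X: np.ndarray,
    y: np.ndarray,
    C: float | None = None,
    tol: float = 1e-6,
    feature_indices: np.ndarray | None = None,
) -> LinearModel:
    """Fit the soft-margin linear SVM by its dual (exact hinge loss).

    ``C`` defaults to :func:`default_C` of ``X``. Both classes must be
    present. The achieved primal objective value is recorded on the
    model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_examples, n_features) matching y")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training labels must contain both -1 and +1")
    if C is None:
        C = default_C(X)
    if C <= 0:
        raise ValueError("C must be positive")
    # libsvm can oscillate indefinitely below ~1e-8; the KKT polish
    # below restores exact optimality from the converged partition, so
    # the solver tolerance is floored and iterations are capped
    clf = SVC(kernel="linear", C=C, tol=max(tol, 1e-8), max_iter=10_000_000)
    if tol <= 1e-6:
        # precision-seeking call: an early-terminated solve is refined
        # to the exact optimum below, so the cap warning is moot
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, y)
        w = clf.coef_.ravel().astype(float)
        b = float(clf.intercept_[0])
        w, b = _kkt_polish(X, y, C, clf, w, b)
    else:
        clf.fit(X, y)
        w = clf.coef_.ravel().astype(float)
        b = float(clf.intercept_[0])
    return LinearModel(
        weights=w,
        bias=b,
        c_param=float(C),
        training_objective=hinge_objective(w, b, X, y, C),
        feature_indices=None if feature_indices is None else np.asarray(feature_indices, dtype=np.intp),
    )


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels in {-1, +1}; a decision value of exactly 0 goes
    to +1 (the action class)."""
    d = model.decision_values(X)
    return np.where(d >= 0.0, 1, -1)


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if predicted.size == 0:
        raise ValueError("cannot score an empty test set")
    return float(np.mean(predicted == true))
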