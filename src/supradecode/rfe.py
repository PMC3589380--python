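"""Recursive feature elimination inside nested cross-validation.

The model-selection engine: stimuli are split into k class-stratified
folds; within each fold a linear SVM is trained on the training
stimuli's examples, the 2% of features (voxels) with the smallest
absolute weights are discarded, surviving voxels are cluster-corrected
(connected components below a minimum size are dropped), test accuracy
is recorded, and the cycle repeats until no voxel survives. Per fold and
condition the iteration with the highest test accuracy defines the best
feature set; the best fold is the one whose conditions' best accuracies
have the highest mean. All subsequent analyses (supramodal classifier,
knock-out) operate on the best fold.

Implementation note: because elimination only ever removes features,
the training Gram matrix of iteration t+1 equals that of iteration t
minus the removed features' outer product. Both the train-train and
test-train kernels are therefore computed once and downdated in place,
which turns the per-iteration kernel cost from O(n^2 p) into O(n^2 k)
for k removed features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import svm as _svm
from .grid import VoxelGrid, cluster_correct
from .synthetic import ExampleSet
from .assembly import FoldAssignment, tanh_transform


@dataclass(frozen=True)
class RFEConfig:
    """Tunables of the elimination loop.

    ``elimination_fraction`` is the fraction of surviving features
    discarded per iteration (ceiling, minimum one, so the loop always
    terminates). ``min_cluster_voxels`` is the cluster-correction
    threshold — 150 voxels (1,200 uL at 2 mm isometric) at brain scale;
    desk-scale synthetic grids use a proportionally smaller value.
    ``connectivity`` is the neighbourhood definition for clusters;
    nearest-neighbour face adjacency by default. When
    ``joint_best_iteration`` is set, the best RFE iteration is chosen
    jointly across conditions (one shared iteration index maximising the
    mean accuracy) instead of per condition.
    """

    elimination_fraction: float = 0.02
    min_cluster_voxels: int = 150
    connectivity: str = "faces"
    k_folds: int = 4
    svm_tol: float = 1e-3
    joint_best_iteration: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.elimination_fraction < 1.0):
            raise ValueError("elimination_fraction must be in (0, 1)")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class RFETrace:
    """Per-iteration (surviving feature set, test accuracy) record."""

    iterations: list

    def __post_init__(self) -> None:
        sizes = [len(fs) for fs, _ in self.iterations]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("feature-set sizes must strictly decrease")
        if any(not (0.0 <= acc <= 1.0) for _, acc in self.iterations):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([acc for _, acc in self.iterations], dtype=float)

    @property
    def feature_counts(self) -> np.ndarray:
        return np.array([len(fs) for fs, _ in self.iterations], dtype=int)

    def best_iteration(self) -> int:
        """Index of the highest test accuracy.

        Ties go to the latest tied iteration, i.e. the smallest
        surviving voxel set: the point of recursive elimination is a
        minimal sufficient feature set, so when pruning does not cost
        accuracy the pruned set is preferred.
        """
        acc = self.accuracies
        return int(len(acc) - 1 - np.argmax(acc[::-1]))

    @property
    def best_feature_set(self) -> np.ndarray:
        return self.iterations[self.best_iteration()][0]

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies[self.best_iteration()])


@dataclass
class FoldRecord:
    """One outer fold's traces and per-condition selections."""

    fold: int
    traces: dict
    best_sets: dict
    best_accuracies: dict

    @property
    def mean_best_accuracy(self) -> float:
        return float(np.mean(list(self.best_accuracies.values())))


@dataclass
class DiscriminativeMap:
    """A selected voxel set with raw and z-scored classifier weights."""

    voxels: np.ndarray
    weights: np.ndarray
    z_weights: np.ndarray

    def to_volumes(self, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
        """Dense (weights, z_weights) 3D volumes on the grid."""
        return (
            grid.volume_from_values(self.voxels, self.weights),
            grid.volume_from_values(self.voxels, self.z_weights),
        )


def eliminate_features(
    abs_weights: np.ndarray,
    feature_set: np.ndarray,
    grid: VoxelGrid,
    config: RFEConfig,
) -> np.ndarray:
    """One elimination step on explicit |weights|.

    Removes the ceil(fraction * n) features with the smallest absolute
    weight (at least one; ties broken by removing the lower voxel index
    first), then cluster-corrects the survivors. The output is a strict
    subset of the input.
    """
    feature_set = np.asarray(feature_set, dtype=np.intp)
    abs_weights = np.asarray(abs_weights, dtype=float)
    if abs_weights.size != feature_set.size:
        raise ValueError("weights and feature set lengths differ")
    n = feature_set.size
    if n == 0:
        return feature_set
    n_remove = max(1, math.ceil(config.elimination_fraction * n))
    order = np.lexsort((feature_set, abs_weights))  # by |w|, then voxel index
    survivors = np.sort(feature_set[order[n_remove:]])
    return cluster_correct(survivors, grid, config.connectivity, config.min_cluster_voxels)


def eliminate_step(
    model: _svm.LinearModel,
    feature_set: np.ndarray,
    grid: VoxelGrid,
    config: RFEConfig,
) -> np.ndarray:
    """Elimination step driven by a trained model's weight vector."""
    feature_set = np.asarray(feature_set, dtype=np.intp)
    if model.weights.size != feature_set.size:
        raise ValueError("model was not trained on exactly this feature set")
    return eliminate_features(np.abs(model.weights), feature_set, grid, config)


def run_rfe(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    initial_mask: np.ndarray,
    grid: VoxelGrid,
    config: RFEConfig,
) -> RFETrace:
    """Full elimination run: train, score, prune, repeat until empty.

    ``train_X`` / ``test_X`` are full-grid matrices; ``initial_mask``
    gives the voxel indices the run starts from. At every iteration the
    SVM is refit with the data-driven C of the surviving training
    submatrix, the test accuracy of that classifier is recorded together
    with the surviving feature set, and the lowest-|w| features are
    eliminated with cluster correction.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    test_y = np.asarray(test_y, dtype=int)
    active = np.sort(np.asarray(initial_mask, dtype=np.intp))
    if active.size == 0:
        raise ValueError("initial mask is empty")

    Xa = train_X[:, active]
    K_tr = Xa @ Xa.T
    K_te = test_X[:, active] @ Xa.T
    sqnorms = np.einsum("ij,ij->i", Xa, Xa)

    iterations = []
    while active.size:
        mean_sq = float(sqnorms.mean())
        if mean_sq <= 0.0:
            break  # nothing but zero features left; accuracy undefined
        C = 1.0 / mean_sq
        clf = SVC(kernel="precomputed", C=C, tol=config.svm_tol)
        clf.fit(K_tr, train_y)
        alpha = clf.dual_coef_.ravel()
        decision = K_te[:, clf.support_] @ alpha + clf.intercept_[0]
        pred = np.where(decision >= 0.0, 1, -1)
        acc = float(np.mean(pred == test_y))
        iterations.append((active.copy(), acc))

        w = alpha @ train_X[clf.support_][:, active]
        new_active = eliminate_features(np.abs(w), active, grid, config)
        removed = np.setdiff1d(active, new_active, assume_unique=True)
        if removed.size:
            B = train_X[:, removed]
            K_tr -= B @ B.T
            K_te -= test_X[:, removed] @ B.T
            sqnorms = sqnorms - np.einsum("ij,ij->i", B, B)
        active = new_active
    return RFETrace(iterations)


def fit_on_features(
    train_X: np.ndarray,
    train_y: np.ndarray,
    feature_set: np.ndarray,
    tol: float = 1e-4,
) -> _svm.LinearModel:
    """Train a linear SVM on a voxel subset of a full-grid matrix.

    C is the data-driven constant of the restricted training submatrix;
    the returned model carries the voxel indices so it can be applied to
    any full-grid example matrix.
    """
    feature_set = np.asarray(feature_set, dtype=np.intp)
    if feature_set.size == 0:
        raise ValueError("cannot train on an empty feature set")
    sub = np.asarray(train_X, dtype=float)[:, feature_set]
    return _svm.train(sub, train_y, C=_svm.default_C(sub), tol=tol, feature_indices=feature_set)


@dataclass
class NestedCVResult:
    fold_records: list
    best_fold: int
    summary: dict  # condition -> {"mean": ..., "sd": ...} over per-fold best accuracies

    def record_for(self, fold: int) -> FoldRecord:
        for rec in self.fold_records:
            if rec.fold == fold:
                return rec
        raise KeyError(f"no record for fold {fold}")

    @property
    def best_record(self) -> FoldRecord:
        return self.record_for(self.best_fold)


def _fold_split(
    exset: ExampleSet,
    assignment: FoldAssignment,
    fold: int,
    scaling: str,
):
    folds = assignment.folds_for(exset)
    train = folds != fold
    test = folds == fold
    y = exset.labels()
    Xtr, Xte = exset.X[train], exset.X[test]
    if scaling == "per_fold":
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        Xtr = tanh_transform(Xtr, mean, sd)
        Xte = tanh_transform(Xte, mean, sd)
    return Xtr, y[train], Xte, y[test], train, test


def nested_cv(
    condition_sets: dict,
    fold_assignments: dict,
    grid: VoxelGrid,
    config: RFEConfig,
    initial_mask: np.ndarray | None = None,
    scaling: str = "pooled",
) -> NestedCVResult:
    """k-fold nested cross-validation with RFE for every condition.

    ``condition_sets`` maps condition names to balanced ExampleSets
    (already tanh-scaled under the default ``scaling="pooled"``;
    unscaled when ``scaling="per_fold"``, in which case scaling is fit
    on each fold's training examples only). Per fold and condition the
    full RFE trace is run; the best iteration is the accuracy argmax
    (per condition, or a shared iteration index across conditions when
    the config requests joint selection). The best fold maximises the
    across-condition mean of best accuracies; ties go to the lower fold
    index. The summary reports mean +/- SD of the per-fold best
    accuracies per condition.
    """
    if scaling not in ("pooled", "per_fold"):
        raise ValueError("scaling must be 'pooled' or 'per_fold'")
    if set(condition_sets) != set(fold_assignments):
        raise ValueError("condition_sets and fold_assignments keys differ")
    if scaling == "pooled":
        unscaled = [name for name, s in condition_sets.items() if not s.scaled]
        if unscaled:
            raise ValueError(f"pooled scaling expects pre-scaled sets; unscaled: {unscaled}")
    mask = (
        np.arange(grid.n_voxels, dtype=np.intp)
        if initial_mask is None
        else np.sort(np.asarray(initial_mask, dtype=np.intp))
    )

    records = []
    for fold in range(1, config.k_folds + 1):
        traces = {}
        for name, exset in condition_sets.items():
            Xtr, ytr, Xte, yte, *_ = _fold_split(exset, fold_assignments[name], fold, scaling)
            traces[name] = run_rfe(Xtr, ytr, Xte, yte, mask, grid, config)
        if config.joint_best_iteration:
            n_shared = min(t.n_iterations for t in traces.values())
            mean_acc = np.mean([t.accuracies[:n_shared] for t in traces.values()], axis=0)
            best_it = int(np.argmax(mean_acc))
            best_sets = {name: t.iterations[best_it][0] for name, t in traces.items()}
            best_accs = {name: float(t.accuracies[best_it]) for name, t in traces.items()}
        else:
            best_sets = {name: t.best_feature_set for name, t in traces.items()}
            best_accs = {name: t.best_accuracy for name, t in traces.items()}
        records.append(
            FoldRecord(fold=fold, traces=traces, best_sets=best_sets, best_accuracies=best_accs)
        )

    fold_means = np.array([rec.mean_best_accuracy for rec in records])
    best_fold = int(np.argmax(fold_means)) + 1
    summary = {}
    for name in condition_sets:
        accs = np.array([rec.best_accuracies[name] for rec in records])
        summary[name] = {
            "mean": float(accs.mean()),
            "sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        }
    return NestedCVResult(fold_records=records, best_fold=best_fold, summary=summary)


def make_map(model: _svm.LinearModel, feature_set: np.ndarray) -> DiscriminativeMap:
    """Discriminative map: the model's weights over its voxel set, plus
    z-scored weights (zero mean, unit variance over the set; a singleton
    set gets z = 0)."""
    feature_set = np.asarray(feature_set, dtype=np.intp)
    if feature_set.size == 0:
        raise ValueError("cannot map an empty feature set")
    if model.weights.size != feature_set.size:
        raise ValueError("model was not trained on exactly this feature set")
    w = model.weights.astype(float)
    sd = w.std()
    z = np.zeros_like(w) if (w.size == 1 or sd == 0.0) else (w - w.mean()) / sd
    return DiscriminativeMap(voxels=feature_set, weights=w, z_weights=z)
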