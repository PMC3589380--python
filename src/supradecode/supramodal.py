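"""Combined supramodal classifier, knock-out mask, and generalization.

The headline analyses. After nested cross-validation has picked a best
fold and per-condition best voxel sets, a single "supramodal" classifier
is trained with the same RFE procedure on the *pooled* training examples
of all conditions of the best fold; its selected voxels form the
knock-out mask. Three follow-up analyses probe whether those voxels
carry the modality-invariant action information:

* exclusion — each condition's classifier is retrained on its best
  voxel set minus the knock-out mask (accuracy should drop if the mask
  carried shared signal);
* restriction — classifiers are retrained on the knock-out voxels only
  and evaluated within and across conditions/groups (cross-condition
  accuracy should appear if the mask is truly supramodal);
* pantomime probing — trained classifiers label motor-pantomime
  examples, and the fraction labeled "action" is tested against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import svm as _svm
from .grid import VoxelGrid
from .rfe import RFEConfig, RFETrace, NestedCVResult, fit_on_features, make_map, run_rfe, _fold_split
from .stats import binomial_test, permutation_test, svm_accuracy_null
from .synthetic import ExampleSet


@dataclass(frozen=True)
class KnockoutMask:
    """The supramodal classifier's selected voxels."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.sort(np.asarray(self.voxels, dtype=np.intp)))

    @property
    def size(self) -> int:
        return self.voxels.size


@dataclass
class ConditionSplit:
    """Best-fold train/test matrices of one condition."""

    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray


def best_fold_splits(
    condition_sets: dict,
    fold_assignments: dict,
    best_fold: int,
    scaling: str = "pooled",
) -> dict:
    """Extract each condition's train/test split of the chosen fold."""
    splits = {}
    for name, exset in condition_sets.items():
        Xtr, ytr, Xte, yte, *_ = _fold_split(exset, fold_assignments[name], best_fold, scaling)
        splits[name] = ConditionSplit(Xtr, ytr, Xte, yte)
    return splits


@dataclass
class SupramodalResult:
    model: _svm.LinearModel
    map: "object"  # DiscriminativeMap
    knockout: KnockoutMask
    trace: RFETrace
    pooled_accuracy: float


def train_supramodal(
    splits: dict,
    grid: VoxelGrid,
    config: RFEConfig,
    initial_mask: np.ndarray | None = None,
) -> SupramodalResult:
    """RFE on the pooled best-fold training data of all conditions.

    The pooled training set is the concatenation of every condition's
    balanced training examples (classes stay balanced by construction;
    no re-balancing across conditions). The best RFE iteration defines
    the supramodal model, its discriminative map, and the knock-out
    mask; the reported accuracy is that iteration's accuracy on the
    pooled best-fold test set.
    """
    Xtr = np.vstack([s.train_X for s in splits.values()])
    ytr = np.concatenate([s.train_y for s in splits.values()])
    Xte = np.vstack([s.test_X for s in splits.values()])
    yte = np.concatenate([s.test_y for s in splits.values()])
    mask = (
        np.arange(Xtr.shape[1], dtype=np.intp) if initial_mask is None else initial_mask
    )
    trace = run_rfe(Xtr, ytr, Xte, yte, mask, grid, config)
    best_set = trace.best_feature_set
    model = fit_on_features(Xtr, ytr, best_set)
    return SupramodalResult(
        model=model,
        map=make_map(model, best_set),
        knockout=KnockoutMask(best_set),
        trace=trace,
        pooled_accuracy=trace.best_accuracy,
    )


@dataclass
class ExclusionResult:
    accuracy: float
    model: _svm.LinearModel | None
    surviving: np.ndarray
    empty_survivor_set: bool = False


def evaluate_excluding(
    best_set: np.ndarray,
    knockout: KnockoutMask,
    split: ConditionSplit,
) -> ExclusionResult:
    """Retrain one condition on its best voxels minus the knock-out mask.

    An empty surviving set yields the defined chance accuracy 0.5 with
    a warning flag rather than an error.
    """
    surviving = np.setdiff1d(np.asarray(best_set, dtype=np.intp), knockout.voxels)
    if surviving.size == 0:
        return ExclusionResult(0.5, None, surviving, empty_survivor_set=True)
    model = fit_on_features(split.train_X, split.train_y, surviving)
    acc = _svm.accuracy(_svm.predict(model, split.test_X), split.test_y)
    return ExclusionResult(acc, model, surviving)


def cross_condition_accuracy(model: _svm.LinearModel, split: ConditionSplit) -> float:
    """Accuracy of one condition's model on another's best-fold test set."""
    return _svm.accuracy(_svm.predict(model, split.test_X), split.test_y)


@dataclass
class AccuracyTable:
    """Long-form (train condition x test condition) accuracy table.

    One row per cell with columns train_condition, test_condition,
    accuracy, and optional p_perm / p_binom; ``variant`` names the
    analysis (whole_map, excluded, restricted).
    """

    variant: str
    cells: pd.DataFrame

    def cell(self, train_condition: str, test_condition: str) -> pd.Series:
        m = self.cells[
            (self.cells["train_condition"] == train_condition)
            & (self.cells["test_condition"] == test_condition)
        ]
        if len(m) != 1:
            raise KeyError(f"no unique cell ({train_condition}, {test_condition})")
        return m.iloc[0]

    def accuracy(self, train_condition: str, test_condition: str) -> float:
        return float(self.cell(train_condition, test_condition)["accuracy"])


def evaluate_restricted(
    knockout: KnockoutMask,
    splits: dict,
    n_perm: int | None = None,
    seed: int = 0,
) -> tuple[AccuracyTable, dict]:
    """Retrain every condition on the knock-out voxels only.

    Fills the full train x test grid: the diagonal is within-condition
    accuracy, off-diagonal cells apply one condition's restricted model
    to another condition's best-fold test examples. When ``n_perm`` is
    given, each cell also gets a training-label permutation p-value.
    Returns the table and the restricted models per condition.
    """
    if knockout.size == 0:
        raise ValueError("knock-out mask is empty")
    models = {
        name: fit_on_features(s.train_X, s.train_y, knockout.voxels)
        for name, s in splits.items()
    }
    rows = []
    for i, (train_name, model) in enumerate(models.items()):
        for test_name, split in splits.items():
            acc = cross_condition_accuracy(model, split)
            p_perm = np.nan
            if n_perm:
                tr = splits[train_name]
                null_fn = svm_accuracy_null(
                    tr.train_X[:, knockout.voxels],
                    tr.train_y,
                    split.test_X[:, knockout.voxels],
                    split.test_y,
                )
                cell_seed = (seed + 1009 * i + 131 * len(rows)) % (2**31)
                p_perm = permutation_test(acc, null_fn, n_perm=n_perm, seed=cell_seed).p_value
            rows.append((train_name, test_name, acc, p_perm, np.nan))
    table = pd.DataFrame(
        rows, columns=["train_condition", "test_condition", "accuracy", "p_perm", "p_binom"]
    )
    return AccuracyTable("restricted", table), models


@dataclass
class PantomimeResult:
    fraction_action: float
    n_examples: int
    p_binomial: float
    p_permutation: float | None = None


def classify_pantomime(
    model: _svm.LinearModel,
    pantomime_X: np.ndarray,
    train_X: np.ndarray | None = None,
    train_y: np.ndarray | None = None,
    n_perm: int | None = None,
    seed: int = 0,
) -> PantomimeResult:
    """Fraction of motor-pantomime examples labeled "action".

    Pantomimes are test-only probes: the null hypothesis is that the
    classifier labels them "action" at rate 0.5. The binomial p is the
    exact upper tail; when the training matrix is supplied a permutation
    p is computed by re-fitting with shuffled training labels and
    re-scoring the action-labeling rate.
    """
    pantomime_X = np.asarray(pantomime_X, dtype=float)
    if pantomime_X.shape[0] == 0:
        raise ValueError("no pantomime examples to classify")
    pred = _svm.predict(model, pantomime_X)
    k = int(np.sum(pred == 1))
    n = pred.size
    frac = k / n
    p_binom = binomial_test(k, n, 0.5, alternative="greater")
    p_perm = None
    if n_perm and train_X is not None:
        feats = model.feature_indices
        Xtr = train_X if feats is None else np.asarray(train_X)[:, feats]
        Xpa = pantomime_X if feats is None else pantomime_X[:, feats]

        def null_fn(rng):
            y_perm = rng.permutation(np.asarray(train_y, dtype=int))
            m = _svm.train(Xtr, y_perm, C=model.c_param, tol=1e-3)
            return float(np.mean(_svm.predict(m, Xpa) == 1))

        p_perm = permutation_test(frac, null_fn, n_perm=n_perm, seed=seed).p_value
    return PantomimeResult(
        fraction_action=frac, n_examples=n, p_binomial=p_binom, p_permutation=p_perm
    )
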