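"""Balanced, scaled, fold-assigned classification matrices per condition.

An experimental condition is a (group, modality) cell of the design:
sighted-auditory, sighted-visual or blind-auditory (blind-visual does
not exist). Class imbalance between action and non-action stimuli is
removed by random up-sampling (duplication) of the minority class and
random down-sampling of the majority class, applied at the stimulus
level so every subject receives the identical stimulus selection. Beta
values are then squashed into (-1, +1) with a hyperbolic tangent, and
stimuli are dealt into class-stratified cross-validation folds.
Up-sampled duplicates always follow their original into a fold, so a
stimulus never straddles the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ExampleSet

#: The three valid (group, modality) condition cells.
CONDITIONS = (
    ("sighted", "visual"),
    ("sighted", "auditory"),
    ("blind", "auditory"),
)


@dataclass(frozen=True)
class ConditionSpec:
    group: str
    modality: str

    def __post_init__(self) -> None:
        if (self.group, self.modality) not in CONDITIONS:
            raise ValueError(
                f"invalid condition {(self.group, self.modality)}; "
                f"valid conditions are {CONDITIONS}"
            )

    @property
    def name(self) -> str:
        return f"{self.group}_{self.modality}"


@dataclass(frozen=True)
class FoldAssignment:
    """Stimulus-level fold labels for one condition.

    ``mapping`` sends each original stimulus_id to a fold in 1..k.
    Up-sampled duplicates are resolved through their ``duplicate_of``
    field, never assigned a fold of their own.
    """

    mapping: dict
    k: int

    def fold_of(self, stimulus_id: str, duplicate_of: str | None = None) -> int:
        key = duplicate_of if duplicate_of not in (None, "") and not pd.isna(duplicate_of) else stimulus_id
        if key not in self.mapping:
            raise KeyError(f"stimulus {key!r} has no fold assignment")
        return self.mapping[key]

    def folds_for(self, exset: ExampleSet) -> np.ndarray:
        """Per-example fold index array for an ExampleSet."""
        return np.array(
            [
                self.fold_of(sid, dup)
                for sid, dup in zip(exset.meta["stimulus_id"], exset.meta["duplicate_of"])
            ],
            dtype=int,
        )


def _check_single_condition(exset: ExampleSet) -> None:
    cells = set(zip(exset.meta["group"], exset.meta["modality"]))
    if len(cells) != 1:
        raise ValueError(f"expected examples from exactly one condition, got {sorted(cells)}")


def balance_classes(exset: ExampleSet, target_per_class: int = 20, seed: int = 0) -> ExampleSet:
    """Equalise action / non-action counts per subject by up/down-sampling.

    The stimulus lists are adjusted once per condition and applied to
    every subject: a class short of ``target_per_class`` stimuli has
    random stimuli duplicated (uniformly, without replacement within a
    round, whole rounds when the deficit exceeds the class size — so a
    10-stimulus class reaching 20 is exactly doubled), a class over
    target is randomly down-sampled. Duplicated examples carry
    ``duplicate_of`` pointing at their source stimulus. A class already
    at target passes through untouched.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    _check_single_condition(exset)
    if (exset.meta["class_label"] == "pantomime").any():
        raise ValueError("pantomime examples cannot enter class balancing")
    rng = np.random.default_rng(seed)

    keep_rows = np.ones(exset.n_examples, dtype=bool)
    dup_blocks: list[tuple[np.ndarray, str, str]] = []  # (row indices, new id, original id)

    for label in ("action", "non_action"):
        in_class = (exset.meta["class_label"] == label).to_numpy()
        stim_ids = sorted(exset.meta.loc[in_class, "stimulus_id"].unique())
        if not stim_ids:
            raise ValueError(f"condition has no {label} examples")
        n = len(stim_ids)
        if n > target_per_class:  # down-sample: random stimulus subset
            keep = set(rng.choice(stim_ids, size=target_per_class, replace=False))
            drop = in_class & ~exset.meta["stimulus_id"].isin(keep).to_numpy()
            keep_rows &= ~drop
        elif n < target_per_class:  # up-sample: duplicate without replacement per round
            deficit = target_per_class - n
            chosen: list[str] = []
            round_no = 1
            while deficit > 0:
                take = min(deficit, n)
                picked = rng.choice(stim_ids, size=take, replace=False)
                chosen.extend((sid, round_no) for sid in picked)
                deficit -= take
                round_no += 1
            for sid, round_no in chosen:
                rows = np.flatnonzero(in_class & (exset.meta["stimulus_id"] == sid).to_numpy())
                dup_blocks.append((rows, f"{sid}#dup{round_no}", sid))

    X_parts = [exset.X[keep_rows]]
    meta_parts = [exset.meta.loc[keep_rows]]
    for rows, new_id, original in dup_blocks:
        X_parts.append(exset.X[rows])
        block = exset.meta.loc[rows].copy()
        block["stimulus_id"] = new_id
        block["duplicate_of"] = original
        meta_parts.append(block)

    if not dup_blocks and keep_rows.all():
        return exset
    X = np.vstack(X_parts)
    meta = pd.concat(meta_parts, ignore_index=True)
    return ExampleSet(X, meta, exset.grid, exset.scaled)


def tanh_transform(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """tanh((X - mean) / sd) with zero-variance voxels mapped to 0."""
    sd = np.asarray(sd, dtype=float)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return np.tanh(Z)


def scale_tanh(exset: ExampleSet) -> ExampleSet:
    """Standardise each voxel across examples, then apply tanh.

    Every output value is strictly inside (-1, +1); a voxel with zero
    variance maps to 0 everywhere. Double scaling is refused.
    """
    if exset.scaled:
        raise ValueError("ExampleSet is already scaled; refusing to scale twice")
    mean = exset.X.mean(axis=0)
    sd = exset.X.std(axis=0)
    X = tanh_transform(exset.X, mean, sd)
    return ExampleSet(X, exset.meta.copy(), exset.grid, scaled=True)


def make_folds(
    stimulus_ids,
    class_labels,
    k: int = 4,
    seed: int = 0,
) -> FoldAssignment:
    """Deal original stimuli into ``k`` class-stratified folds.

    Per class the shuffled stimuli go round-robin into folds 1..k, so
    per-class fold sizes differ by at most one. Pass original stimuli
    only; duplicates inherit their source's fold through
    ``FoldAssignment.fold_of``.
    """
    stimulus_ids = list(stimulus_ids)
    class_labels = list(class_labels)
    if len(stimulus_ids) != len(class_labels):
        raise ValueError("stimulus_ids and class_labels lengths differ")
    if len(set(stimulus_ids)) != len(stimulus_ids):
        raise ValueError("stimulus_ids must be unique")
    rng = np.random.default_rng(seed)
    mapping: dict[str, int] = {}
    for label in sorted(set(class_labels)):
        ids = sorted(sid for sid, lab in zip(stimulus_ids, class_labels) if lab == label)
        if len(ids) < k:
            raise ValueError(f"class {label!r} has {len(ids)} stimuli, fewer than k={k} folds")
        rng.shuffle(ids)
        for pos, sid in enumerate(ids):
            mapping[sid] = pos % k + 1
    return FoldAssignment(mapping=mapping, k=k)


def condition_folds(exset: ExampleSet, k: int = 4, seed: int = 0) -> FoldAssignment:
    """Fold assignment for a balanced condition ExampleSet."""
    originals = exset.meta[exset.meta["duplicate_of"].isna()]
    stim = originals.drop_duplicates("stimulus_id")
    return make_folds(stim["stimulus_id"], stim["class_label"], k=k, seed=seed)
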