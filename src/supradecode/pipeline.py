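"""End-to-end experiment: generate, assemble, select, knock out, test.

`run_experiment` reproduces the full analysis workflow on a synthetic
dataset: per-condition balancing and tanh scaling, 4-fold nested
cross-validation with RFE, best-fold selection, the combined supramodal
classifier and knock-out mask, exclusion / restriction re-evaluation,
cross-condition and cross-group generalization, pantomime probing, and
the permutation / Wilcoxon / Fisher / binomial inference layer. Because
the data are synthetic, the result also carries ground-truth recovery
diagnostics (Jaccard overlap of selected voxel sets with the generating
clusters).

Scaling convention: every example is scaled within its own acquisition
condition (the per-voxel mean/SD of that condition's balanced
perception matrix), including motor-pantomime probes, which use the
statistics of the perception condition of their group and session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import svm as _svm
from .assembly import (
    CONDITIONS,
    FoldAssignment,
    balance_classes,
    condition_folds,
    tanh_transform,
)
from .config import ExperimentConfig
from .grid import VoxelGrid
from .rfe import NestedCVResult, RFEConfig, fit_on_features, make_map, nested_cv
from .stats import fisher_combine, permutation_test, svm_accuracy_null, wilcoxon_signed_rank
from .supramodal import (
    AccuracyTable,
    ConditionSplit,
    ExclusionResult,
    KnockoutMask,
    SupramodalResult,
    best_fold_splits,
    classify_pantomime,
    cross_condition_accuracy,
    evaluate_excluding,
    evaluate_restricted,
    train_supramodal,
)
from .synthetic import (
    DesignSpec,
    ExampleSet,
    GroundTruth,
    default_cluster_spec,
    generate_examples,
    generate_ground_truth,
)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |a & b| / |a | b| of two voxel-index sets."""
    a = set(np.asarray(a, dtype=np.intp).tolist())
    b = set(np.asarray(b, dtype=np.intp).tolist())
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def truth_set_for_condition(gt: GroundTruth, modality: str) -> np.ndarray:
    """Voxels actually informative for one perception condition: the
    shared set plus the modality's own set, each only if its effect is
    nonzero."""
    parts = []
    if gt.effect_size["shared"] != 0.0 and gt.shared.size:
        parts.append(gt.shared)
    mod = gt.set_for_modality(modality)
    if gt.effect_size[modality] != 0.0 and mod.size:
        parts.append(mod)
    return np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.intp)


@dataclass
class ConditionData:
    """One condition's balanced matrix, its scaling statistics, the
    scaled matrix used for classification, and the fold assignment."""

    name: str
    group: str
    modality: str
    balanced: ExampleSet
    scaled: ExampleSet
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    folds: FoldAssignment


def make_dataset(config: ExperimentConfig):
    """Grid, ground truth and raw example set for a configuration."""
    grid = VoxelGrid(config.grid_dims, config.voxel_size_mm)
    spec = default_cluster_spec(grid, config.cluster_sizes)
    gt = generate_ground_truth(grid, spec, seed=config.seed, effect_size=config.effect_size)
    data = generate_examples(gt, config.design, grid)
    return grid, gt, data


def prepare_conditions(data: ExampleSet, config: ExperimentConfig) -> dict:
    """Balance, scale and fold-assign every valid condition cell."""
    conditions = {}
    for i, (group, modality) in enumerate(CONDITIONS):
        raw = data.select(group=group, modality=modality)
        if raw.n_examples == 0:
            raise ValueError(f"dataset has no examples for condition {group}/{modality}")
        balanced = balance_classes(
            raw, target_per_class=config.target_per_class, seed=config.seed + 17 * i + 1
        )
        mean = balanced.X.mean(axis=0)
        sd = balanced.X.std(axis=0)
        scaled = ExampleSet(
            tanh_transform(balanced.X, mean, sd), balanced.meta.copy(), balanced.grid, scaled=True
        )
        folds = condition_folds(balanced, k=config.rfe.k_folds, seed=config.seed + 29 * i + 2)
        name = f"{group}_{modality}"
        conditions[name] = ConditionData(
            name=name,
            group=group,
            modality=modality,
            balanced=balanced,
            scaled=scaled,
            scale_mean=mean,
            scale_sd=sd,
            folds=folds,
        )
    return conditions


def pantomime_matrix(
    data: ExampleSet, conditions: dict, group: str, sessions: tuple
) -> np.ndarray:
    """Scaled pantomime patterns of one group, pooled over sessions.

    Each session's pantomimes are scaled with its own perception
    condition's statistics (sighted visual-session pantomimes with the
    sighted_visual stats, auditory-session ones with the group's
    auditory stats).
    """
    blocks = []
    for session in sessions:
        probe = data.select(group=group, class_label="pantomime", session=session)
        if probe.n_examples == 0:
            continue
        cond = conditions[f"{group}_{session}"]
        blocks.append(tanh_transform(probe.X, cond.scale_mean, cond.scale_sd))
    if not blocks:
        raise ValueError(f"no pantomime examples for group {group!r}")
    return np.vstack(blocks)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    grid: VoxelGrid
    ground_truth: GroundTruth
    conditions: dict
    ncv: NestedCVResult
    best_fold: int
    counts: dict
    within: dict
    whole_map_table: AccuracyTable
    supramodal: SupramodalResult
    supramodal_p: float | None
    exclusion: dict
    fisher_exclusion_p: float | None
    restricted_table: AccuracyTable
    pantomime: pd.DataFrame
    recovery: dict

    def report(self) -> dict:
        """JSON-serializable summary of every computed quantity."""
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "best_fold": self.best_fold,
            "counts": self.counts,
            "ncv_summary": self.ncv.summary,
            "within": self.within,
            "whole_map_table": self.whole_map_table.cells.to_dict(orient="records"),
            "supramodal": {
                "n_voxels": int(self.supramodal.knockout.size),
                "accuracy": float(self.supramodal.pooled_accuracy),
                "p_perm": self.supramodal_p,
            },
            "exclusion": self.exclusion,
            "fisher_exclusion_p": self.fisher_exclusion_p,
            "restricted_table": self.restricted_table.cells.to_dict(orient="records"),
            "pantomime": self.pantomime.to_dict(orient="records"),
            "recovery": self.recovery,
        }


def _per_subject_accuracy(pred, truth, subjects) -> pd.Series:
    ok = pd.Series(np.asarray(pred) == np.asarray(truth), index=None)
    return ok.groupby(list(subjects)).mean()


def run_experiment(config: ExperimentConfig, with_permutations: bool = True) -> ExperimentResult:
    """Generate a synthetic dataset and run the full analysis on it."""
    grid, gt, data = make_dataset(config)
    return analyze_dataset(data, grid, config, gt=gt, with_permutations=with_permutations)


def analyze_dataset(
    data: ExampleSet,
    grid: VoxelGrid,
    config: ExperimentConfig,
    gt: GroundTruth | None = None,
    with_permutations: bool = True,
) -> ExperimentResult:
    """Full analysis of an in-memory dataset (synthetic or loaded).

    Ground-truth recovery diagnostics are filled only when the
    generating GroundTruth is supplied.
    """
    conditions = prepare_conditions(data, config)
    n_perm = config.stats.n_perm if with_permutations else None
    rng_seeds = iter(np.random.SeedSequence(config.seed + 4099).generate_state(256) % (2**31))

    counts = {}
    for name, cond in conditions.items():
        by_class = cond.balanced.meta["class_label"].value_counts().to_dict()
        counts[name] = {"total": int(cond.balanced.n_examples), **{k: int(v) for k, v in by_class.items()}}
    for group in ("sighted", "blind"):
        counts[f"pantomime_{group}"] = int(
            (data.meta["class_label"].eq("pantomime") & data.meta["group"].eq(group)).sum()
        )

    # -- nested cross-validation with RFE --------------------------------
    cond_sets = {name: c.scaled for name, c in conditions.items()}
    cond_folds = {name: c.folds for name, c in conditions.items()}
    ncv = nested_cv(cond_sets, cond_folds, grid, config.rfe, scaling=config.scaling)
    best_fold = ncv.best_fold
    best = ncv.best_record
    splits = best_fold_splits(cond_sets, cond_folds, best_fold, scaling=config.scaling)

    # whole-map models: refit on each condition's best-fold best voxel set
    whole_models = {
        name: fit_on_features(splits[name].train_X, splits[name].train_y, best.best_sets[name])
        for name in conditions
    }

    def perm_p(model, train_split, test_split) -> float | None:
        if not n_perm:
            return None
        feats = model.feature_indices
        obs = _svm.accuracy(_svm.predict(model, test_split.test_X), test_split.test_y)
        null_fn = svm_accuracy_null(
            train_split.train_X[:, feats],
            train_split.train_y,
            test_split.test_X[:, feats],
            test_split.test_y,
            C=model.c_param,
        )
        return permutation_test(obs, null_fn, n_perm=n_perm, seed=int(next(rng_seeds))).p_value

    within = {}
    rows = []
    for train_name, model in whole_models.items():
        for test_name in conditions:
            acc = cross_condition_accuracy(model, splits[test_name])
            p = perm_p(model, splits[train_name], splits[test_name])
            rows.append((train_name, test_name, acc, np.nan if p is None else p, np.nan))
            if train_name == test_name:
                within[train_name] = {
                    "accuracy": acc,
                    "p_perm": p,
                    "n_test": int(splits[test_name].test_y.size),
                    "n_voxels": int(best.best_sets[train_name].size),
                }
    whole_table = AccuracyTable(
        "whole_map",
        pd.DataFrame(rows, columns=["train_condition", "test_condition", "accuracy", "p_perm", "p_binom"]),
    )

    # -- supramodal classifier and knock-out mask ------------------------
    supra = train_supramodal(splits, grid, config.rfe)
    supramodal_p = None
    if n_perm:
        Xtr = np.vstack([s.train_X for s in splits.values()])[:, supra.knockout.voxels]
        ytr = np.concatenate([s.train_y for s in splits.values()])
        Xte = np.vstack([s.test_X for s in splits.values()])[:, supra.knockout.voxels]
        yte = np.concatenate([s.test_y for s in splits.values()])
        supramodal_p = permutation_test(
            supra.pooled_accuracy,
            svm_accuracy_null(Xtr, ytr, Xte, yte),
            n_perm=n_perm,
            seed=int(next(rng_seeds)),
        ).p_value

    # -- exclusion (knock-out removal) ------------------------------------
    exclusion: dict = {}
    wilcoxon_ps = []
    excl_models = {}
    for name, cond in conditions.items():
        res = evaluate_excluding(best.best_sets[name], supra.knockout, splits[name])
        excl_models[name] = res.model
        entry = {
            "accuracy": res.accuracy,
            "n_voxels": int(res.surviving.size),
            "empty_survivor_set": res.empty_survivor_set,
            "p_perm": None,
            "wilcoxon_p": None,
        }
        if res.model is not None and n_perm:
            entry["p_perm"] = perm_p(res.model, splits[name], splits[name])
        # paired per-subject accuracies, whole map vs excluded
        if res.model is not None:
            folds = cond.folds.folds_for(cond.scaled)
            test_mask = folds == best_fold
            subjects = cond.scaled.meta.loc[test_mask, "subject_id"].to_numpy()
            yte = splits[name].test_y
            acc_whole = _per_subject_accuracy(
                _svm.predict(whole_models[name], splits[name].test_X), yte, subjects
            )
            acc_excl = _per_subject_accuracy(
                _svm.predict(res.model, splits[name].test_X), yte, subjects
            )
            try:
                wp = wilcoxon_signed_rank(acc_whole.to_numpy(), acc_excl.to_numpy())
            except ValueError:  # too few informative pairs: no evidence of a drop
                wp = 1.0
            entry["wilcoxon_p"] = wp
            wilcoxon_ps.append(wp)
        exclusion[name] = entry
    fisher_p = fisher_combine(wilcoxon_ps) if wilcoxon_ps else None

    # -- restriction to the knock-out mask --------------------------------
    restricted_table, restr_models = evaluate_restricted(
        supra.knockout, splits, n_perm=n_perm, seed=int(next(rng_seeds))
    )

    # -- pantomime probing -------------------------------------------------
    pant_X = {
        "sighted": pantomime_matrix(data, conditions, "sighted", ("auditory", "visual")),
        "blind": pantomime_matrix(data, conditions, "blind", ("auditory",)),
    }
    variant_models = {
        "whole_map": whole_models,
        "excluded": excl_models,
        "restricted": restr_models,
    }
    pant_rows = []
    for variant, models in variant_models.items():
        for clf_name, model in models.items():
            if model is None:
                continue
            for pgroup, X in pant_X.items():
                res = classify_pantomime(
                    model,
                    X,
                    train_X=splits[clf_name].train_X,
                    train_y=splits[clf_name].train_y,
                    n_perm=n_perm,
                    seed=int(next(rng_seeds)),
                )
                pant_rows.append(
                    (variant, clf_name, pgroup, res.fraction_action, res.n_examples,
                     res.p_binomial, res.p_permutation)
                )
    # the combined supramodal classifier probed with pantomimes as well
    supra_train_X = np.vstack([s.train_X for s in splits.values()])
    supra_train_y = np.concatenate([s.train_y for s in splits.values()])
    for pgroup, X in pant_X.items():
        res = classify_pantomime(
            supra.model, X, train_X=supra_train_X, train_y=supra_train_y,
            n_perm=n_perm, seed=int(next(rng_seeds)),
        )
        pant_rows.append(
            ("restricted", "supramodal", pgroup, res.fraction_action, res.n_examples,
             res.p_binomial, res.p_permutation)
        )
    pantomime = pd.DataFrame(
        pant_rows,
        columns=["variant", "classifier", "pantomime_group", "fraction_action", "n", "p_binom", "p_perm"],
    )

    # -- ground-truth recovery diagnostics --------------------------------
    recovery = {}
    if gt is not None:
        recovery = {
            name: jaccard(best.best_sets[name], truth_set_for_condition(gt, cond.modality))
            for name, cond in conditions.items()
        }
        recovery["supramodal_vs_shared"] = jaccard(supra.knockout.voxels, gt.shared)
        recovery["supramodal_vs_auditory"] = jaccard(supra.knockout.voxels, gt.auditory)
        recovery["supramodal_vs_visual"] = jaccard(supra.knockout.voxels, gt.visual)

    return ExperimentResult(
        config=config,
        grid=grid,
        ground_truth=gt,
        conditions=conditions,
        ncv=ncv,
        best_fold=best_fold,
        counts=counts,
        within=within,
        whole_map_table=whole_table,
        supramodal=supra,
        supramodal_p=supramodal_p,
        exclusion=exclusion,
        fisher_exclusion_p=fisher_p,
        restricted_table=restricted_table,
        pantomime=pantomime,
        recovery=recovery,
    )
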