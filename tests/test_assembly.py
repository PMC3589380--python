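import numpy as np
import pandas as pd
import pytest

from supradecode.assembly import (
    ConditionSpec,
    balance_classes,
    condition_folds,
    make_folds,
    scale_tanh,
)
from supradecode.grid import VoxelGrid
from supradecode.synthetic import DesignSpec, ExampleSet, generate_examples, generate_ground_truth


@pytest.fixture(scope="module")
def raw_data():
    """Full study design on a tiny grid (values irrelevant, counts exact)."""
    grid = VoxelGrid((4, 4, 4))
    gt = generate_ground_truth(grid, {}, seed=0)
    return generate_examples(gt, DesignSpec(noise_sd=0.1, seed=3), grid)


def test_blind_visual_condition_is_invalid():
    with pytest.raises(ValueError):
        ConditionSpec("blind", "visual")
    assert ConditionSpec("sighted", "visual").name == "sighted_visual"


class TestBalancing:
    def test_sighted_auditory_reaches_560_examples(self, raw_data):
        cond = raw_data.select(group="sighted", modality="auditory")
        bal = balance_classes(cond, target_per_class=20, seed=0)
        counts = bal.meta["class_label"].value_counts()
        assert bal.n_examples == 560
        assert counts["action"] == 280 and counts["non_action"] == 280
        # non-action sounds (10 -> 20) are exactly doubled
        dups = bal.meta[bal.meta.duplicate_of.notna()]
        assert sorted(dups["duplicate_of"].unique()) == sorted(
            cond.meta.loc[cond.meta.class_label == "non_action", "stimulus_id"].unique()
        )

    def test_blind_auditory_reaches_320_examples(self, raw_data):
        cond = raw_data.select(group="blind", modality="auditory")
        bal = balance_classes(cond, target_per_class=20, seed=0)
        counts = bal.meta["class_label"].value_counts()
        assert bal.n_examples == 320
        assert counts["action"] == 160 and counts["non_action"] == 160

    def test_sighted_visual_downsamples_actions(self, raw_data):
        cond = raw_data.select(group="sighted", modality="visual")
        bal = balance_classes(cond, target_per_class=20, seed=0)
        assert bal.n_examples == 560
        # 23 action videos down to 20 distinct stimuli, no action duplicates
        act = bal.meta[bal.meta.class_label == "action"]
        assert act["stimulus_id"].nunique() == 20
        assert act["duplicate_of"].isna().all()

    def test_per_subject_counts_are_equal(self, raw_data):
        cond = raw_data.select(group="sighted", modality="auditory")
        bal = balance_classes(cond, target_per_class=20, seed=1)
        per = bal.meta.groupby(["subject_id", "class_label"]).size()
        assert (per == 20).all()

    def test_identical_stimulus_selection_across_subjects(self, raw_data):
        cond = raw_data.select(group="sighted", modality="visual")
        bal = balance_classes(cond, target_per_class=20, seed=2)
        per_subject = bal.meta.groupby("subject_id")["stimulus_id"].apply(frozenset)
        assert per_subject.nunique() == 1

    def test_already_balanced_input_is_unchanged(self, raw_data):
        cond = raw_data.select(group="sighted", modality="auditory")
        bal = balance_classes(cond, target_per_class=20, seed=0)
        again = balance_classes(bal, target_per_class=20, seed=5)
        assert again is bal

    def test_voxel_dimension_never_changes(self, raw_data):
        cond = raw_data.select(group="blind", modality="auditory")
        bal = balance_classes(cond, target_per_class=7, seed=0)
        assert bal.n_voxels == cond.n_voxels

    def test_empty_class_raises(self, raw_data):
        cond = raw_data.select(group="blind", modality="auditory")
        only_action = ExampleSet(
            cond.X[cond.meta.class_label == "action"],
            cond.meta[cond.meta.class_label == "action"],
            cond.grid,
        )
        with pytest.raises(ValueError):
            balance_classes(only_action, target_per_class=5, seed=0)


class TestScaling:
    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        grid = VoxelGrid((3, 3, 3))
        X = rng.normal(0, 50, size=(20, grid.n_voxels))
        exset = _wrap(X, grid)
        out = scale_tanh(exset)
        assert out.scaled
        assert np.all(np.abs(out.X) < 1.0)

    def test_constant_voxel_maps_to_zero(self):
        grid = VoxelGrid((3, 3, 3))
        X = np.ones((10, grid.n_voxels))
        X[:, 1:] = np.random.default_rng(1).normal(size=(10, grid.n_voxels - 1))
        out = scale_tanh(_wrap(X, grid))
        assert np.all(out.X[:, 0] == 0.0)

    def test_rank_order_preserved_per_voxel(self):
        rng = np.random.default_rng(2)
        grid = VoxelGrid((5, 2, 2))
        X = rng.normal(size=(50, grid.n_voxels))
        out = scale_tanh(_wrap(X, grid))
        for j in range(grid.n_voxels):
            assert np.array_equal(np.argsort(X[:, j]), np.argsort(out.X[:, j]))

    def test_double_scaling_refused(self):
        grid = VoxelGrid((2, 2, 2))
        out = scale_tanh(_wrap(np.random.default_rng(3).normal(size=(8, 8)), grid))
        with pytest.raises(ValueError):
            scale_tanh(out)


def _wrap(X, grid):
    n = X.shape[0]
    meta = pd.DataFrame(
        {
            "class_label": ["action", "non_action"] * (n // 2) + ["action"] * (n % 2),
            "modality": "auditory",
            "group": "sighted",
            "subject_id": "s01",
            "stimulus_id": [f"st{i}" for i in range(n)],
            "duplicate_of": [None] * n,
            "session": "auditory",
        }
    )
    return ExampleSet(X, meta, grid, scaled=False)


class TestFolds:
    def test_exact_division_five_per_class_per_fold(self):
        ids = [f"a{i}" for i in range(20)] + [f"n{i}" for i in range(20)]
        labels = ["action"] * 20 + ["non_action"] * 20
        fa = make_folds(ids, labels, k=4, seed=0)
        per_fold = pd.Series(fa.mapping).groupby(lambda sid: (sid[0], fa.mapping[sid])).size()
        counts = pd.Series(fa.mapping).value_counts()
        assert sorted(counts) == [10, 10, 10, 10]
        for cls in ("a", "n"):
            cls_folds = [f for sid, f in fa.mapping.items() if sid.startswith(cls)]
            assert sorted(pd.Series(cls_folds).value_counts()) == [5, 5, 5, 5]

    def test_every_stimulus_in_exactly_one_fold(self):
        ids = [f"s{i}" for i in range(13)]
        labels = ["action"] * 7 + ["non_action"] * 6
        fa = make_folds(ids, labels, k=4, seed=1)
        assert set(fa.mapping) == set(ids)
        assert all(1 <= f <= 4 for f in fa.mapping.values())

    def test_stratified_fold_sizes_differ_by_at_most_one(self):
        ids = [f"s{i}" for i in range(13)]
        labels = ["action"] * 7 + ["non_action"] * 6
        fa = make_folds(ids, labels, k=4, seed=2)
        for cls, n_cls in (("action", 7), ("non_action", 6)):
            sizes = pd.Series(
                [f for sid, f in fa.mapping.items() if labels[ids.index(sid)] == cls]
            ).value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_fewer_stimuli_than_folds_raises(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], ["action", "action", "non_action"], k=4, seed=0)

    def test_duplicates_never_straddle_train_test(self, raw_data):
        """Leak audit: over every fold, an upsampled copy is always on the
        same side of the split as its original."""
        cond = raw_data.select(group="sighted", modality="auditory")
        bal = balance_classes(cond, target_per_class=20, seed=4)
        fa = condition_folds(bal, k=4, seed=4)
        folds = fa.folds_for(bal)
        dup_rows = bal.meta["duplicate_of"].notna().to_numpy()
        for i in np.flatnonzero(dup_rows):
            orig = bal.meta.loc[i, "duplicate_of"]
            assert folds[i] == fa.mapping[orig]

    def test_fixed_seed_reproducible(self):
        ids = [f"s{i}" for i in range(16)]
        labels = (["action"] * 8) + (["non_action"] * 8)
        a = make_folds(ids, labels, k=4, seed=9)
        b = make_folds(ids, labels, k=4, seed=9)
        assert a.mapping == b.mapping
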