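import numpy as np
import pytest

from supradecode import svm as _svm
from supradecode.grid import VoxelGrid
from supradecode.pipeline import make_dataset, prepare_conditions, truth_set_for_condition
from supradecode.rfe import (
    RFEConfig,
    RFETrace,
    eliminate_features,
    eliminate_step,
    fit_on_features,
    make_map,
    nested_cv,
    run_rfe,
)

from conftest import tiny_config


@pytest.fixture(scope="module")
def flat_cfg():
    """Config whose cluster correction is inert (min size 1)."""
    return RFEConfig(min_cluster_voxels=1)


class TestEliminate:
    def test_two_percent_of_100_features_removes_two(self, small_grid, flat_cfg):
        feats = np.arange(100)
        w = np.linspace(1.0, 2.0, 100)
        out = eliminate_features(w, feats, small_grid, flat_cfg)
        assert out.size == 98
        assert 0 not in out and 1 not in out

    def test_minimum_one_rule_for_small_sets(self, small_grid, flat_cfg):
        feats = np.arange(10)
        out = eliminate_features(np.ones(10), feats, small_grid, flat_cfg)
        assert out.size == 9

    def test_equal_weights_remove_lowest_indices_first(self, small_grid, flat_cfg):
        feats = np.array([5, 17, 40, 41, 90, 200])
        cfg = RFEConfig(elimination_fraction=0.4, min_cluster_voxels=1)
        out = eliminate_features(np.ones(6), feats, small_grid, cfg)
        # ceil(0.4 * 6) = 3 removals, ties resolved toward lower indices
        assert np.array_equal(out, np.array([41, 90, 200]))

    def test_output_is_strict_subset(self, small_grid, flat_cfg):
        rng = np.random.default_rng(0)
        feats = np.sort(rng.choice(small_grid.n_voxels, 60, replace=False))
        out = eliminate_features(rng.random(60), feats, small_grid, flat_cfg)
        assert set(out.tolist()) < set(feats.tolist())

    def test_cluster_correction_applied_after_removal(self, small_grid):
        # two 2x2x2 blocks; removing one voxel drops that block below min size
        grid = small_grid
        a = grid.ravel(np.array([(i, j, k) for i in range(2) for j in range(2) for k in range(2)]))
        b = grid.ravel(np.array([(i + 5, j + 5, k + 5) for i in range(2) for j in range(2) for k in range(2)]))
        feats = np.sort(np.concatenate([a, b]))
        w = np.ones(16)
        w[np.isin(feats, a[0])] = 0.0  # weakest voxel sits in block a
        cfg = RFEConfig(elimination_fraction=0.05, min_cluster_voxels=8)
        out = eliminate_features(w, feats, grid, cfg)
        assert set(out.tolist()) == set(b.tolist())

    def test_model_feature_mismatch_raises(self, small_grid, flat_cfg):
        m = _svm.LinearModel(np.ones(3), 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            eliminate_step(m, np.arange(5), small_grid, flat_cfg)


def _toy_problem(seed=0, n_tr=40, n_te=16, grid=None):
    grid = grid or VoxelGrid((5, 5, 5))
    rng = np.random.default_rng(seed)
    informative = grid.ravel(np.array([(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1)]))
    y_tr = np.array([1, -1] * (n_tr // 2))
    y_te = np.array([1, -1] * (n_te // 2))
    X_tr = rng.normal(0, 1, (n_tr, grid.n_voxels))
    X_te = rng.normal(0, 1, (n_te, grid.n_voxels))
    X_tr[y_tr == 1][:, informative] += 0  # keep signature simple
    X_tr[np.ix_(y_tr == 1, informative)] += 1.5
    X_te[np.ix_(y_te == 1, informative)] += 1.5
    return grid, X_tr, y_tr, X_te, y_te, informative


class TestRunRFE:
    def test_feature_counts_strictly_decrease_to_zero(self):
        grid, X_tr, y_tr, X_te, y_te, _ = _toy_problem()
        cfg = RFEConfig(min_cluster_voxels=1)
        trace = run_rfe(X_tr, y_tr, X_te, y_te, np.arange(grid.n_voxels), grid, cfg)
        counts = trace.feature_counts
        assert counts[0] == grid.n_voxels
        assert np.all(np.diff(counts) < 0)
        assert counts[-1] >= 1  # the last trained set; next elimination empties it
        assert np.all((trace.accuracies >= 0) & (trace.accuracies <= 1))

    def test_gram_downdating_matches_naive_reimplementation(self):
        """The kernel-downdating fast path must reproduce, iteration by
        iteration, a naive loop that retrains on the explicit submatrix."""
        grid, X_tr, y_tr, X_te, y_te, _ = _toy_problem(seed=3, n_tr=24, n_te=12)
        cfg = RFEConfig(min_cluster_voxels=1, svm_tol=1e-8)
        trace = run_rfe(X_tr, y_tr, X_te, y_te, np.arange(grid.n_voxels), grid, cfg)

        active = np.arange(grid.n_voxels)
        for feats, acc in trace.iterations:
            assert np.array_equal(feats, active)
            sub = X_tr[:, active]
            model = _svm.train(sub, y_tr, C=_svm.default_C(sub), tol=1e-8)
            naive_acc = _svm.accuracy(_svm.predict(model, X_te[:, active]), y_te)
            assert naive_acc == pytest.approx(acc, abs=1e-12)
            active = eliminate_step(model, active, grid, cfg)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_best_set_retains_informative_voxels(self, seed):
        """Elimination prunes noise voxels before signal voxels: the
        best-accuracy set keeps every informative voxel while shrinking
        well below the grid size."""
        grid, X_tr, y_tr, X_te, y_te, informative = _toy_problem(seed=seed, n_tr=60, n_te=30)
        cfg = RFEConfig(min_cluster_voxels=1)
        trace = run_rfe(X_tr, y_tr, X_te, y_te, np.arange(grid.n_voxels), grid, cfg)
        best = trace.best_feature_set
        assert np.isin(informative, best).all()
        assert best.size < grid.n_voxels / 2

    def test_deterministic_given_data(self):
        grid, X_tr, y_tr, X_te, y_te, _ = _toy_problem(seed=7)
        cfg = RFEConfig(min_cluster_voxels=1)
        t1 = run_rfe(X_tr, y_tr, X_te, y_te, np.arange(grid.n_voxels), grid, cfg)
        t2 = run_rfe(X_tr, y_tr, X_te, y_te, np.arange(grid.n_voxels), grid, cfg)
        assert np.array_equal(t1.accuracies, t2.accuracies)
        for (f1, _), (f2, _) in zip(t1.iterations, t2.iterations):
            assert np.array_equal(f1, f2)


class TestTrace:
    def test_best_iteration_prefers_smallest_tied_set(self):
        trace = RFETrace([(np.arange(30), 0.9), (np.arange(10), 0.9), (np.arange(3), 0.7)])
        assert trace.best_iteration() == 1
        assert trace.best_accuracy == 0.9
        assert trace.best_feature_set.size == 10

    def test_nondecreasing_sizes_rejected(self):
        with pytest.raises(ValueError):
            RFETrace([(np.arange(5), 0.5), (np.arange(5), 0.6)])


@pytest.fixture(scope="module")
def ncv_result():
    cfg = tiny_config(seed=21)
    grid, gt, data = make_dataset(cfg)
    conds = prepare_conditions(data, cfg)
    res = nested_cv(
        {n: c.scaled for n, c in conds.items()},
        {n: c.folds for n, c in conds.items()},
        grid,
        cfg.rfe,
    )
    return cfg, grid, gt, conds, res


class TestNestedCV:
    def test_four_folds_produced_and_best_fold_in_range(self, ncv_result):
        *_, res = ncv_result
        assert len(res.fold_records) == 4
        assert [r.fold for r in res.fold_records] == [1, 2, 3, 4]
        assert 1 <= res.best_fold <= 4

    def test_summary_mean_is_arithmetic_mean_of_fold_bests(self, ncv_result):
        *_, res = ncv_result
        for name, s in res.summary.items():
            accs = [r.best_accuracies[name] for r in res.fold_records]
            assert s["mean"] == pytest.approx(np.mean(accs), abs=1e-15)

    def test_best_fold_maximises_cross_condition_mean(self, ncv_result):
        *_, res = ncv_result
        means = [r.mean_best_accuracy for r in res.fold_records]
        assert means[res.best_fold - 1] == max(means)

    def test_fold_record_best_is_trace_maximum(self, ncv_result):
        *_, res = ncv_result
        for rec in res.fold_records:
            for name, trace in rec.traces.items():
                assert rec.best_accuracies[name] == pytest.approx(trace.accuracies.max())

    def test_joint_selection_uses_one_iteration_index(self, ncv_result):
        cfg, grid, gt, conds, _ = ncv_result
        from dataclasses import replace

        res = nested_cv(
            {n: c.scaled for n, c in conds.items()},
            {n: c.folds for n, c in conds.items()},
            grid,
            replace(cfg.rfe, joint_best_iteration=True),
        )
        for rec in res.fold_records:
            idx = {
                name: next(
                    i for i, (fs, _) in enumerate(trace.iterations)
                    if fs.size == rec.best_sets[name].size
                    and np.array_equal(fs, rec.best_sets[name])
                )
                for name, trace in rec.traces.items()
            }
            assert len(set(idx.values())) == 1


class TestMap:
    def test_singleton_set_gets_zero_z(self):
        m = _svm.LinearModel(np.array([2.5]), 0.0, 1.0, 0.0)
        dmap = make_map(m, np.array([12]))
        assert dmap.z_weights[0] == 0.0

    def test_z_weights_standardised(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=20)
        m = _svm.LinearModel(w, 0.0, 1.0, 0.0)
        dmap = make_map(m, np.arange(20))
        assert dmap.z_weights.mean() == pytest.approx(0.0, abs=1e-12)
        assert dmap.z_weights.var() == pytest.approx(1.0, rel=1e-12)

    def test_empty_set_raises(self):
        m = _svm.LinearModel(np.array([]), 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            make_map(m, np.array([], dtype=int))

    def test_nifti_roundtrip_preserves_membership(self, tmp_path, small_grid):
        from supradecode.io import read_map_voxels, write_map

        rng = np.random.default_rng(2)
        voxels = np.sort(rng.choice(small_grid.n_voxels, 25, replace=False))
        w = rng.normal(size=25)
        w[w == 0] = 0.5
        dmap = make_map(_svm.LinearModel(w, 0.0, 1.0, 0.0), voxels)
        w_path, _ = write_map(dmap, small_grid, tmp_path / "m")
        assert np.array_equal(read_map_voxels(w_path), voxels)


def test_fit_on_features_carries_indices():
    grid, X_tr, y_tr, *_ = _toy_problem(seed=9)
    feats = np.array([3, 10, 44])
    m = fit_on_features(X_tr, y_tr, feats)
    assert np.array_equal(m.feature_indices, feats)
    # model applies transparently to full-grid matrices
    d_full = m.decision_values(X_tr)
    d_sub = m.decision_values(X_tr[:, feats])
    assert np.allclose(d_full, d_sub)
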