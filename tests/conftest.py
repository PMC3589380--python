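from dataclasses import replace

import numpy as np
import pytest

from supradecode.config import ExperimentConfig
from supradecode.grid import VoxelGrid
from supradecode.pipeline import make_dataset, run_experiment
from supradecode.rfe import RFEConfig
from supradecode.synthetic import DesignSpec


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    return VoxelGrid((8, 8, 8))


def tiny_config(seed: int = 0, **effects) -> ExperimentConfig:
    """A fast, small-but-complete experiment configuration.

    6 sighted + 4 blind subjects, 8/4 sounds and 9/5 videos, 2
    pantomimes per subject per session, on an 8x8x8 grid with small
    informative clusters; used wherever a full pipeline object is
    needed quickly.
    """
    effect = dict({"shared": 1.0, "auditory": 1.0, "visual": 1.0, "motor": 1.0}, **effects)
    cfg = ExperimentConfig(
        grid_dims=(8, 8, 8),
        cluster_sizes={"shared": 10, "auditory": 6, "visual": 6, "motor": 6},
        effect_size=effect,
        design=DesignSpec(
            n_sighted=6,
            n_blind=4,
            n_action_sounds=8,
            n_nonaction_sounds=4,
            n_action_videos=9,
            n_nonaction_videos=5,
            n_pantomime_per_subject_per_session=2,
        ),
        target_per_class=8,
        rfe=RFEConfig(min_cluster_voxels=2, k_folds=4),
    )
    return cfg.with_seed(seed)


@pytest.fixture(scope="session")
def tiny_cfg() -> ExperimentConfig:
    return tiny_config(seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return make_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_result(tiny_cfg):
    """One full pipeline run (no permutation p-values) shared by tests."""
    return run_experiment(tiny_cfg, with_permutations=False)
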