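"""Synthetic multi-subject beta-pattern datasets with known informative voxels.

The generator emulates a cross-modal action-recognition study: two groups
(sighted, blind) hear action and environmental (non-action) sounds, the
sighted group additionally watches action / non-action videos, and both
groups execute motor pantomimes of object manipulation. Each stimulus
yields one beta pattern (a vector of per-voxel response amplitudes) per
subject. Ground-truth informative voxels come in four spatially
contiguous, pairwise disjoint sets: a shared ("supramodal") set S active
for actions in every modality, auditory-only (A), visual-only (V) and
motor-only (M) sets. Action-class examples carry an additive effect at
S plus the set of their modality; pantomime examples carry it at S plus
M. On top sit a per-subject scalar offset and i.i.d. Gaussian noise.

A small forward model of sparse-sampling acquisition (gamma-shaped
response sampled at a few volumes per trial, deconvolved by FIR least
squares) is included so the "average the middle volumes" beta-extraction
convention is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import VoxelGrid, connected_components

META_COLUMNS = [
    "class_label",
    "modality",
    "group",
    "subject_id",
    "stimulus_id",
    "duplicate_of",
    "session",
]

CLASS_LABELS = {"action", "non_action", "pantomime"}
MODALITIES = {"auditory", "visual", "motor"}
GROUPS = {"sighted", "blind"}

GROUND_TRUTH_SETS = ("shared", "auditory", "visual", "motor")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class ExampleSet:
    """A matrix of per-stimulus beta patterns plus per-example metadata.

    ``X`` has one row per example and one column per grid voxel (C
    order). ``meta`` carries the labels: class_label in {action,
    non_action, pantomime}, modality in {auditory, visual, motor}, group
    in {sighted, blind}, subject_id, stimulus_id, duplicate_of (set only
    on upsampled copies) and session in {auditory, visual} (the run type
    the example was acquired in; differs from modality only for
    pantomimes, which are motor-modality events embedded in auditory or
    visual runs).
    """

    X: np.ndarray
    meta: pd.DataFrame
    grid: VoxelGrid
    scaled: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (examples x voxels)")
        if self.X.shape[1] != self.grid.n_voxels:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but grid has {self.grid.n_voxels} voxels"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta and X row counts differ")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns {missing}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("beta values must be finite")
        bad_class = set(self.meta["class_label"]) - CLASS_LABELS
        if bad_class:
            raise ValueError(f"unknown class labels {sorted(bad_class)}")
        bad_mod = set(self.meta["modality"]) - MODALITIES
        if bad_mod:
            raise ValueError(f"unknown modalities {sorted(bad_mod)}")
        bad_grp = set(self.meta["group"]) - GROUPS
        if bad_grp:
            raise ValueError(f"unknown groups {sorted(bad_grp)}")
        is_pant = self.meta["class_label"] == "pantomime"
        is_motor = self.meta["modality"] == "motor"
        if not (is_pant == is_motor).all():
            raise ValueError("pantomime class and motor modality must coincide")
        if self.scaled and self.X.size and np.abs(self.X).max() >= 1.0:
            raise ValueError("scaled ExampleSet must have all values strictly in (-1, 1)")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def select(self, **criteria: str) -> "ExampleSet":
        """Subset by metadata equality, e.g. ``select(group="blind")``."""
        keep = np.ones(self.n_examples, dtype=bool)
        for col, value in criteria.items():
            if col not in self.meta.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            keep &= (self.meta[col] == value).to_numpy()
        return ExampleSet(self.X[keep], self.meta.loc[keep], self.grid, self.scaled)

    def labels(self) -> np.ndarray:
        """Class labels as +/-1 (+1 action, -1 non-action).

        Pantomime examples have no binary label (they are test-only
        probes) and raise.
        """
        y = np.where(self.meta["class_label"] == "action", 1, -1)
        if (self.meta["class_label"] == "pantomime").any():
            raise ValueError("pantomime examples carry no action/non-action label")
        return y.astype(int)

    @staticmethod
    def concat(parts: list["ExampleSet"]) -> "ExampleSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        grid = parts[0].grid
        scaled = parts[0].scaled
        if any(p.grid != grid for p in parts):
            raise ValueError("all parts must share one grid")
        if any(p.scaled != scaled for p in parts):
            raise ValueError("cannot mix scaled and unscaled parts")
        X = np.vstack([p.X for p in parts])
        meta = pd.concat([p.meta for p in parts], ignore_index=True)
        return ExampleSet(X, meta, grid, scaled)


@dataclass(frozen=True)
class GroundTruth:
    """The generator's informative voxel sets and their effect sizes.

    ``effect_size`` maps each set name to the mean beta difference
    (action minus non-action) its member voxels carry, in the same
    arbitrary BOLD-amplitude units as the noise standard deviation.
    """

    shared: np.ndarray
    auditory: np.ndarray
    visual: np.ndarray
    motor: np.ndarray
    effect_size: dict
    cluster_spec: dict

    def sets(self) -> dict:
        return {
            "shared": self.shared,
            "auditory": self.auditory,
            "visual": self.visual,
            "motor": self.motor,
        }

    def set_for_modality(self, modality: str) -> np.ndarray:
        return {"auditory": self.auditory, "visual": self.visual, "motor": self.motor}[modality]


@dataclass(frozen=True)
class DesignSpec:
    """Counts, noise levels and seed of one synthetic experiment.

    Defaults mirror the emulated study: 14 sighted and 8 blind subjects,
    20 action + 10 non-action sounds, 23 action + 11 non-action videos
    (sighted only), and 10 motor pantomimes per subject per session type
    (auditory sessions for everyone, visual sessions for the sighted).
    """

    n_sighted: int = 14
    n_blind: int = 8
    n_action_sounds: int = 20
    n_nonaction_sounds: int = 10
    n_action_videos: int = 23
    n_nonaction_videos: int = 11
    n_pantomime_per_subject_per_session: int = 10
    noise_sd: float = 0.5
    subject_offset_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_sighted,
            self.n_blind,
            self.n_action_sounds,
            self.n_nonaction_sounds,
            self.n_action_videos,
            self.n_nonaction_videos,
            self.n_pantomime_per_subject_per_session,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all design counts must be >= 0")
        if self.noise_sd < 0 or self.subject_offset_sd < 0:
            raise ValueError("noise and offset standard deviations must be >= 0")


# ---------------------------------------------------------------------------
# Ground-truth placement
# ---------------------------------------------------------------------------


def _grow_blob(
    grid: VoxelGrid,
    seed_coord: tuple[int, int, int],
    size: int,
    occupied: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Grow one face-connected blob of ``size`` voxels from a seed.

    Randomised breadth-first growth: repeatedly pick a random frontier
    voxel and claim it. Returns None when the region around the seed is
    too crowded to reach the requested size.
    """
    seed_idx = int(grid.ravel(np.array([seed_coord]))[0])
    if occupied[seed_idx]:
        return None
    nx, ny, nz = grid.dims
    chosen: list[int] = []
    in_frontier = np.zeros(grid.n_voxels, dtype=bool)
    frontier = [seed_idx]
    in_frontier[seed_idx] = True
    taken = occupied.copy()
    while len(chosen) < size and frontier:
        pos = int(rng.integers(len(frontier)))
        vox = frontier.pop(pos)
        if taken[vox]:
            continue
        chosen.append(vox)
        taken[vox] = True
        i, j, k = np.unravel_index(vox, grid.dims)
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz:
                nb = int(np.ravel_multi_index((ni, nj, nk), grid.dims))
                if not taken[nb] and not in_frontier[nb]:
                    frontier.append(nb)
                    in_frontier[nb] = True
    if len(chosen) < size:
        return None
    return np.sort(np.asarray(chosen, dtype=np.intp))


def generate_ground_truth(
    grid: VoxelGrid,
    cluster_spec: dict,
    seed: int = 0,
    effect_size: dict | None = None,
    max_retries: int = 100,
) -> GroundTruth:
    """Place disjoint, face-connected informative voxel sets on the grid.

    Parameters
    ----------
    cluster_spec
        Mapping from set name ("shared", "auditory", "visual", "motor")
        to a list of ``(seed_coord, size)`` pairs; each pair becomes one
        face-connected component of exactly ``size`` voxels. Missing
        names get empty sets.
    effect_size
        Mean action minus non-action beta difference per set; defaults
        to 1.0 for every named set.

    Raises
    ------
    RuntimeError
        If a blob cannot be placed disjointly after ``max_retries``
        randomised growth attempts (grid too small / seeds too close).
    """
    unknown = set(cluster_spec) - set(GROUND_TRUTH_SETS)
    if unknown:
        raise ValueError(f"unknown ground-truth set names {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    occupied = np.zeros(grid.n_voxels, dtype=bool)
    sets: dict[str, np.ndarray] = {}
    for name in GROUND_TRUTH_SETS:
        pieces: list[np.ndarray] = []
        for seed_coord, size in cluster_spec.get(name, []):
            if size < 1:
                raise ValueError("cluster sizes must be >= 1")
            blob = None
            for _ in range(max_retries):
                blob = _grow_blob(grid, tuple(seed_coord), int(size), occupied, rng)
                if blob is not None:
                    break
            if blob is None:
                raise RuntimeError(
                    f"could not place a {size}-voxel cluster for set {name!r} at "
                    f"{tuple(seed_coord)}: grid too small or too crowded"
                )
            occupied[blob] = True
            pieces.append(blob)
        sets[name] = (
            np.sort(np.concatenate(pieces)) if pieces else np.empty(0, dtype=np.intp)
        )
    effects = dict.fromkeys(GROUND_TRUTH_SETS, 1.0)
    if effect_size:
        unknown = set(effect_size) - set(GROUND_TRUTH_SETS)
        if unknown:
            raise ValueError(f"unknown effect-size names {sorted(unknown)}")
        effects.update({k: float(v) for k, v in effect_size.items()})
    return GroundTruth(
        shared=sets["shared"],
        auditory=sets["auditory"],
        visual=sets["visual"],
        motor=sets["motor"],
        effect_size=effects,
        cluster_spec={k: list(v) for k, v in cluster_spec.items()},
    )


def default_cluster_spec(grid: VoxelGrid, sizes: dict | None = None) -> dict:
    """One well-separated cluster per set, sized for a desk-scale grid.

    Default sizes are 40 shared and 30 per modality-specific set; seeds
    sit in distinct octants of the grid so disjoint placement succeeds
    on a 12x12x12 grid or larger.
    """
    sizes = dict({"shared": 40, "auditory": 30, "visual": 30, "motor": 30}, **(sizes or {}))
    nx, ny, nz = grid.dims
    lo = lambda d: max(d // 4, 0)
    hi = lambda d: min(3 * d // 4, d - 1)
    seeds = {
        "shared": (lo(nx), lo(ny), lo(nz)),
        "auditory": (hi(nx), hi(ny), lo(nz)),
        "visual": (lo(nx), hi(ny), hi(nz)),
        "motor": (hi(nx), lo(ny), hi(nz)),
    }
    return {name: [(seeds[name], sizes[name])] for name in GROUND_TRUTH_SETS if sizes[name] > 0}


# ---------------------------------------------------------------------------
# Example generation
# ---------------------------------------------------------------------------


def _stimulus_table(design: DesignSpec) -> list[tuple[str, str, str]]:
    """(stimulus_id, class_label, modality) for every perception stimulus."""
    rows = []
    rows += [(f"aud_act_{i:02d}", "action", "auditory") for i in range(design.n_action_sounds)]
    rows += [(f"aud_non_{i:02d}", "non_action", "auditory") for i in range(design.n_nonaction_sounds)]
    rows += [(f"vis_act_{i:02d}", "action", "visual") for i in range(design.n_action_videos)]
    rows += [(f"vis_non_{i:02d}", "non_action", "visual") for i in range(design.n_nonaction_videos)]
    return rows


def generate_examples(gt: GroundTruth, design: DesignSpec, grid: VoxelGrid) -> ExampleSet:
    """Simulate one beta pattern per (subject, stimulus).

    Every subject hears every auditory stimulus; sighted subjects also
    see every visual stimulus; each subject additionally contributes
    ``n_pantomime_per_subject_per_session`` motor-pantomime examples per
    session type (auditory for everyone, visual for the sighted).

    An action example's pattern is ``effect * membership(S + modality
    set)``; a pantomime carries the action effect at S + M; non-action
    examples carry no effect. All examples add a per-subject scalar
    offset (same at every voxel) and i.i.d. Gaussian noise. Example
    counts are a deterministic function of the design; with a fixed seed
    the output is bit-reproducible.
    """
    rng = np.random.default_rng(design.seed)
    subjects = [(f"s{i + 1:02d}", "sighted") for i in range(design.n_sighted)]
    subjects += [(f"b{i + 1:02d}", "blind") for i in range(design.n_blind)]
    offsets = {sid: rng.normal(0.0, design.subject_offset_sd) for sid, _ in subjects}

    stimuli = _stimulus_table(design)
    signal = {}
    for modality in ("auditory", "visual", "motor"):
        vec = np.zeros(grid.n_voxels)
        vec[gt.shared] += gt.effect_size["shared"]
        mod_set = gt.set_for_modality(modality)
        vec[mod_set] += gt.effect_size[modality]
        signal[modality] = vec

    rows = []
    patterns = []

    def emit(subject_id, group, stimulus_id, class_label, modality, session):
        pattern = np.full(grid.n_voxels, offsets[subject_id])
        if class_label in ("action", "pantomime"):
            pattern = pattern + signal[modality]
        if design.noise_sd:
            pattern = pattern + rng.normal(0.0, design.noise_sd, grid.n_voxels)
        patterns.append(pattern)
        rows.append((class_label, modality, group, subject_id, stimulus_id, None, session))

    for subject_id, group in subjects:
        for stimulus_id, class_label, modality in stimuli:
            if modality == "visual" and group == "blind":
                continue
            emit(subject_id, group, stimulus_id, class_label, modality, session=modality)
        sessions = ["auditory"] if group == "blind" else ["auditory", "visual"]
        for session in sessions:
            for i in range(design.n_pantomime_per_subject_per_session):
                sid = f"pan_{session[:3]}_{subject_id}_{i:02d}"
                emit(subject_id, group, sid, "pantomime", "motor", session)

    X = np.array(patterns) if patterns else np.empty((0, grid.n_voxels))
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return ExampleSet(X, meta, grid, scaled=False)


# ---------------------------------------------------------------------------
# Sparse-sampling forward model and FIR deconvolution
# ---------------------------------------------------------------------------

#: Shape parameter of the gamma-variate impulse response. With unit
#: scale the mode sits at (shape - 1) = 3, i.e. the response peaks at
#: the third of the five volumes acquired per trial, which is what makes
#: averaging volumes 2-4 a sensible amplitude estimate.
GAMMA_SHAPE = 4.0
N_VOLUMES_PER_TRIAL = 5
#: 1-based volume numbers averaged into the per-stimulus beta.
BETA_VOLUMES = (2, 3, 4)


def gamma_kernel(n_volumes: int = N_VOLUMES_PER_TRIAL) -> np.ndarray:
    """Unit gamma-variate response sampled at volumes 1..n (peak = 1)."""
    t = np.arange(1, n_volumes + 1, dtype=float)
    pdf = sps.gamma.pdf(t, GAMMA_SHAPE)
    return pdf / sps.gamma.pdf(GAMMA_SHAPE - 1.0, GAMMA_SHAPE)


def simulate_sparse_run(
    amplitudes: np.ndarray,
    n_volumes_per_trial: int = N_VOLUMES_PER_TRIAL,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-trial volume series under a sparse-sampling acquisition.

    Each trial contributes ``amplitude * gamma_kernel`` sampled at its
    ``n_volumes_per_trial`` acquisition times, plus Gaussian noise.
    Returns an (n_trials, n_volumes_per_trial) array.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(amplitudes)):
        raise ValueError("amplitudes must be finite")
    kernel = gamma_kernel(n_volumes_per_trial)
    series = amplitudes[:, None] * kernel[None, :]
    if noise_sd:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, series.shape)
    return series


def fir_design(n_trials: int, n_volumes_per_trial: int = N_VOLUMES_PER_TRIAL) -> np.ndarray:
    """FIR design matrix for concatenated non-overlapping trials.

    One indicator regressor per (trial, volume position); rows are the
    concatenated volumes of all trials. With non-overlapping trials this
    is an identity matrix, under which deconvolution recovers each
    trial's response shape exactly.
    """
    return np.eye(n_trials * n_volumes_per_trial)


def deconvolve_betas(
    volume_series: np.ndarray,
    design: np.ndarray,
    n_volumes_per_trial: int = N_VOLUMES_PER_TRIAL,
    beta_volumes: tuple[int, ...] = BETA_VOLUMES,
) -> np.ndarray:
    """Per-stimulus beta by FIR least squares, averaging middle volumes.

    ``volume_series`` is the concatenated time series (n_timepoints,) or
    (n_timepoints, n_voxels); ``design`` is an (n_timepoints, n_stimuli
    * n_volumes_per_trial) matrix whose columns are grouped per stimulus
    in volume order. The fitted per-volume beta-weights are averaged
    over ``beta_volumes`` (1-based volume numbers, default the second,
    third and fourth) to give one beta per stimulus.
    """
    y = np.asarray(volume_series, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.shape[1] % n_volumes_per_trial:
        raise ValueError("design columns must be a multiple of n_volumes_per_trial")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    n_stimuli = X.shape[1] // n_volumes_per_trial
    beta = beta.reshape(n_stimuli, n_volumes_per_trial, -1)
    vol_idx = np.asarray(beta_volumes, dtype=int) - 1  # 1-based volume numbering
    if vol_idx.min() < 0 or vol_idx.max() >= n_volumes_per_trial:
        raise ValueError("beta_volumes out of range")
    out = beta[:, vol_idx, :].mean(axis=1)
    return out[:, 0] if np.asarray(volume_series).ndim == 1 else out
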