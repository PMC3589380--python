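"""Dataset and result interchange: NIfTI volumes, TSV tables, JSON reports.

A dataset on disk is a directory of one NIfTI volume per example plus a
``metadata.tsv`` table (columns: file, class, modality, group, subject,
stimulus, duplicate_of, session). Ground-truth informative sets export
as one integer-labeled NIfTI mask; discriminative maps as paired
weight / z-score volumes; RFE traces as TSV; the experiment report as
JSON carrying the package version, seed and config hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .grid import VoxelGrid
from .rfe import DiscriminativeMap, RFETrace
from .synthetic import META_COLUMNS, ExampleSet, GroundTruth, GROUND_TRUTH_SETS

METADATA_FILE = "metadata.tsv"
METADATA_HEADER = ["file", "class", "modality", "group", "subject", "stimulus", "duplicate_of", "session"]


def _affine(grid: VoxelGrid) -> np.ndarray:
    return np.diag(list(grid.voxel_size_mm) + [1.0])


def write_dataset(exset: ExampleSet, outdir) -> Path:
    """One float32 NIfTI volume per example plus a metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = _affine(exset.grid)
    rows = []
    for i in range(exset.n_examples):
        fname = f"example_{i:05d}.nii"
        vol = exset.X[i].reshape(exset.grid.dims).astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine), outdir / fname)
        m = exset.meta.iloc[i]
        rows.append(
            [fname, m["class_label"], m["modality"], m["group"], m["subject_id"],
             m["stimulus_id"], m["duplicate_of"] if pd.notna(m["duplicate_of"]) else "", m["session"]]
        )
    pd.DataFrame(rows, columns=METADATA_HEADER).to_csv(outdir / METADATA_FILE, sep="\t", index=False)
    return outdir


def read_dataset(path) -> ExampleSet:
    """Load a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    meta_path = path / METADATA_FILE
    if not meta_path.exists():
        raise FileNotFoundError(f"no examples: {meta_path} is missing")
    table = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_HEADER if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metadata table is missing columns {missing_cols}")
    if len(table) == 0:
        raise ValueError(f"no examples listed in {meta_path}")

    volumes = []
    dims = None
    voxel_size = None
    for fname in table["file"]:
        fpath = path / fname
        if not fpath.exists():
            raise FileNotFoundError(f"volume {fpath} listed in metadata is missing")
        img = nib.load(fpath)
        data = np.asarray(img.dataobj, dtype=float)
        if dims is None:
            dims = data.shape
            voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        elif data.shape != dims:
            raise ValueError(f"volume {fname} has shape {data.shape}, expected {dims}")
        volumes.append(data.ravel())
    grid = VoxelGrid(dims, voxel_size)
    meta = pd.DataFrame(
        {
            "class_label": table["class"],
            "modality": table["modality"],
            "group": table["group"],
            "subject_id": table["subject"],
            "stimulus_id": table["stimulus"],
            "duplicate_of": table["duplicate_of"].replace("", None),
            "session": table["session"],
        }
    )
    return ExampleSet(np.vstack(volumes), meta, grid, scaled=False)


def write_ground_truth_mask(gt: GroundTruth, grid: VoxelGrid, path) -> Path:
    """Integer-labeled NIfTI mask: 1 shared, 2 auditory, 3 visual, 4 motor."""
    vol = np.zeros(grid.n_voxels, dtype=np.int16)
    for code, name in enumerate(GROUND_TRUTH_SETS, start=1):
        vol[gt.sets()[name]] = code
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.reshape(grid.dims), _affine(grid)), path)
    return path


def write_map(dmap: DiscriminativeMap, grid: VoxelGrid, prefix) -> tuple[Path, Path]:
    """Weight and z-score volumes of a discriminative map."""
    w_vol, z_vol = dmap.to_volumes(grid)
    prefix = Path(prefix)
    w_path = prefix.with_name(prefix.name + "_weights.nii")
    z_path = prefix.with_name(prefix.name + "_zweights.nii")
    nib.save(nib.Nifti1Image(w_vol.astype(np.float32), _affine(grid)), w_path)
    nib.save(nib.Nifti1Image(z_vol.astype(np.float32), _affine(grid)), z_path)
    return w_path, z_path


def read_map_voxels(weights_path) -> np.ndarray:
    """Voxel membership (linear indices of nonzero weights) of a saved map."""
    img = nib.load(weights_path)
    return np.flatnonzero(np.asarray(img.dataobj, dtype=float).ravel())


def write_trace(trace: RFETrace, path) -> Path:
    """TSV of (iteration, n_features, accuracy)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "iteration": np.arange(1, trace.n_iterations + 1),
            "n_features": trace.feature_counts,
            "accuracy": trace.accuracies,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def write_report(report: dict, config: ExperimentConfig, outdir) -> Path:
    """JSON report (plus TSV renderings of the accuracy tables).

    The report embeds the package version, the run seed and a hash of
    the configuration so any result file can be traced to its exact
    inputs. Serialization is deterministic: two runs from the same
    (config, seed) produce byte-identical JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    full = {
        "pipeline_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        **report,
    }
    out = outdir / "report.json"
    out.write_text(json.dumps(full, indent=2, sort_keys=True, allow_nan=True, default=_jsonable))
    for key in ("whole_map_table", "restricted_table", "pantomime"):
        if key in report:
            pd.DataFrame(report[key]).to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
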