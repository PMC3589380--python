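"""3D voxel grids and cluster-size correction of voxel sets.

Voxel patterns live on a regular 3D grid; a voxel is addressed either by
its (i, j, k) coordinate or by its linear index in C (row-major) order.
Cluster correction removes connected components smaller than a minimum
size from a voxel set, the standard step used to discard small isolated
clusters from discriminative maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: Connectivity names mapped to scipy's binary-structure rank.
#: "faces" is nearest-neighbour (6-connectivity), "faces+edges" 18, and
#: "faces+edges+corners" full 26-connectivity.
CONNECTIVITY_RANKS = {"faces": 1, "faces+edges": 2, "faces+edges+corners": 3}


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D sampling grid of isometric (or anisometric) voxels.

    Parameters
    ----------
    dims
        Grid shape ``(nx, ny, nz)``; every entry must be >= 1.
    voxel_size_mm
        Physical edge lengths of one voxel in millimetres. Defaults to
        the isometric 2 mm convention used for group-space beta maps.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive reals")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def ravel(self, coords: np.ndarray) -> np.ndarray:
        """Map (n, 3) integer coordinates to linear voxel indices."""
        coords = np.atleast_2d(np.asarray(coords, dtype=np.intp))
        return np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), self.dims)

    def unravel(self, indices: np.ndarray) -> np.ndarray:
        """Map linear voxel indices to (n, 3) integer coordinates."""
        indices = np.atleast_1d(np.asarray(indices, dtype=np.intp))
        return np.stack(np.unravel_index(indices, self.dims), axis=1)

    def mask_from_indices(self, indices: np.ndarray) -> np.ndarray:
        """Boolean 3D volume with True at the given linear indices."""
        mask = np.zeros(self.n_voxels, dtype=bool)
        mask[np.asarray(indices, dtype=np.intp)] = True
        return mask.reshape(self.dims)

    def volume_from_values(self, indices: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Dense float 3D volume with ``values`` at ``indices``, 0 elsewhere."""
        vol = np.zeros(self.n_voxels, dtype=float)
        vol[np.asarray(indices, dtype=np.intp)] = np.asarray(values, dtype=float)
        return vol.reshape(self.dims)


def _structure(connectivity: str) -> np.ndarray:
    try:
        rank = CONNECTIVITY_RANKS[connectivity]
    except KeyError:
        raise ValueError(
            f"unknown connectivity {connectivity!r}; expected one of {sorted(CONNECTIVITY_RANKS)}"
        ) from None
    return ndimage.generate_binary_structure(3, rank)


def connected_components(
    voxel_set: np.ndarray, grid: VoxelGrid, connectivity: str = "faces"
) -> list[np.ndarray]:
    """Split a voxel-index set into its connected components.

    Returns a list of sorted linear-index arrays, one per component,
    ordered by first (lowest) voxel index.
    """
    voxel_set = np.asarray(voxel_set, dtype=np.intp)
    if voxel_set.size == 0:
        return []
    if voxel_set.min() < 0 or voxel_set.max() >= grid.n_voxels:
        raise ValueError("voxel indices out of grid bounds")
    mask = grid.mask_from_indices(voxel_set)
    labels, n_labels = ndimage.label(mask, structure=_structure(connectivity))
    flat = labels.ravel()
    comps = [np.flatnonzero(flat == lab) for lab in range(1, n_labels + 1)]
    comps.sort(key=lambda c: int(c[0]))
    return comps


def cluster_correct(
    voxel_set: np.ndarray,
    grid: VoxelGrid,
    connectivity: str = "faces",
    min_size: int = 150,
) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` voxels.

    The output is the sorted union of all surviving components; it is
    always a subset of the input, and an empty input yields an empty
    output.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    comps = connected_components(voxel_set, grid, connectivity)
    keep = [c for c in comps if c.size >= min_size]
    if not keep:
        return np.empty(0, dtype=np.intp)
    return np.sort(np.concatenate(keep))
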