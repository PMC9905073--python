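"""Trimming-box voxelization of local atom-distribution patterns.

The neighbourhood of a 3D point is converted into a 4-channel binary
occupancy grid (one channel per element class C/N/O/S).  Two standard box
specifications are used: a fine box of 41^3 voxels at 0.25 A (a 10.25 A
cube) and a coarse box of 21^3 voxels at 0.50 A (a 10.5 A cube).

Voxelization is binary presence at the atom-centre voxel in the global
frame (no rotational canonicalization, no partial-volume painting); two
atoms falling in one voxel still yield the value 1 (saturation).  Voxel
intervals are half-open: an atom exactly on the max-edge boundary of the
box is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .structure import ELEMENT_CLASSES, ProteinStructure

#: Grid channel order.
CHANNELS = ELEMENT_CLASSES

LABEL_PRESENT = "water_present"
LABEL_ABSENT = "water_absent"
LABEL_UNLABELED = "unlabeled"
_LABELS = (LABEL_PRESENT, LABEL_ABSENT, LABEL_UNLABELED)


@dataclass(frozen=True)
class BoxSpec:
    """Cubic trimming-box geometry: odd voxel count and voxel size (A)."""

    n_voxels_per_edge: int = 41
    voxel_size: float = 0.25

    def __post_init__(self) -> None:
        if self.n_voxels_per_edge < 3 or self.n_voxels_per_edge % 2 == 0:
            raise ValueError("n_voxels_per_edge must be odd and >= 3")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def edge(self) -> float:
        """Physical edge length (A) = n_voxels_per_edge * voxel_size."""
        return self.n_voxels_per_edge * self.voxel_size


#: Fine box: 41^3 voxels of 0.25 A (10.25 A cube).
FINE_BOX = BoxSpec(41, 0.25)
#: Coarse box: 21^3 voxels of 0.50 A (10.5 A cube).
COARSE_BOX = BoxSpec(21, 0.50)


@dataclass
class Pattern:
    """A voxelized atom-distribution pattern around a centre point."""

    grid: np.ndarray
    center: np.ndarray
    label: str = LABEL_UNLABELED
    source_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.center = np.asarray(self.center, dtype=float)
        if self.grid.ndim != 4 or self.grid.shape[0] != len(CHANNELS):
            raise ValueError(f"grid must have shape (4, n, n, n), got {self.grid.shape}")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("grid values must be binary")
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("center must be 3 finite coordinates")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}")


def voxelize_grids(
    structure: ProteinStructure,
    centers: np.ndarray,
    box: BoxSpec,
    dtype=np.uint8,
    channels_last: bool = False,
) -> np.ndarray:
    """Voxelize many centres at once; returns (n_centers, 4, n, n, n).

    Only protein heavy atoms populate the grid; waters never do.  Index
    convention: ``index = floor((coord - corner) / voxel_size)`` with the
    box corner at ``center - edge/2``, so the centre point falls at the
    centre of the middle voxel.  ``channels_last=True`` emits
    (n_centers, n, n, n, 4) instead (internal fast path for inference).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = box.n_voxels_per_edge
    shape = (len(centers), n, n, n, len(CHANNELS)) if channels_last else \
            (len(centers), len(CHANNELS), n, n, n)
    out = np.zeros(shape, dtype=dtype)
    coords = structure.protein_coords
    if coords.shape[0] == 0 or len(centers) == 0:
        return out
    channels = structure.element_channels
    half_edge = box.edge / 2.0
    tree = cKDTree(coords)
    # Atoms possibly in the box lie within the half-diagonal of the cube.
    hits = tree.query_ball_point(centers, half_edge * np.sqrt(3.0) + 1e-9)
    for c, atom_idx in enumerate(hits):
        if not atom_idx:
            continue
        ai = np.asarray(atom_idx, dtype=np.intp)
        rel = coords[ai] - (centers[c] - half_edge)
        idx = np.floor(rel / box.voxel_size).astype(np.intp)
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        if ok.any():
            ii = idx[ok]
            ch = channels[ai[ok]]
            if channels_last:
                out[c, ii[:, 0], ii[:, 1], ii[:, 2], ch] = 1
            else:
                out[c, ch, ii[:, 0], ii[:, 1], ii[:, 2]] = 1
    return out


def voxelize_sparse_batch(structure: ProteinStructure, centers: np.ndarray,
                          box: BoxSpec):
    """Internal scanning fast path: nonzero voxel indices per centre.

    Returns ``(batch, ix, iy, iz, channel)`` index arrays equivalent to
    ``np.nonzero`` of the channels-last dense grids.  Duplicate atom hits
    in one voxel are collapsed (binary saturation).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = box.n_voxels_per_edge
    coords = structure.protein_coords
    empty = tuple(np.empty(0, dtype=np.intp) for _ in range(5))
    if coords.shape[0] == 0 or len(centers) == 0:
        return empty
    channels = structure.element_channels
    half_edge = box.edge / 2.0
    tree = cKDTree(coords)
    hits = tree.query_ball_point(centers, half_edge * np.sqrt(3.0) + 1e-9)
    rows = []
    for c, atom_idx in enumerate(hits):
        if not atom_idx:
            continue
        ai = np.asarray(atom_idx, dtype=np.intp)
        rel = coords[ai] - (centers[c] - half_edge)
        idx = np.floor(rel / box.voxel_size).astype(np.intp)
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        if ok.any():
            ii = idx[ok]
            ch = channels[ai[ok]]
            rec = np.column_stack([np.full(len(ii), c, dtype=np.intp),
                                   ii, ch])
            rows.append(np.unique(rec, axis=0))
    if not rows:
        return empty
    all_rows = np.concatenate(rows)
    return tuple(all_rows[:, d] for d in range(5))


def voxelize(structure: ProteinStructure, center, box: BoxSpec = FINE_BOX,
             label: str = LABEL_UNLABELED) -> Pattern:
    """Voxelize the neighbourhood of a single centre point."""
    center = np.asarray(center, dtype=float)
    grid = voxelize_grids(structure, center[None, :], box)[0]
    return Pattern(grid=grid, center=center, label=label, source_id=structure.id)


def batch_voxelize(structure: ProteinStructure, centers, box: BoxSpec = FINE_BOX,
                   label: str = LABEL_UNLABELED) -> list[Pattern]:
    """Voxelize a list of centres; elementwise identical to :func:`voxelize`."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float)) if len(centers) else np.empty((0, 3))
    grids = voxelize_grids(structure, centers, box)
    return [
        Pattern(grid=g, center=c, label=label, source_id=structure.id)
        for g, c in zip(grids, centers)
    ]


class Voxelizer(TransformerMixin, BaseEstimator):
    """Transformer mapping centre points to voxel grids for one structure.

    Composes with the CNN classifier in an sklearn pipeline::

        Pipeline([("voxelize", Voxelizer(structure, box)),
                  ("cnn", HydrationCNN(...))])

    ``transform`` takes an (n, 3) array of centre coordinates and returns
    float32 grids of shape (n, 4, n_voxels, n_voxels, n_voxels).
    """

    def __init__(self, structure: ProteinStructure | None = None, box: BoxSpec = FINE_BOX):
        self.structure = structure
        self.box = box

    def fit(self, X=None, y=None):
        if self.structure is None:
            raise ValueError("Voxelizer requires a structure")
        self.n_features_out_ = len(CHANNELS) * self.box.n_voxels_per_edge ** 3
        return self

    def transform(self, X) -> np.ndarray:
        if self.structure is None:
            raise ValueError("Voxelizer requires a structure")
        return voxelize_grids(self.structure, np.asarray(X, dtype=float), self.box,
                              dtype=np.float32)
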