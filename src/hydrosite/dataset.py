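"""Balanced water-present/water-absent pattern datasets and splits.

One water-present pattern is produced per crystal-water site (box centred
on the water oxygen), and an equal number of water-absent patterns is
drawn per structure from the hydration zone: lattice points within
``max_dist_protein`` of a solvent-reachable (non-zero ASA) atom, at least
``min_dist_protein`` from every protein heavy atom, and at least
``min_dist_water`` from every crystal-water oxygen.  70/30 train/validation
splitting is per-pattern, independent of the source structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinStructure
from .voxel import (
    LABEL_ABSENT,
    LABEL_PRESENT,
    BoxSpec,
    Pattern,
    voxelize_grids,
)

#: Negative-sampling exclusion radii (Angstrom).  2.4 A from waters is
#: about the closest water-water contact; 2.0 A keeps centres off protein
#: atoms; the 4.0 A outer shell mirrors the prediction zone.
DEFAULT_MIN_DIST_WATER = 2.4
DEFAULT_MIN_DIST_PROTEIN = 2.0
DEFAULT_MAX_DIST_PROTEIN = 4.0
#: Absent centres are drawn from a lattice of fine-voxel spacing so that
#: rebuilding a dataset is reproducible bit-exactly.
DEFAULT_LATTICE_SPACING = 0.25


class InsufficientCandidatesError(RuntimeError):
    """Candidate lattice too small for the requested absent-sample count."""

    def __init__(self, requested: int, available: int):
        super().__init__(
            f"requested {requested} water-absent centres but only "
            f"{available} candidate lattice points satisfy the distance rules"
        )
        self.requested = requested
        self.available = available


@dataclass
class PatternDataset:
    """Labeled patterns with present/absent bookkeeping counts."""

    patterns: list[Pattern]
    n_present: int
    n_absent: int
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = [p.label for p in self.patterns]
        if labels.count(LABEL_PRESENT) != self.n_present or \
           labels.count(LABEL_ABSENT) != self.n_absent:
            raise ValueError("counts do not match pattern labels")
        if self.n_present + self.n_absent != len(self.patterns):
            raise ValueError("every pattern must be labeled present or absent")

    def __len__(self) -> int:
        return len(self.patterns)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Grids as float32 (n, 4, e, e, e) and binary labels (1 = present)."""
        X = np.stack([p.grid for p in self.patterns]).astype(np.float32)
        y = np.array([1 if p.label == LABEL_PRESENT else 0 for p in self.patterns],
                     dtype=np.uint8)
        return X, y


@dataclass
class SplitDataset:
    """Disjoint train/validation partition of a pattern dataset."""

    train: PatternDataset
    validation: PatternDataset
    fraction: float


def balanced_counts(water_counts) -> tuple[int, int, int]:
    """Present/absent/total pattern counts implied by the balance rule.

    One present pattern per crystal-water site and, per structure, an
    equal number of absent patterns, so the totals are (W, W, 2W) for W
    waters.  ``water_counts`` is the per-structure water count manifest.
    """
    counts = [int(c) for c in water_counts]
    if any(c < 0 for c in counts):
        raise ValueError("water counts must be non-negative")
    n_present = sum(counts)
    n_absent = sum(counts)  # per-structure balancing: absent_i = present_i
    return n_present, n_absent, n_present + n_absent


def sample_present(structure: ProteinStructure, box: BoxSpec) -> list[Pattern]:
    """One water-present pattern per crystal-water site.

    The box is centred on the water oxygen; the centred water and all
    other waters are excluded from the grid (only protein atoms are
    voxelized).
    """
    if structure.asa is None:
        raise ValueError("structure needs ASA; call compute_asa first")
    centers = structure.water_coords
    if len(centers) == 0:
        return []
    grids = voxelize_grids(structure, centers, box)
    return [
        Pattern(grid=g, center=c, label=LABEL_PRESENT, source_id=structure.id)
        for g, c in zip(grids, centers)
    ]


def absent_candidate_lattice(
    structure: ProteinStructure,
    min_dist_water: float = DEFAULT_MIN_DIST_WATER,
    min_dist_protein: float = DEFAULT_MIN_DIST_PROTEIN,
    max_dist_protein: float = DEFAULT_MAX_DIST_PROTEIN,
    lattice_spacing: float = DEFAULT_LATTICE_SPACING,
) -> np.ndarray:
    """All lattice points in the hydration zone that pass the distance rules.

    The lattice has ``lattice_spacing`` pitch and is anchored at integer
    multiples of the spacing in the global frame, so candidate centres are
    reproducible grid points.
    """
    if structure.asa is None:
        raise ValueError("structure needs ASA; call compute_asa first")
    surf = structure.nonzero_asa_coords()
    if len(surf) == 0:
        return np.empty((0, 3))
    lo = np.floor((surf.min(axis=0) - max_dist_protein) / lattice_spacing).astype(int)
    hi = np.ceil((surf.max(axis=0) + max_dist_protein) / lattice_spacing).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) * lattice_spacing for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    d_surf, _ = cKDTree(surf).query(pts, workers=1)
    keep = d_surf <= max_dist_protein
    pts = pts[keep]
    d_prot, _ = cKDTree(structure.protein_coords).query(pts, workers=1)
    pts = pts[d_prot >= min_dist_protein]
    if len(structure.water_sites) and len(pts):
        d_wat, _ = cKDTree(structure.water_coords).query(pts, workers=1)
        pts = pts[d_wat >= min_dist_water]
    return pts


def sample_absent(
    structure: ProteinStructure,
    box: BoxSpec,
    n: int,
    min_dist_water: float = DEFAULT_MIN_DIST_WATER,
    min_dist_protein: float = DEFAULT_MIN_DIST_PROTEIN,
    max_dist_protein: float = DEFAULT_MAX_DIST_PROTEIN,
    seed: int | None = 0,
    lattice_spacing: float = DEFAULT_LATTICE_SPACING,
) -> list[Pattern]:
    """Draw ``n`` seeded water-absent patterns from the candidate lattice."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    cand = absent_candidate_lattice(
        structure, min_dist_water, min_dist_protein, max_dist_protein, lattice_spacing
    )
    if len(cand) < n:
        raise InsufficientCandidatesError(n, len(cand))
    rng = np.random.default_rng(seed)
    centers = cand[rng.choice(len(cand), size=n, replace=False)]
    grids = voxelize_grids(structure, centers, box)
    return [
        Pattern(grid=g, center=c, label=LABEL_ABSENT, source_id=structure.id)
        for g, c in zip(grids, centers)
    ]


def build_dataset(
    structures: list[ProteinStructure],
    box: BoxSpec,
    seed: int | None = 0,
    **absent_kwargs,
) -> PatternDataset:
    """Balanced dataset over a corpus: per structure, one present pattern
    per water plus an equal number of absent patterns."""
    if not structures:
        raise ValueError("need at least one structure")
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=len(structures))
    patterns: list[Pattern] = []
    n_present = n_absent = 0
    for st, s in zip(structures, seeds):
        present = sample_present(st, box)
        absent = sample_absent(st, box, n=len(present), seed=int(s), **absent_kwargs)
        patterns.extend(present)
        patterns.extend(absent)
        n_present += len(present)
        n_absent += len(absent)
    return PatternDataset(patterns=patterns, n_present=n_present,
                          n_absent=n_absent, seed=seed)


def split_dataset(dataset: PatternDataset, fraction: float = 0.7,
                  seed: int | None = 0) -> SplitDataset:
    """Seeded uniform per-pattern partition; |train| = floor(fraction * n)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fraction * n))
    parts = []
    for idx in (order[:n_train], order[n_train:]):
        pats = [dataset.patterns[i] for i in sorted(idx)]
        labels = [p.label for p in pats]
        parts.append(PatternDataset(
            patterns=pats,
            n_present=labels.count(LABEL_PRESENT),
            n_absent=labels.count(LABEL_ABSENT),
            seed=dataset.seed,
        ))
    return SplitDataset(train=parts[0], validation=parts[1], fraction=fraction)


def save_dataset(dataset: PatternDataset, path, box: BoxSpec | None = None) -> None:
    """Serialize to HDF5 (datasets: grids, labels, centers, source_ids).

    Written without timestamps so the same dataset is byte-identical on
    disk across rebuilds.
    """
    X, y = (np.empty((0, 4, 0, 0, 0), np.uint8), np.empty(0, np.uint8)) \
        if not dataset.patterns else (
            np.stack([p.grid for p in dataset.patterns]).astype(np.uint8),
            np.array([1 if p.label == LABEL_PRESENT else 0 for p in dataset.patterns],
                     dtype=np.uint8),
        )
    centers = np.array([p.center for p in dataset.patterns], dtype=np.float64) \
        if dataset.patterns else np.empty((0, 3))
    ids = [p.source_id for p in dataset.patterns]
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("grids", data=X, track_times=False)
        f.create_dataset("labels", data=y, track_times=False)
        f.create_dataset("centers", data=centers, track_times=False)
        f.create_dataset("source_ids", data=ids, track_times=False,
                         dtype=h5py.string_dtype())
        f.attrs["seed"] = -1 if dataset.seed is None else dataset.seed
        if box is not None:
            f.attrs["n_voxels_per_edge"] = box.n_voxels_per_edge
            f.attrs["voxel_size"] = box.voxel_size


def load_dataset(path) -> PatternDataset:
    """Inverse of :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        X = f["grids"][...]
        y = f["labels"][...]
        centers = f["centers"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["source_ids"][...]]
        seed = int(f.attrs["seed"])
    patterns = [
        Pattern(grid=g, center=c,
                label=LABEL_PRESENT if lab else LABEL_ABSENT, source_id=sid)
        for g, c, lab, sid in zip(X, centers, y, ids)
    ]
    return PatternDataset(
        patterns=patterns,
        n_present=int(np.sum(y == 1)),
        n_absent=int(np.sum(y == 0)),
        seed=None if seed == -1 else seed,
    )
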