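"""Coarse-to-fine scanning of a structure into a hydration-probability map.

The first stage evaluates the coarse classifier on a coarse-pitch lattice
restricted to points within 4 A of any solvent-reachable (non-zero ASA)
protein atom; lattice points whose coarse probability reaches
``coarse_threshold`` become candidates.  The second stage evaluates the
fine classifier at every fine voxel within ``refine_radius`` of a
candidate and writes the probabilities into a 3D map (MRC2014, mode 2).
Predicted hydration sites are the thresholded local maxima of the map
after non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import ProteinStructure
from .voxel import voxelize_grids, voxelize_sparse_batch

#: Candidate threshold on the coarse probability; mirrors the 10 % display
#: contour that envelopes first-layer hydration.
DEFAULT_COARSE_THRESHOLD = 0.1
#: Fine evaluation radius (A) around each coarse candidate.
DEFAULT_REFINE_RADIUS = 1.0
#: Probability threshold for calling a local maximum a hydration site.
DEFAULT_SITE_THRESHOLD = 0.8
#: Peak-separation radius (A): above the three-fine-voxel (0.75 A)
#: discretization scale so duplicate grid peaks collapse, but safely
#: below half the closest water-water contact (2.4 A / 2 = 1.2 A) so the
#: maxima of two adjacent hydration sites are never merged.
DEFAULT_NMS_RADIUS = 0.8
#: Prediction zone: distance (A) from non-zero-ASA atoms that is scanned.
SCAN_DISTANCE = 4.0

_ORIGIN_WORDS = (50, 51, 52)  # MRC2014 ORIGIN x/y/z header words


class MRCFormatError(ValueError):
    """Raised when a map file cannot be read as MRC."""


@dataclass
class HydrationSite:
    """A predicted hydration site: position (A) and map probability."""

    position: np.ndarray
    probability: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class ProbabilityMap:
    """Hydration-probability grid with physical placement metadata.

    ``origin`` is the Cartesian position of the corner of voxel (0,0,0);
    the centre of voxel ``(i,j,k)`` is ``origin + (ijk + 0.5) * voxel_size``.
    ``evaluated_mask`` flags voxels where the classifier was actually run;
    values outside the mask are exactly zero.
    """

    values: np.ndarray
    origin: np.ndarray
    voxel_size: float
    evaluated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3D array")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("map values must lie in [0, 1]")
        if self.evaluated_mask is None:
            self.evaluated_mask = self.values != 0
        self.evaluated_mask = np.asarray(self.evaluated_mask, dtype=bool)
        if self.evaluated_mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if np.any(self.values[~self.evaluated_mask] != 0):
            raise ValueError("values outside the evaluated mask must be 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size


@dataclass
class CoarseScan:
    """Candidate points from the first scanning stage."""

    points: np.ndarray
    probabilities: np.ndarray
    n_evaluated: int


def _snapped_origin(structure: ProteinStructure, voxel_size: float,
                    padding: float = SCAN_DISTANCE) -> tuple[np.ndarray, np.ndarray]:
    """Map corner and voxel counts: bounding box + padding, corner snapped
    to a multiple of the voxel size for reproducibility."""
    coords = structure.protein_coords
    lo = np.floor((coords.min(axis=0) - padding) / voxel_size) * voxel_size
    hi = coords.max(axis=0) + padding
    n = np.ceil((hi - lo) / voxel_size).astype(int)
    return lo, n


def scan_lattice_points(structure: ProteinStructure, spacing: float,
                        scan_distance: float = SCAN_DISTANCE) -> np.ndarray:
    """Lattice points (pitch = ``spacing``) within ``scan_distance`` of any
    non-zero-ASA protein atom."""
    surf = structure.nonzero_asa_coords()
    if len(surf) == 0:
        raise ValueError("structure has no atoms with non-zero ASA")
    lo, n = _snapped_origin(structure, spacing, padding=scan_distance)
    axes = [lo[d] + (np.arange(n[d]) + 0.5) * spacing for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = cKDTree(surf).query(pts, workers=1)
    return pts[d <= scan_distance]


def scan_coarse(structure: ProteinStructure, coarse_model,
                coarse_threshold: float = DEFAULT_COARSE_THRESHOLD,
                batch_size: int = 512) -> CoarseScan:
    """First stage: evaluate the coarse classifier over the scan lattice."""
    if getattr(coarse_model, "resolution_tag", None) not in (None, "coarse"):
        raise ValueError("coarse_model must carry resolution_tag 'coarse'")
    box = coarse_model.box
    pts = scan_lattice_points(structure, box.voxel_size)
    probs = _predict_points(structure, coarse_model, pts, batch_size)
    keep = probs >= coarse_threshold
    return CoarseScan(points=pts[keep], probabilities=probs[keep],
                      n_evaluated=len(pts))


def _predict_points(structure, model, points: np.ndarray, batch_size: int) -> np.ndarray:
    fast = getattr(model, "_predict_sparse", None)
    out = np.empty(len(points))
    for s in range(0, len(points), batch_size):
        batch = points[s:s + batch_size]
        if fast is not None and hasattr(model, "layers_"):
            nz = voxelize_sparse_batch(structure, batch, model.box)
            out[s:s + batch_size] = fast(nz, len(batch))
        else:
            grids = voxelize_grids(structure, batch, model.box, dtype=np.float32)
            out[s:s + batch_size] = model.predict_water_probability(grids)
    return out


def predict_map(structure: ProteinStructure, fine_model, candidates,
                refine_radius: float = DEFAULT_REFINE_RADIUS,
                batch_size: int = 256) -> ProbabilityMap:
    """Second stage: fine probabilities on voxels near candidate points.

    Overlapping candidate neighbourhoods are merged by union; the map is
    zero (and unmasked) everywhere the classifier was not evaluated.
    """
    if getattr(fine_model, "resolution_tag", None) not in (None, "fine"):
        raise ValueError("fine_model must carry resolution_tag 'fine'")
    pts = candidates.points if isinstance(candidates, CoarseScan) else np.asarray(candidates)
    if len(pts) == 0:
        raise ValueError("no candidate points to refine")
    vs = fine_model.box.voxel_size
    origin, n = _snapped_origin(structure, vs)
    values = np.zeros(tuple(n), dtype=np.float32)
    mask = np.zeros(tuple(n), dtype=bool)

    tree = cKDTree(pts)
    # voxels whose centre lies within refine_radius of any candidate
    lo_idx = np.floor((pts.min(axis=0) - refine_radius - origin) / vs - 0.5).astype(int)
    hi_idx = np.ceil((pts.max(axis=0) + refine_radius - origin) / vs).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, n - 1)
    axes = [np.arange(lo_idx[d], hi_idx[d] + 1) for d in range(3)]
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = origin + (idx + 0.5) * vs
    d, _ = tree.query(centers, distance_upper_bound=refine_radius, workers=1)
    sel = np.isfinite(d)
    idx, centers = idx[sel], centers[sel]
    probs = _predict_points(structure, fine_model, centers, batch_size)
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = np.clip(probs, 0.0, 1.0)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    values[~mask] = 0.0
    return ProbabilityMap(values=values, origin=origin, voxel_size=vs,
                          evaluated_mask=mask)


def extract_sites(pmap: ProbabilityMap, threshold: float = DEFAULT_SITE_THRESHOLD,
                  nms_radius: float = DEFAULT_NMS_RADIUS) -> list[HydrationSite]:
    """Thresholded local maxima of the map, after non-maximum suppression.

    A voxel is a peak when its value reaches ``threshold``, its whole
    26-neighbourhood was evaluated (voxels on the border of the
    evaluated region compare against unevaluated zeros and would be
    spurious maxima), and it is no smaller than all 26 neighbours;
    within a plateau or within ``nms_radius`` of a higher peak, the
    lexicographically smallest voxel index wins.  Sites are sorted by
    descending probability.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    v = pmap.values
    if v.size == 0:
        return []
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(v, footprint=footprint,
                                          mode="constant", cval=0.0)
    interior = ndimage.binary_erosion(pmap.evaluated_mask,
                                      structure=np.ones((3, 3, 3), dtype=bool),
                                      border_value=0)
    peak = (v >= neighbor_max) & (v >= threshold) & interior
    idx = np.argwhere(peak)
    if len(idx) == 0:
        return []
    probs = v[idx[:, 0], idx[:, 1], idx[:, 2]]
    # descending probability, then lexicographic voxel index
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -probs))
    idx, probs = idx[order], probs[order]
    pos = pmap.voxel_centers(idx)
    kept: list[int] = []
    kept_tree: cKDTree | None = None
    for i in range(len(idx)):
        if kept:
            if kept_tree is None or len(kept) != kept_tree.n:
                kept_tree = cKDTree(pos[kept])
            if kept_tree.query_ball_point(pos[i], nms_radius):
                continue
        kept.append(i)
    return [HydrationSite(position=pos[i], probability=float(probs[i])) for i in kept]


def predict_hydration(structure: ProteinStructure, coarse_model, fine_model,
                      coarse_threshold: float = DEFAULT_COARSE_THRESHOLD,
                      refine_radius: float = DEFAULT_REFINE_RADIUS,
                      site_threshold: float = DEFAULT_SITE_THRESHOLD,
                      nms_radius: float = DEFAULT_NMS_RADIUS,
                      ) -> tuple[ProbabilityMap, list[HydrationSite]]:
    """Full two-stage prediction: coarse scan, fine map, site extraction."""
    scan = scan_coarse(structure, coarse_model, coarse_threshold)
    if len(scan.points) == 0:
        vs = fine_model.box.voxel_size
        origin, n = _snapped_origin(structure, vs)
        empty = ProbabilityMap(values=np.zeros(tuple(n), np.float32),
                               origin=origin, voxel_size=vs)
        return empty, []
    pmap = predict_map(structure, fine_model, scan, refine_radius)
    sites = extract_sites(pmap, site_threshold, nms_radius)
    return pmap, sites


# ---------------------------------------------------------------------------
# MRC and site output
# ---------------------------------------------------------------------------

def write_mrc(pmap: ProbabilityMap, path) -> None:
    """Write the map as MRC2014 mode 2 (32-bit float), x fastest axis.

    The voxel size is carried by the cell dimensions (n * voxel_size per
    axis) and the placement by the ORIGIN header words.
    """
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(pmap.values, dtype=np.float32))
    n = pmap.values.shape
    m.grid.unit_cell = gemmi.UnitCell(n[0] * pmap.voxel_size, n[1] * pmap.voxel_size,
                                      n[2] * pmap.voxel_size, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2, True)
    for w, val in zip(_ORIGIN_WORDS, pmap.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> ProbabilityMap:
    """Read an MRC map written by :func:`write_mrc`.

    The evaluated mask is reconstructed as the nonzero voxels (MRC stores
    no mask, so evaluated-but-zero voxels are indistinguishable from
    unevaluated ones).
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MRCFormatError(f"cannot read MRC map: {exc}") from exc
    values = np.array(m.grid, copy=True)
    n = values.shape
    cell = m.grid.unit_cell
    vs = cell.a / n[0]
    if not (np.isclose(cell.b / n[1], vs) and np.isclose(cell.c / n[2], vs)):
        raise MRCFormatError("anisotropic voxel size is not supported")
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS])
    return ProbabilityMap(values=np.clip(values, 0.0, 1.0), origin=origin,
                          voxel_size=float(vs))


def write_sites_pdb(sites: list[HydrationSite], path) -> str:
    """Predicted sites as HETATM HOH oxygen records.

    The B-factor column carries 100 x probability.
    """
    lines = []
    for i, s in enumerate(sites, start=1):
        x, y, z = s.position
        lines.append(
            f"HETATM{i % 100000:5d}  O   HOH A{i % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{100.0 * s.probability:6.2f}"
            f"          {'O':>2s}"
        )
    text = "\n".join(lines + ["END", ""])
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def read_sites_pdb(path) -> list[HydrationSite]:
    """Read back a predicted-sites PDB written by :func:`write_sites_pdb`."""
    st = gemmi.read_pdb(str(path))
    sites = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name != "HOH":
                    continue
                for atom in res:
                    sites.append(HydrationSite(
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        probability=float(atom.b_iso) / 100.0,
                    ))
        break  # first model only
    return sites


def write_sites_tsv(sites: list[HydrationSite], path) -> str:
    """Predicted sites as tab-separated x, y, z, probability."""
    lines = ["x\ty\tz\tprobability"]
    for s in sites:
        lines.append(f"{s.position[0]:.3f}\t{s.position[1]:.3f}\t"
                     f"{s.position[2]:.3f}\t{s.probability:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
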