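"""Quantitative evaluation of hydration predictions.

Classification metrics (accuracy/precision/recall/F-measure over the
water-present decision at a probability threshold), per-site map
probabilities with their frequency histogram, MAD/RMSD matching of
crystal-water sites to predicted maxima, and surface coverage at a
nominal 20 A^2 of protein surface per hydration site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .predict import SCAN_DISTANCE, HydrationSite, ProbabilityMap
from .structure import VDW_RADII, ProteinStructure, sphere_points

#: Average protein surface area (A^2) accounted for by one first-layer
#: hydration water.
DEFAULT_AREA_PER_SITE = 20.0
#: Crystal-to-predicted matching cutoff (A).
DEFAULT_MATCH_CUTOFF = 3.0
#: Histogram bin width on the probability axis; 0.8 is a bin edge.
DEFAULT_BIN_WIDTH = 0.05


@dataclass
class ClassificationReport:
    """Confusion counts and the four derived rates."""

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f_measure: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.TP + self.FP + self.TN + self.FN
        self.accuracy = (self.TP + self.TN) / total if total else float("nan")
        self.precision = _rate(self.TP, self.TP + self.FP, "precision")
        self.recall = _rate(self.TP, self.TP + self.FN, "recall")
        self.f_measure = f_measure(self.precision, self.recall)


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if np.isnan(precision) or np.isnan(recall):
        return float("nan")
    if precision + recall == 0:
        warnings.warn("F-measure undefined (precision + recall = 0); reporting NaN",
                      stacklevel=2)
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(outputs, threshold: float = 0.5,
                           positive_label: int = 1) -> ClassificationReport:
    """Confusion counts via the decision rule y >= threshold -> present.

    ``outputs`` is a sequence of ``(y, d)`` pairs (probability, binary
    label); ``positive_label=0`` evaluates the water-absent class instead
    (prediction and label both inverted).
    """
    pairs = list(outputs)
    if not pairs:
        raise ValueError("empty outputs")
    y = np.array([p[0] for p in pairs], dtype=float)
    d = np.array([p[1] for p in pairs], dtype=int)
    pred = (y >= threshold).astype(int)
    if positive_label == 0:
        pred, d = 1 - pred, 1 - d
    TP = int(np.sum((pred == 1) & (d == 1)))
    FP = int(np.sum((pred == 1) & (d == 0)))
    TN = int(np.sum((pred == 0) & (d == 0)))
    FN = int(np.sum((pred == 0) & (d == 1)))
    return ClassificationReport(TP=TP, FP=FP, TN=TN, FN=FN)


# ---------------------------------------------------------------------------
# probability at crystal sites
# ---------------------------------------------------------------------------

@dataclass
class SiteProbabilityReport:
    """Per-site interpolated probabilities and their histogram."""

    probabilities: np.ndarray
    bin_edges: np.ndarray
    histogram: np.ndarray
    fraction_above_80: float
    n_outside: int


def probability_at_sites(pmap: ProbabilityMap, sites,
                         bin_width: float = DEFAULT_BIN_WIDTH) -> SiteProbabilityReport:
    """Trilinear map probability at each site plus its frequency histogram.

    Sites outside the map bounds are excluded (with a warning) and
    counted in ``n_outside``.  ``fraction_above_80`` is the share of
    in-bounds sites with probability > 0.8.
    """
    positions = np.atleast_2d(np.array([
        s.position if isinstance(s, HydrationSite) else s for s in sites
    ], dtype=float))
    if positions.size == 0:
        positions = positions.reshape(0, 3)
    n = np.array(pmap.shape)
    extent = pmap.origin + n * pmap.voxel_size
    inside = np.all((positions >= pmap.origin) & (positions < extent), axis=1)
    n_outside = int(np.sum(~inside))
    if n_outside:
        warnings.warn(f"{n_outside} site(s) outside the map bounds were excluded")
    pos = positions[inside]
    # fractional voxel-centre coordinates; clamped at the half-voxel border
    coords = (pos - pmap.origin) / pmap.voxel_size - 0.5
    probs = ndimage.map_coordinates(pmap.values.astype(float), coords.T,
                                    order=1, mode="nearest")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(probs, bins=edges)
    frac = float(np.mean(probs > 0.8)) if len(probs) else float("nan")
    return SiteProbabilityReport(probabilities=probs, bin_edges=edges,
                                 histogram=hist, fraction_above_80=frac,
                                 n_outside=n_outside)


# ---------------------------------------------------------------------------
# site matching (MAD / RMSD)
# ---------------------------------------------------------------------------

@dataclass
class SiteMatchReport:
    """Crystal-to-predicted site pairing with MAD and RMSD (A).

    MAD = mean |r_c - r_p| over matched pairs; RMSD is the root of the
    mean squared pair distance.  Matching is crystal -> nearest predicted
    site within ``cutoff`` (non-bijective: a predicted site may serve
    several crystal sites).
    """

    pairs: list[tuple[np.ndarray, np.ndarray, float]]
    N: int
    mad: float
    rmsd: float
    unmatched_crystal: int
    cutoff: float


def mad_rmsd(crystal_sites, predicted_sites,
             match_cutoff: float = DEFAULT_MATCH_CUTOFF) -> SiteMatchReport:
    """Match each crystal site to its nearest predicted site within cutoff."""
    crystal = np.atleast_2d(np.asarray(
        [s.position if isinstance(s, HydrationSite) else s for s in crystal_sites],
        dtype=float)) if len(crystal_sites) else np.empty((0, 3))
    pred = np.atleast_2d(np.asarray(
        [s.position if isinstance(s, HydrationSite) else s for s in predicted_sites],
        dtype=float)) if len(predicted_sites) else np.empty((0, 3))
    pairs: list[tuple[np.ndarray, np.ndarray, float]] = []
    unmatched = 0
    if len(crystal) == 0:
        return SiteMatchReport(pairs=[], N=0, mad=float("nan"), rmsd=float("nan"),
                               unmatched_crystal=0, cutoff=match_cutoff)
    if len(pred) == 0:
        return SiteMatchReport(pairs=[], N=0, mad=float("nan"), rmsd=float("nan"),
                               unmatched_crystal=len(crystal), cutoff=match_cutoff)
    d, j = cKDTree(pred).query(crystal, workers=1)
    for rc, dist, jj in zip(crystal, d, j):
        if dist <= match_cutoff:
            pairs.append((rc, pred[jj], float(dist)))
        else:
            unmatched += 1
    if not pairs:
        return SiteMatchReport(pairs=[], N=0, mad=float("nan"), rmsd=float("nan"),
                               unmatched_crystal=unmatched, cutoff=match_cutoff)
    dists = np.array([p[2] for p in pairs])
    return SiteMatchReport(
        pairs=pairs,
        N=len(pairs),
        mad=float(np.mean(dists)),
        rmsd=float(np.sqrt(np.mean(dists ** 2))),
        unmatched_crystal=unmatched,
        cutoff=match_cutoff,
    )


# ---------------------------------------------------------------------------
# first-layer / inside classification and surface coverage
# ---------------------------------------------------------------------------

def classify_sites(structure: ProteinStructure, positions,
                   probe_radius: float = 1.4, n_points: int = 240) -> np.ndarray:
    """Label each site "first_layer" or "inside".

    A site is *inside* when its own accessible surface — computed with
    the site as a water-oxygen sphere against protein atoms plus the
    other sites as occluders — is zero (a cavity or interface water
    isolated from bulk solvent); otherwise it is first-layer.
    """
    positions = np.atleast_2d(np.asarray(
        [s.position if isinstance(s, HydrationSite) else s for s in positions],
        dtype=float)) if len(positions) else np.empty((0, 3))
    if len(positions) == 0:
        return np.array([], dtype=object)
    prot = structure.protein_coords
    prot_r = np.array([VDW_RADII[a.element_class] for a in structure.protein_atoms])
    site_r = VDW_RADII["O"]
    occl = np.vstack([prot, positions])
    occl_r = np.concatenate([prot_r, np.full(len(positions), site_r)]) + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(occl)
    labels = np.empty(len(positions), dtype=object)
    R = site_r + probe_radius
    for i, p in enumerate(positions):
        pts = p + R * unit
        nb = [j for j in tree.query_ball_point(p, R + occl_r.max())
              if j != len(prot) + i]
        if nb:
            nb = np.asarray(nb, dtype=np.intp)
            d2 = np.sum((pts[:, None, :] - occl[nb][None, :, :]) ** 2, axis=2)
            exposed = ~np.all(np.any(d2 < (occl_r[nb] ** 2)[None, :], axis=1))
        else:
            exposed = True
        labels[i] = "first_layer" if exposed else "inside"
    return labels


@dataclass
class CoverageReport:
    """Surface coverage by first-layer predicted sites."""

    n_sites: int
    area_per_site: float
    total_surface: float
    coverage_percent: float


def surface_coverage(predicted_sites, structure: ProteinStructure,
                     area_per_site: float = DEFAULT_AREA_PER_SITE) -> CoverageReport:
    """Percent of the protein surface covered by first-layer sites.

    Counts predicted sites in the first-layer shell (within 4 A of a
    non-zero-ASA atom and not interior), each covering ``area_per_site``
    of the total per-atom ASA sum; capped at 100 %.
    """
    if structure.asa is None:
        raise ValueError("structure needs ASA; call compute_asa first")
    total = float(structure.asa.sum())
    if total <= 0:
        raise ValueError("total accessible surface is zero")
    positions = np.atleast_2d(np.asarray(
        [s.position if isinstance(s, HydrationSite) else s for s in predicted_sites],
        dtype=float)) if len(predicted_sites) else np.empty((0, 3))
    if len(positions):
        surf = structure.nonzero_asa_coords()
        d, _ = cKDTree(surf).query(positions, workers=1)
        shell = d <= SCAN_DISTANCE
        labels = classify_sites(structure, positions)
        count = int(np.sum(shell & (labels == "first_layer")))
    else:
        count = 0
    pct = min(100.0, 100.0 * count * area_per_site / total)
    return CoverageReport(n_sites=count, area_per_site=area_per_site,
                          total_surface=total, coverage_percent=pct)
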