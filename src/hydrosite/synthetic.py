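"""Toy protein-like structures with rule-placed crystal waters.

The generator packs C/N/O/S heavy atoms at protein-like contact distances
inside a sphere, then places one "crystal water" per solvent-reachable
nitrogen or oxygen at a fixed hydrogen-bond-like distance along the
outward direction from the cluster centroid, unless the position clashes
with an existing atom or water.  The rule is deterministic given a seed,
so every downstream module (voxelizer, dataset builder, classifier,
scanner, metrics) can be trained and tested without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structure import Atom, ProteinStructure, compute_asa

#: Protein-like heavy-atom composition.
DEFAULT_ELEMENT_FRACTIONS = {"C": 0.60, "N": 0.15, "O": 0.22, "S": 0.03}


class PackingError(RuntimeError):
    """Rejection sampling could not place all atoms."""


@dataclass(frozen=True)
class ToyStructureSpec:
    """Parameters of the toy structure generator.

    ``hydration_distance`` (default 2.8 A) is a typical donor/acceptor-
    to-water hydrogen-bond length; ``clash_distance`` (default 2.4 A) is
    about the closest water-water contact; ``min_contact`` keeps packed
    heavy atoms at non-bonded protein-like separations.
    """

    n_atoms: int = 60
    element_fractions: dict = field(default_factory=lambda: dict(DEFAULT_ELEMENT_FRACTIONS))
    cluster_radius: float = 6.0
    min_contact: float = 2.2
    hydration_distance: float = 2.8
    clash_distance: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 10:
            raise ValueError("n_atoms must be >= 10")
        total = sum(self.element_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"element fractions must sum to 1, got {total}")
        if self.min_contact <= 0:
            raise ValueError("min_contact must be positive")
        if self.hydration_distance <= self.clash_distance:
            raise ValueError("hydration_distance must exceed clash_distance")


def generate_structure(spec: ToyStructureSpec,
                       max_tries_per_atom: int = 2000) -> ProteinStructure:
    """Generate one toy structure (ASA computed, waters placed)."""
    rng = np.random.default_rng(spec.seed)
    elements = list(spec.element_fractions)
    probs = np.array([spec.element_fractions[e] for e in elements], dtype=float)
    drawn = rng.choice(len(elements), size=spec.n_atoms, p=probs)

    coords = np.empty((spec.n_atoms, 3))
    placed = 0
    tries = 0
    cap = spec.n_atoms * max_tries_per_atom
    while placed < spec.n_atoms:
        if tries >= cap:
            raise PackingError(
                f"placed only {placed}/{spec.n_atoms} atoms after {cap} draws; "
                "increase cluster_radius or reduce n_atoms/min_contact"
            )
        tries += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = spec.cluster_radius * rng.random() ** (1.0 / 3.0)
        p = r * direction
        if placed == 0 or np.min(np.linalg.norm(coords[:placed] - p, axis=1)) >= spec.min_contact:
            coords[placed] = p
            placed += 1

    atoms = [
        Atom(position=coords[i], element_class=elements[drawn[i]],
             occupancy=1.0, b_factor=20.0, residue_name="TOY", chain_id="A")
        for i in range(spec.n_atoms)
    ]
    structure = compute_asa(ProteinStructure(
        protein_atoms=atoms, water_sites=[], id=f"toy-{spec.seed}"))

    centroid = coords.mean(axis=0)
    waters: list[Atom] = []
    water_pos: list[np.ndarray] = []
    for i, atom in enumerate(structure.protein_atoms):
        if atom.element_class not in ("N", "O") or structure.asa[i] <= 0:
            continue
        outward = atom.position - centroid
        norm = np.linalg.norm(outward)
        if norm < 1e-9:
            continue
        w = atom.position + spec.hydration_distance * outward / norm
        near_atom = np.min(np.linalg.norm(coords - w, axis=1))
        near_water = min((np.linalg.norm(q - w) for q in water_pos), default=np.inf)
        if near_atom < spec.clash_distance or near_water < spec.clash_distance:
            continue
        waters.append(Atom(position=w, element_class="O", occupancy=1.0,
                           b_factor=20.0, residue_name="HOH", chain_id="A",
                           is_water=True))
        water_pos.append(w)
    return ProteinStructure(
        protein_atoms=structure.protein_atoms,
        water_sites=waters,
        asa=structure.asa,
        id=structure.id,
    )


def generate_corpus(n_structures: int, spec: ToyStructureSpec,
                    seed: int | None = 0) -> list[ProteinStructure]:
    """Independent structures with per-structure seeds derived from ``seed``."""
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n_structures)
    corpus = []
    for i, s in enumerate(seeds):
        st = generate_structure(replace(spec, seed=int(s)))
        st.id = f"toy-{i:03d}-{int(s)}"
        corpus.append(st)
    return corpus
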