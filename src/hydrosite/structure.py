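"""Crystal-structure input: atoms, waters, and solvent accessibility.

Reads protein crystal structures from PDB text, keeps the four heavy-atom
element classes (C, N, O, S) used as input channels, separates crystal-water
oxygen sites, and computes per-atom accessible surface area (ASA) by
probe-sphere point sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
from scipy.spatial import cKDTree

#: Element classes carried as voxel channels, in fixed channel order.
ELEMENT_CLASSES = ("C", "N", "O", "S")

#: Van der Waals radii (Angstrom) used for ASA.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Default probe radius (Angstrom) of the rolling water sphere.
DEFAULT_PROBE_RADIUS = 1.4

_WATER_NAMES = frozenset({"HOH", "WAT"})


class PDBParseError(ValueError):
    """Raised when the source is not parseable PDB text."""


class EmptyStructureError(ValueError):
    """Raised when no protein heavy atoms survive filtering."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom (or crystal-water oxygen) in a structure.

    Parameters
    ----------
    position : ndarray of shape (3,)
        Cartesian coordinates in Angstrom.
    element_class : str
        One of ``"C"``, ``"N"``, ``"O"``, ``"S"``.
    occupancy : float
        Crystallographic occupancy in [0, 1].
    b_factor : float
        Isotropic displacement parameter (Angstrom^2), non-negative.
    residue_name, chain_id : str
        Bookkeeping copied from the source record.
    is_water : bool
        True for crystal-water oxygen sites.
    """

    position: np.ndarray
    element_class: str
    occupancy: float = 1.0
    b_factor: float = 0.0
    residue_name: str = "UNK"
    chain_id: str = "A"
    is_water: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be 3 finite coordinates, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"element_class must be one of {ELEMENT_CLASSES}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.b_factor < 0:
            raise ValueError(f"b_factor must be >= 0, got {self.b_factor}")
        if self.is_water and self.element_class != "O":
            raise ValueError("water sites must be oxygen atoms")


@dataclass
class ProteinStructure:
    """Protein heavy atoms plus crystal-water oxygen sites.

    ``asa`` is filled by :func:`compute_asa`; it holds one non-negative
    entry (Angstrom^2) per protein atom.  Structures are treated as
    immutable once built; coordinate arrays are cached on first access.
    """

    protein_atoms: list[Atom]
    water_sites: list[Atom]
    asa: np.ndarray | None = None
    id: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(a.is_water for a in self.protein_atoms):
            raise ValueError("protein_atoms must not contain waters")
        if not all(w.is_water for w in self.water_sites):
            raise ValueError("every water site must be flagged is_water")
        if self.asa is not None:
            self.asa = np.asarray(self.asa, dtype=float)
            if self.asa.shape != (len(self.protein_atoms),) or np.any(self.asa < 0):
                raise ValueError("asa must hold one non-negative entry per protein atom")

    @property
    def n_atoms(self) -> int:
        return len(self.protein_atoms)

    @property
    def n_waters(self) -> int:
        return len(self.water_sites)

    @property
    def protein_coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates of the protein heavy atoms."""
        if "pc" not in self._cache:
            self._cache["pc"] = (
                np.array([a.position for a in self.protein_atoms], dtype=float)
                if self.protein_atoms
                else np.empty((0, 3))
            )
        return self._cache["pc"]

    @property
    def water_coords(self) -> np.ndarray:
        """(n_waters, 3) coordinates of the crystal-water oxygens."""
        if "wc" not in self._cache:
            self._cache["wc"] = (
                np.array([w.position for w in self.water_sites], dtype=float)
                if self.water_sites
                else np.empty((0, 3))
            )
        return self._cache["wc"]

    @property
    def element_channels(self) -> np.ndarray:
        """(n_atoms,) integer channel index of each protein atom."""
        if "ch" not in self._cache:
            idx = {e: i for i, e in enumerate(ELEMENT_CLASSES)}
            self._cache["ch"] = np.array(
                [idx[a.element_class] for a in self.protein_atoms], dtype=np.intp
            )
        return self._cache["ch"]

    def nonzero_asa_coords(self) -> np.ndarray:
        """Coordinates of solvent-reachable (ASA > 0) protein atoms."""
        if self.asa is None:
            raise ValueError("ASA not computed; call compute_asa first")
        return self.protein_coords[self.asa > 0]

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "ProteinStructure":
        """Return a rigidly moved copy (ASA is carried over unchanged)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.broadcast_to(np.asarray(translation, dtype=float), (3,))

        def move(a: Atom) -> Atom:
            return replace(a, position=R @ a.position + t)

        return ProteinStructure(
            protein_atoms=[move(a) for a in self.protein_atoms],
            water_sites=[move(w) for w in self.water_sites],
            asa=None if self.asa is None else self.asa.copy(),
            id=self.id,
        )


def _as_text(pdb_source) -> str:
    if isinstance(pdb_source, Path):
        return pdb_source.read_text()
    if hasattr(pdb_source, "read"):
        return pdb_source.read()
    text = str(pdb_source)
    # A bare path string (no newline, existing file) is read from disk.
    if "\n" not in text and Path(text).is_file():
        return Path(text).read_text()
    return text


def read_structure(pdb_source, altloc_policy: str = "blank_or_a") -> ProteinStructure:
    """Read a PDB source into a :class:`ProteinStructure`.

    Only the first MODEL is used.  Protein atoms are ATOM records whose
    element is one of C/N/O/S; hydrogens, other elements and non-water
    HETATM ligands are dropped.  Waters are ATOM/HETATM records with
    residue name HOH or WAT (oxygen only).

    Parameters
    ----------
    pdb_source : str, Path or text stream
        PDB text, a path to a PDB file, or an open text stream.
    altloc_policy : {"blank_or_a", "highest_occupancy"}
        ``"blank_or_a"`` keeps alternate locations ' ' or 'A' (the usual
        crystallographic convention); ``"highest_occupancy"`` keeps the
        highest-occupancy conformer of each altloc group.
    """
    if altloc_policy not in ("blank_or_a", "highest_occupancy"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    text = _as_text(pdb_source)
    lines = text.splitlines()
    first = next((ln for ln in lines if ln.strip()), "")
    if not any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        raise PDBParseError(
            f"no ATOM/HETATM records found; first non-blank line: {first!r}"
        )
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(f"unparseable PDB source: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"no model parsed; first non-blank line: {first!r}")

    protein: list[Atom] = []
    waters: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            is_water = res.name in _WATER_NAMES or res.is_water()
            if not is_water and res.het_flag == "H":
                continue  # non-water HETATM ligand: excluded from the channels
            atoms: Iterable[gemmi.Atom] = res
            if altloc_policy == "highest_occupancy":
                atoms = _highest_occupancy(res)
            for atom in atoms:
                if altloc_policy == "blank_or_a" and atom.altloc not in ("\x00", "", "A"):
                    continue
                elem = atom.element.name.upper()
                if elem not in ELEMENT_CLASSES:
                    continue
                if is_water and elem != "O":
                    continue
                rec = Atom(
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    element_class=elem,
                    occupancy=float(min(max(atom.occ, 0.0), 1.0)),
                    b_factor=float(max(atom.b_iso, 0.0)),
                    residue_name=res.name,
                    chain_id=chain.name,
                    is_water=is_water,
                )
                (waters if is_water else protein).append(rec)
    if not protein:
        raise EmptyStructureError(
            "no protein heavy atoms in the C/N/O/S classes after filtering"
        )
    return ProteinStructure(protein_atoms=protein, water_sites=waters, id=st.name or "")


def _highest_occupancy(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom-name group."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        key = atom.name
        if key not in best or atom.occ > best[key].occ:
            best[key] = atom
    return list(best.values())


def write_pdb(structure: ProteinStructure, target=None) -> str:
    """Write a structure as PDB text; optionally to a path or stream.

    Coordinates are emitted at PDB precision (3 decimals).  Returns the
    PDB text in all cases.
    """
    st = gemmi.Structure()
    st.name = structure.id or "hydrosite"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for atom_rec, het in [(a, False) for a in structure.protein_atoms] + [
        (w, True) for w in structure.water_sites
    ]:
        serial += 1
        cid = atom_rec.chain_id or "A"
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = atom_rec.residue_name if not het else "HOH"
        res.seqid = gemmi.SeqId(serial, " ")
        res.het_flag = "H" if het else "A"
        g = gemmi.Atom()
        g.name = atom_rec.element_class if not het else "O"
        g.element = gemmi.Element(atom_rec.element_class)
        g.pos = gemmi.Position(*atom_rec.position)
        g.occ = atom_rec.occupancy
        g.b_iso = atom_rec.b_factor
        res.add_atom(g)
        chains[cid].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            Path(target).write_text(text)
    return text


def sphere_points(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def compute_asa(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> ProteinStructure:
    """Per-atom accessible surface area by sphere-point sampling.

    Shrake-Rupley-style: each protein atom is expanded by the probe
    radius, ``n_points`` quasi-uniform points are placed on the expanded
    sphere, and the accessible fraction is the share of points outside
    every neighbouring expanded sphere.  Only protein heavy atoms occlude;
    waters are ignored.  Deterministic for fixed ``n_points``.

    Returns a new structure with ``asa`` filled (Angstrom^2 per atom).
    """
    if structure.n_atoms < 1:
        raise ValueError("structure has no protein atoms")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 64:
        raise ValueError("n_points must be >= 64 for a usable estimate")

    coords = structure.protein_coords
    radii = np.array(
        [VDW_RADII[a.element_class] for a in structure.protein_atoms]
    ) + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    asa = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if neighbors:
            nb = np.asarray(neighbors, dtype=np.intp)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (radii[nb] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        asa[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return ProteinStructure(
        protein_atoms=structure.protein_atoms,
        water_sites=structure.water_sites,
        asa=asa,
        id=structure.id,
    )
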