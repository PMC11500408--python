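"""Chemical data model shared by every stage of the parameterization.

Atoms carry Cartesian positions in Angstrom and partial charges in units of
the elementary charge.  A :class:`Structure` is an ordered list of atoms plus
an undirected bond graph; coordination (metal-ligand) bonds are ordinary
graph edges.  Indices are 0-based everywhere in memory and converted to
1-based only by the file writers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "MetalFFError",
    "ParseError",
    "NoMatchError",
    "ValenceError",
    "LibraryError",
    "ConvergenceError",
    "TopologyError",
    "COVALENT_RADII",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "STANDARD_VALENCES",
    "is_metal_element",
    "perceive_bonds",
    "metal_indices",
    "molecular_graph",
    "graphs_isomorphic",
    "BOHR_TO_ANGSTROM",
]

BOHR_TO_ANGSTROM = 0.52917721092


class MetalFFError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MetalFFError):
    """A file could not be parsed."""


class NoMatchError(MetalFFError):
    """A template could not be matched onto a metal site."""


class ValenceError(MetalFFError):
    """An atom's valence is inconsistent with its element."""


class LibraryError(MetalFFError):
    """A template or Lennard-Jones library lookup failed."""


class ConvergenceError(MetalFFError):
    """An iterative solver failed to converge."""


class TopologyError(MetalFFError):
    """A topology violates its invariants."""


# Single-reference covalent radii (Angstrom), Cordero et al. 2008.
# Low-spin values are used for the 3d metals with a spin-state split.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07, "Hf": 1.75, "Ta": 1.70, "W": 1.62,
    "Re": 1.51, "Os": 1.44, "Ir": 1.41, "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Tl": 1.45, "Pb": 1.46, "Bi": 1.48,
}

# Bondi/Alvarez van der Waals radii (Angstrom); metals default to 2.0 in
# :func:`vdw_radius` when absent here.  Used only for ESP shell construction.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# Sigma-framework valences used by saturation.  Aromatic-ring membership
# lowers the effective valence by one (the delocalized pi bond); metal
# coordination bonds are dative and never count.
STANDARD_VALENCES: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

# Standard atomic weights (amu), rounded; used for topology atom records.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "Ga": 69.723, "Br": 79.904, "Ru": 101.07, "Rh": 102.906,
    "Pd": 106.42, "Ag": 107.868, "Cd": 112.414, "I": 126.904, "Ir": 192.217,
    "Pt": 195.084, "Au": 196.967, "Hg": 200.592, "Pb": 207.2,
}

_NONMETALS = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "Ge", "As", "Se", "Br", "Kr", "Sb", "Te", "I", "Xe",
}


def is_metal_element(element: str) -> bool:
    return normalize_element(element) not in _NONMETALS


def normalize_element(element: str) -> str:
    """Canonical capitalization of an element symbol ('PD' -> 'Pd')."""
    return element.strip().capitalize()


def covalent_radius(element: str) -> float:
    el = normalize_element(element)
    try:
        return COVALENT_RADII[el]
    except KeyError:
        raise MetalFFError(f"unknown element {element!r}: no covalent radius")


def vdw_radius(element: str) -> float:
    el = normalize_element(element)
    if el in VDW_RADII:
        return VDW_RADII[el]
    return 2.0


@dataclass
class Atom:
    """One atom: element symbol, label, position (Angstrom), charge (e)."""

    index: int
    element: str
    name: str = ""
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    partial_charge: float = 0.0
    is_metal: bool = False
    is_link_atom: bool = False

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite position")
        if not self.name:
            self.name = f"{self.element}{self.index + 1}"
        if not self.is_metal:
            self.is_metal = is_metal_element(self.element)

    def copy(self) -> "Atom":
        return dataclasses.replace(self, position=self.position.copy())


class Structure:
    """An ordered collection of atoms plus an undirected bond graph."""

    def __init__(self, atoms, bonds=(), formal_charge: int = 0):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: set[tuple[int, int]] = set()
        self.formal_charge = int(formal_charge)
        for i, j in bonds:
            self.add_bond(i, j)

    def __len__(self) -> int:
        return len(self.atoms)

    def add_bond(self, i: int, j: int) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise MetalFFError(f"bond ({i}, {j}) references a missing atom")
        if i == j:
            raise MetalFFError(f"self-bond on atom {i}")
        if self.atoms[i].is_metal and self.atoms[j].is_metal:
            raise MetalFFError(
                f"bond between metal atoms {i} and {j}: metal clusters "
                "(directly bonded metals) are not supported"
            )
        self.bonds.add((min(i, j), max(i, j)))

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def copy(self) -> "Structure":
        s = Structure([a.copy() for a in self.atoms], formal_charge=self.formal_charge)
        s.bonds = set(self.bonds)
        return s

    def subset(self, indices) -> tuple["Structure", dict[int, int]]:
        """Extract the atoms in ``indices`` (kept in ascending original
        order) as a new Structure; returns it plus the old->new index map."""
        order = sorted(indices)
        old_to_new = {old: new for new, old in enumerate(order)}
        atoms = []
        for new, old in enumerate(order):
            a = self.atoms[old].copy()
            a.index = new
            atoms.append(a)
        sub = Structure(atoms, formal_charge=self.formal_charge)
        for i, j in self.bonds:
            if i in old_to_new and j in old_to_new:
                sub.add_bond(old_to_new[i], old_to_new[j])
        return sub, old_to_new

    def graph(self) -> nx.Graph:
        return molecular_graph(self)


def molecular_graph(structure: Structure) -> nx.Graph:
    """Element-labeled undirected graph mirroring the structure's bonds."""
    g = nx.Graph()
    for atom in structure.atoms:
        g.add_node(atom.index, element=atom.element)
    g.add_edges_from(structure.bonds)
    return g


def perceive_bonds(structure: Structure, scale: float = 1.15) -> Structure:
    """Add a bond for every pair closer than ``scale`` times the sum of
    covalent radii.  Metal-metal bonds are never created; existing bonds are
    preserved.  Returns a new Structure."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = structure.copy()
    radii = np.array([covalent_radius(a.element) for a in out.atoms])
    pos = out.positions
    n = len(out)
    metal = np.array([a.is_metal for a in out.atoms])
    for i in range(n):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        cut = scale * (radii[i] + radii[i + 1:])
        for off in np.nonzero(d <= cut)[0]:
            j = i + 1 + int(off)
            if metal[i] and metal[j]:
                continue
            out.bonds.add((i, j))
    return out


def metal_indices(structure: Structure, metal_names) -> list[int]:
    """Indices of atoms whose element matches any requested metal symbol
    (case-insensitive), ascending.  Raises if a requested metal is absent."""
    if isinstance(metal_names, str):
        metal_names = [metal_names]
    if not metal_names:
        raise ValueError("metal_names must be nonempty")
    wanted = {normalize_element(m) for m in metal_names}
    found: dict[str, list[int]] = {m: [] for m in wanted}
    for atom in structure.atoms:
        if atom.element in wanted:
            found[atom.element].append(atom.index)
    missing = sorted(m for m, idx in found.items() if not idx)
    if missing:
        raise MetalFFError(f"metal not found in structure: {', '.join(missing)}")
    return sorted(i for idx in found.values() for i in idx)


def graphs_isomorphic(g1: nx.Graph, g2: nx.Graph):
    """Element-label-preserving graph isomorphism g1 -> g2, or None."""
    gm = nx.isomorphism.GraphMatcher(
        g1, g2, node_match=lambda a, b: a["element"] == b["element"]
    )
    if gm.is_isomorphic():
        return dict(gm.mapping)
    return None
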