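"""Metal-site location, template-backbone extraction and saturation.

A *template backbone* around a metal is the union of (a) all atoms within
three bonds of the metal and (b) every complete aromatic ring system that
contains a metal-coordinated atom.  Atoms one bond outside the backbone are
kept as link atoms; hydrogens are then added to complete sigma valences so
the saturated species is suitable for an electronic-structure calculation.
Coordination bonds to metals are dative and never count toward a ligand
atom's valence; aromatic-ring membership lowers the effective sigma valence
by one (the delocalized pi bond).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import (
    Atom,
    MetalFFError,
    Structure,
    ValenceError,
    STANDARD_VALENCES,
    molecular_graph,
    normalize_element,
)
from .topology import Topology

__all__ = [
    "MetalSite", "Template",
    "aromatic_ring_systems", "extract_template_backbone", "saturate",
    "build_sites", "ligand_components",
]

_H_BOND_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34, "B": 1.19,
                   "Si": 1.48, "P": 1.42}
_AROMATIC_ELEMENTS = {"C", "N", "O", "S", "B"}
_PLANARITY_TOL = 0.1  # Angstrom, max deviation from the best-fit ring plane


@dataclass
class MetalSite:
    """One metal center of the input structure together with its ligand
    surroundings.  ``site_to_parent`` maps site-structure indices back to
    the parent structure; ``metal_site_index`` is the metal's index inside
    ``structure``."""

    metal_index: int              # index in the parent structure
    metal_symbol: str
    formal_charge: int
    coordinating: list[int]       # parent-structure indices
    structure: Structure
    site_to_parent: list[int]
    metal_site_index: int

    def __post_init__(self) -> None:
        for c in self.coordinating:
            pair = (min(c, self.metal_index), max(c, self.metal_index))
            # every coordinating atom must be bonded to the metal, checked
            # against the parent bond list carried into the site structure
            local = (min(self.site_to_parent.index(c), self.metal_site_index),
                     max(self.site_to_parent.index(c), self.metal_site_index))
            if local not in self.structure.bonds:
                raise MetalFFError(
                    f"coordinating atom {c} is not bonded to metal "
                    f"{self.metal_index}")


@dataclass
class Template:
    """A parameterized metal binding site.

    ``structure`` is the final (unsaturated) template: backbone plus link
    atoms, without the saturation hydrogens.  ``topology`` indexes into
    ``structure`` and carries the bonded terms involving or near the metal.
    ``residual_charges`` (one entry per structure atom, units e) encode the
    metal-to-ligand charge transfer and sum to zero.
    """

    name: str
    structure: Structure
    saturated_structure: Structure
    topology: Topology
    residual_charges: np.ndarray
    metal_index: int
    metal_symbol: str
    formal_charge: int
    lj_source: str = "merz"
    improper_flag: bool = False
    truncation_level: str = "none"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residual_charges = np.asarray(self.residual_charges, dtype=float)
        if len(self.residual_charges) != len(self.structure):
            raise MetalFFError(
                "residual charges must have one entry per template atom")
        self.validate()

    def validate(self) -> None:
        total = math.fsum(self.residual_charges.tolist())
        if abs(total) > 1e-10:
            raise MetalFFError(
                f"template residual charges sum to {total:.3e} e, not 0")

    @property
    def radius(self) -> float:
        """Distance from the metal to its furthest template atom (A)."""
        pos = self.structure.positions
        d = np.linalg.norm(pos - pos[self.metal_index], axis=1)
        return float(d.max())


def aromatic_ring_systems(structure: Structure) -> list[set[int]]:
    """Fused systems of aromatic rings: SSSR-style cycles of size 5-7 whose
    atoms are sp2-capable elements with <=3 sigma bonds and which deviate
    from their best-fit plane by less than 0.1 A.  Rings sharing an atom
    are merged into one system."""
    g = molecular_graph(structure)
    rings = nx.minimum_cycle_basis(g)
    aromatic: list[set[int]] = []
    for ring in rings:
        if not 5 <= len(ring) <= 7:
            continue
        ok = True
        for i in ring:
            atom = structure.atoms[i]
            if atom.element not in _AROMATIC_ELEMENTS:
                ok = False
                break
            heavy_deg = sum(
                1 for nbr in structure.neighbors(i)
                if not structure.atoms[nbr].is_metal)
            if heavy_deg > 3:
                ok = False
                break
        if not ok:
            continue
        pts = structure.positions[sorted(ring)]
        center = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - center)
        dev = np.abs((pts - center) @ vt[2])
        if dev.max() < _PLANARITY_TOL:
            aromatic.append(set(ring))
    # merge fused rings
    merged: list[set[int]] = []
    for ring in aromatic:
        hits = [s for s in merged if s & ring]
        for s in hits:
            merged.remove(s)
            ring = ring | s
        merged.append(ring)
    return merged


def aromatic_atoms(structure: Structure) -> set[int]:
    out: set[int] = set()
    for system in aromatic_ring_systems(structure):
        out |= system
    return out


def _backbone_indices(structure: Structure, metal_index: int,
                      max_bond_distance: int = 3):
    """Backbone and link-atom index sets around one metal."""
    if not structure.neighbors(metal_index):
        raise MetalFFError(f"metal atom {metal_index} has no bonds; cannot "
                           "extract a template around an isolated metal")
    g = molecular_graph(structure)
    for atom in structure.atoms:
        if atom.is_metal and atom.index != metal_index:
            g.remove_node(atom.index)
    dist = nx.single_source_shortest_path_length(
        g, metal_index, cutoff=max_bond_distance)
    backbone = set(dist)
    coordinated = set(structure.neighbors(metal_index))
    for system in aromatic_ring_systems(structure):
        if system & coordinated:
            backbone |= system
    link: set[int] = set()
    for i in sorted(backbone):
        for j in structure.neighbors(i):
            if j not in backbone and not structure.atoms[j].is_metal:
                link.add(j)
    return backbone, link


def extract_template_backbone(structure: Structure, metal_index: int,
                              max_bond_distance: int = 3) -> Structure:
    """Carve out the template around ``metal_index``: the 3-bond ball plus
    complete metal-coordinated aromatic ring systems, with the one-bond
    shell of extra atoms flagged ``is_link_atom``."""
    backbone, link = _backbone_indices(structure, metal_index,
                                       max_bond_distance)
    sub, old_to_new = structure.subset(backbone | link)
    for old in link:
        sub.atoms[old_to_new[old]].is_link_atom = True
    sub.formal_charge = 0  # set by the caller once ligand charges are known
    return sub


def _completion_directions(existing: list[np.ndarray], missing: int
                           ) -> list[np.ndarray]:
    """Unit vectors for hydrogens completing a center with the given
    existing bond directions (deterministic)."""
    def _unit(v):
        n = np.linalg.norm(v)
        return v / n if n > 1e-10 else np.array([0.0, 0.0, 1.0])

    if not existing:
        base = np.array([0.0, 0.0, 1.0])
    else:
        base = _unit(-sum(existing))
    if missing == 1:
        return [base]
    # reference perpendicular: symmetric w.r.t. existing bonds when possible
    if len(existing) >= 2:
        ref = existing[0] - existing[1]
    else:
        ref = np.array([1.0, 0.0, 0.0])
    perp = ref - np.dot(ref, base) * base
    if np.linalg.norm(perp) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        perp = ref - np.dot(ref, base) * base
    perp = _unit(perp)
    perp2 = np.cross(base, perp)
    if len(existing) <= 1:
        half = math.radians(180.0 - 109.471)   # cone opening for -CH3 etc.
    else:
        half = math.radians(109.471 / 2.0)     # e.g. the two H of a CH2
    out = []
    for m in range(missing):
        az = 2.0 * math.pi * m / missing
        d = (math.cos(half) * base
             + math.sin(half) * (math.cos(az) * perp + math.sin(az) * perp2))
        out.append(_unit(d))
    return out


def saturate(template_structure: Structure) -> Structure:
    """Add hydrogens until every non-metal atom reaches its standard sigma
    valence (C4 N3 O2 S2 H1; aromatic atoms one less; dative metal bonds do
    not count).  Existing atoms are never moved; added H carry
    ``is_added_h=True`` and are appended after the input atoms."""
    out = template_structure.copy()
    arom = aromatic_atoms(out)
    n0 = len(out)
    for i in range(n0):
        atom = out.atoms[i]
        if atom.is_metal or atom.element == "H":
            continue
        if atom.element not in STANDARD_VALENCES:
            warnings.warn(f"no standard valence for {atom.element}; atom "
                          f"{i} left unsaturated")
            continue
        target = STANDARD_VALENCES[atom.element]
        if i in arom:
            target -= 1
        sigma_bonds = [j for j in out.neighbors(i)
                       if not out.atoms[j].is_metal]
        current = len(sigma_bonds)
        if current > target:
            if atom.element in ("S", "P"):
                warnings.warn(
                    f"hypervalent {atom.element} at atom {i} "
                    f"({current} bonds); left as-is")
                continue
            raise ValenceError(
                f"atom {i} ({atom.element}) has {current} bonds, exceeding "
                f"its standard valence {target}")
        missing = target - current
        if missing == 0:
            continue
        dirs = _completion_directions(
            [  # unit vectors toward existing neighbors
                (out.atoms[j].position - atom.position)
                / np.linalg.norm(out.atoms[j].position - atom.position)
                for j in out.neighbors(i)
            ],
            missing,
        )
        length = _H_BOND_LENGTHS.get(atom.element, 1.0)
        for d in dirs:
            h = Atom(index=len(out.atoms), element="H",
                     name=f"H{len(out.atoms) + 1}",
                     position=atom.position + length * d)
            h.is_added_h = True
            out.atoms.append(h)
            out.add_bond(i, h.index)
    for atom in out.atoms:
        if not hasattr(atom, "is_added_h"):
            atom.is_added_h = False
    return out


def ligand_components(structure: Structure, metal_index: int | None = None
                      ) -> list[list[int]]:
    """Connected components of the structure with all metals removed
    (the ligands/linkers), each sorted ascending; components sorted by
    their smallest index."""
    g = molecular_graph(structure)
    for atom in structure.atoms:
        if atom.is_metal:
            g.remove_node(atom.index)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def build_sites(structure: Structure, metal_and_charge: dict[str, int],
                topology: Topology | None = None) -> list[MetalSite]:
    """One MetalSite per requested metal atom.  The site structure holds
    the metal plus every ligand connected to it (bridging ligands appear in
    both bridged sites).  Raises if two metals share a ligand atom (metals
    must be separated by at least two nonmetal atoms)."""
    from .core import metal_indices as _metal_indices

    wanted = {normalize_element(k): int(v) for k, v in metal_and_charge.items()}
    midx = _metal_indices(structure, list(wanted))
    # limitation check: no single nonmetal atom bonded to two metals
    for atom in structure.atoms:
        if atom.is_metal:
            continue
        metal_nbrs = [j for j in structure.neighbors(atom.index)
                      if structure.atoms[j].is_metal]
        if len(metal_nbrs) > 1:
            raise MetalFFError(
                f"atom {atom.index} bridges metals {metal_nbrs}; metals must "
                "be separated by at least two nonmetal atoms (metal clusters "
                "are not supported)")
    sites = []
    components = ligand_components(structure)
    for m in midx:
        coordinating = [j for j in structure.neighbors(m)
                        if not structure.atoms[j].is_metal]
        if not coordinating:
            raise MetalFFError(f"metal atom {m} has no coordinating atoms")
        keep: set[int] = {m}
        for comp in components:
            if any(c in comp for c in coordinating):
                keep |= set(comp)
        sub, old_to_new = structure.subset(keep)
        site_to_parent = sorted(keep)
        sites.append(MetalSite(
            metal_index=m,
            metal_symbol=structure.atoms[m].element,
            formal_charge=wanted[structure.atoms[m].element],
            coordinating=sorted(coordinating),
            structure=sub,
            site_to_parent=site_to_parent,
            metal_site_index=old_to_new[m],
        ))
    return sites
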