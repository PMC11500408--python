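"""Patching the input topology with template parameters.

For every mapped site the template's bonded terms replace the input
topology's terms over the mapped atoms (metal-involving terms, absent from
a metal-free topology, are added); the template's residual charges are
added on top of the input partial charges, with the metal reset to its
integer formal charge first (the nonbonded-model convention); and the
metal's Lennard-Jones parameters are taken from the requested library.
Because each residual-charge set sums to zero, patching only redistributes
charge.  Atoms outside all mapped sites are untouched.  GROMACS generates
1-2/1-3/1-4 exclusions from the bond list via nrexcl, so adding the new
metal bonds to [ bonds ] is what regenerates the exclusions they require.
"""

from __future__ import annotations

import math

from .core import MetalFFError, Structure
from .coordinates import write_coordinates
from .ljlib import lookup_lj
from .sites import Template
from .topology import (
    AngleTerm,
    AtomType,
    BondTerm,
    DihedralTerm,
    Topology,
    write_topology,
)

__all__ = [
    "patch_bonded", "apply_residual_charges", "assign_metal_lj",
    "reorder_and_emit",
]


def _mapped(mapping: dict[int, int], indices) -> list[int]:
    out = []
    for t in indices:
        if t not in mapping:
            raise MetalFFError(
                f"mapping incomplete: template atom {t} of a bonded term "
                "has no image in the site")
        out.append(mapping[t])
    return out


def patch_bonded(topology: Topology, template: Template,
                 mapping: dict[int, int]) -> Topology:
    """Substitute/add the template's bonds, angles and impropers into the
    topology through ``mapping`` (template atom -> topology atom).  Proper
    dihedrals through the metal are never introduced; terms not touching
    mapped atoms are unchanged."""
    out = topology.copy()
    bond_pos = out.bond_index()
    for b in template.topology.bonds:
        gi, gj = _mapped(mapping, (b.i, b.j))
        term = BondTerm(i=gi, j=gj, r_eq=b.r_eq, k=b.k, funct=b.funct)
        key = term.key()
        if key in bond_pos:
            out.bonds[bond_pos[key]] = term
        else:
            bond_pos[key] = len(out.bonds)
            out.bonds.append(term)
    angle_pos = out.angle_index()
    for a in template.topology.angles:
        gi, gj, gk = _mapped(mapping, (a.i, a.j, a.k_idx))
        term = AngleTerm(i=gi, j=gj, k_idx=gk, theta_eq=a.theta_eq, k=a.k,
                         funct=a.funct)
        key = term.key()
        if key in angle_pos:
            out.angles[angle_pos[key]] = term
        else:
            angle_pos[key] = len(out.angles)
            out.angles.append(term)
    dih_pos = {d.key(): pos for pos, d in enumerate(out.dihedrals)}
    for d in template.topology.dihedrals:
        if d.funct == 1:
            continue  # proper dihedrals through the metal stay absent
        gi, gj, gk, gl = _mapped(mapping, (d.i, d.j, d.k_idx, d.l))
        term = DihedralTerm(i=gi, j=gj, k_idx=gk, l=gl, funct=d.funct,
                            params=d.params)
        key = term.key()
        if key in dih_pos:
            out.dihedrals[dih_pos[key]] = term
        else:
            dih_pos[key] = len(out.dihedrals)
            out.dihedrals.append(term)
    out.validate()
    return out


def apply_residual_charges(topology: Topology, template: Template,
                           mapping: dict[int, int],
                           metal_topology_index: int | None = None,
                           ) -> Topology:
    """Add the template's residual charges through the mapping.  The metal
    is first reset to its integer formal charge (nonbonded-model
    convention), then receives its own residual."""
    template.validate()
    out = topology.copy()
    if metal_topology_index is None:
        metal_topology_index = mapping[template.metal_index]
    out.atoms[metal_topology_index].charge = float(template.formal_charge)
    for t_idx, dq in enumerate(template.residual_charges):
        if t_idx not in mapping:
            raise MetalFFError(
                f"mapping incomplete: template atom {t_idx} carries a "
                "residual charge but has no image in the site")
        out.atoms[mapping[t_idx]].charge += float(dq)
    return out


def assign_metal_lj(topology: Topology, metal_indices: list[int],
                    symbol: str, formal_charge: int,
                    lj_source: str) -> Topology:
    """Give the metal atoms' type the library sigma/epsilon for
    (symbol, charge, source); all other atom types are untouched.  If the
    metal shares its type with non-metal atoms it gets a fresh type."""
    entry = lookup_lj(symbol, formal_charge, lj_source)
    out = topology.copy()
    metal_set = set(metal_indices)
    metal_types = {out.atoms[i].type for i in metal_set}
    for tname in sorted(metal_types):
        shared = any(a.type == tname for i, a in enumerate(out.atoms)
                     if i not in metal_set)
        if shared:
            new_name = f"{entry.symbol}{entry.formal_charge}{entry.source}"
            old = out.atomtypes[tname]
            out.atomtypes[new_name] = AtomType(
                name=new_name, atnum=old.atnum, mass=old.mass,
                charge=old.charge, sigma=entry.sigma, epsilon=entry.epsilon,
                ptype=old.ptype)
            for i in metal_set:
                if out.atoms[i].type == tname:
                    out.atoms[i].type = new_name
        else:
            t = out.atomtypes[tname]
            t.sigma = entry.sigma
            t.epsilon = entry.epsilon
    out.validate()
    return out


def reorder_and_emit(structure: Structure, topology: Topology,
                     mappings, out_prefix: str) -> tuple[str, str]:
    """Write the output coordinate (PDB) and topology (GROMACS .top) files
    with a consistent atom order; template-to-site reordering is carried
    by the mappings, so the emitted order is the input order.  Returns the
    two paths."""
    if len(structure) != topology.n_atoms:
        raise MetalFFError(
            f"structure ({len(structure)} atoms) and topology "
            f"({topology.n_atoms} atoms) are inconsistent")
    out = structure.copy()
    for atom, record in zip(out.atoms, topology.atoms):
        atom.partial_charge = record.charge
    pdb_path = f"{out_prefix}.pdb"
    top_path = f"{out_prefix}.top"
    write_coordinates(out, pdb_path, format="pdb")
    write_topology(topology, top_path)
    return pdb_path, top_path


def total_charge_shift(before: Topology, after: Topology) -> float:
    return math.fsum(a.charge for a in after.atoms) - math.fsum(
        a.charge for a in before.atoms)
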