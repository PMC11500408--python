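"""Construction of new templates from a Hessian and ESP grids.

The pipeline mirrors how a site is parameterized from scratch: the
template backbone is carved out around the metal and saturated with
hydrogens; bonds and angles come from the modified-Seminario projection of
the supplied Hessian (computed for the saturated species); charges come
from RESP fits of the supplied ESP grids for the saturated template and
for each isolated ligand fragment, with the saturation hydrogens
constrained to zero charge; the residual charges are the difference.
Finally the saturation hydrogens are removed again, leaving the template
that enters the library.
"""

from __future__ import annotations

import math

import numpy as np

from .core import MetalFFError, Structure
from .resp import ESPGrid, fit_resp, residual_charges, symmetrize_charges
from .seminario import HessianData, ScanData, build_template_bonded, symmetrize
from .sites import Template, ligand_components, saturate
from .sites import _backbone_indices
from .topology import Topology

__all__ = ["prepare_saturated_template", "build_template"]

GEOMETRY_TOL = 1e-3  # Angstrom, Hessian/ESP geometry consistency


def prepare_saturated_template(structure: Structure, metal_index: int
                               ) -> tuple[Structure, Structure, int]:
    """Extract and saturate the template around one metal.  Returns
    (unsaturated template, saturated template, metal index within them)."""
    backbone, link = _backbone_indices(structure, metal_index)
    sub, old_to_new = structure.subset(backbone | link)
    for old in link:
        sub.atoms[old_to_new[old]].is_link_atom = True
    saturated = saturate(sub)
    return sub, saturated, old_to_new[metal_index]


def _check_geometry(reference: Structure, candidate_pos: np.ndarray,
                    what: str, tol: float = GEOMETRY_TOL) -> None:
    if len(reference) != len(candidate_pos):
        raise MetalFFError(
            f"{what}: {len(candidate_pos)} atoms, saturated template has "
            f"{len(reference)}")
    dev = np.linalg.norm(reference.positions - candidate_pos, axis=1)
    if dev.max() > tol:
        raise MetalFFError(
            f"{what}: geometry deviates from the saturated template "
            f"(max {dev.max():.4f} A > {tol} A)")


def _match_fragment(saturated: Structure, grid: ESPGrid,
                    tol: float = GEOMETRY_TOL) -> list[int]:
    """Map each grid nucleus to the saturated-template atom at the same
    position."""
    nuc = grid.nuclei_angstrom()
    pos = saturated.positions
    out = []
    used: set[int] = set()
    for k, p in enumerate(nuc):
        d = np.linalg.norm(pos - p, axis=1)
        i = int(np.argmin(d))
        if d[i] > tol or i in used:
            raise MetalFFError(
                f"fragment ESP nucleus {k} does not coincide with a unique "
                f"saturated-template atom (nearest at {d[i]:.4f} A)")
        if saturated.atoms[i].element != grid.elements[k].capitalize():
            raise MetalFFError(
                f"fragment ESP nucleus {k}: element "
                f"{grid.elements[k]} != template atom {i} "
                f"({saturated.atoms[i].element})")
        used.add(i)
        out.append(i)
    return out


def build_template(structure: Structure, metal_index: int,
                   formal_charge: int, hessian: HessianData,
                   template_grid: ESPGrid, fragment_grids: list[ESPGrid],
                   *, lj_source: str = "merz", improper_flag: bool = False,
                   improper_scan: ScanData | None = None,
                   name: str | None = None,
                   resp_restraint: float = 0.0005) -> Template:
    """Build a Template for the metal at ``metal_index``.

    ``hessian`` and ``template_grid`` must have been computed at the
    saturated-template geometry (checked to 1e-3 A); ``fragment_grids``
    cover the isolated saturated ligands, one grid per ligand, and must
    partition the non-metal template atoms.
    """
    sub, saturated, m_new = prepare_saturated_template(structure, metal_index)
    metal_symbol = saturated.atoms[m_new].element

    _check_geometry(saturated, hessian.geometry.positions, "Hessian")
    hess = HessianData(matrix=hessian.matrix, geometry=saturated)

    bonded = build_template_bonded(
        hess, m_new, formal_charge,
        improper_flag=improper_flag, improper_scan=improper_scan)
    bonded = symmetrize(bonded, saturated)

    added_h = [i for i, a in enumerate(saturated.atoms)
               if getattr(a, "is_added_h", False)]

    _check_geometry(saturated, template_grid.nuclei_angstrom(),
                    "template ESP grid")
    q_template = fit_resp(template_grid, zero_constrained=added_h,
                          a=resp_restraint)
    q_template = symmetrize_charges(q_template, saturated)

    fragments = ligand_components(saturated)
    if len(fragment_grids) != len(fragments):
        raise MetalFFError(
            f"{len(fragment_grids)} fragment grids for {len(fragments)} "
            "saturated-template ligands")
    frag_total = 0
    q_frag_full = np.zeros(len(saturated))
    q_frag_full[m_new] = float(formal_charge)
    assigned: list[list[int]] = []
    for grid in fragment_grids:
        indices = _match_fragment(saturated, grid)
        if sorted(indices) not in [sorted(f) for f in fragments]:
            raise MetalFFError(
                "fragment ESP grid does not coincide with one "
                "saturated-template ligand")
        local_zero = [k for k, i in enumerate(indices) if i in set(added_h)]
        q = fit_resp(grid, zero_constrained=local_zero, a=resp_restraint)
        for i, qv in zip(indices, q):
            q_frag_full[i] = qv
        assigned.append(indices)
        frag_total += grid.total_charge
    covered = sorted(i for f in assigned for i in f)
    if covered != sorted(i for f in fragments for i in f):
        raise MetalFFError("fragment grids do not partition the ligands")
    if template_grid.total_charge != formal_charge + frag_total:
        raise MetalFFError(
            f"template total charge {template_grid.total_charge} != metal "
            f"formal charge {formal_charge} + fragment charges {frag_total}")
    q_frag_full = symmetrize_charges(q_frag_full, saturated)

    dq = residual_charges(
        q_template,
        [(f, q_frag_full[f]) for f in (sorted(f) for f in fragments)],
        m_new, formal_charge)

    # remove the saturation hydrogens (appended last, so the kept indices
    # are unchanged); their charges were constrained to zero on both sides
    n0 = len(sub)
    dq_final = dq[:n0]
    total = math.fsum(dq_final.tolist())
    if abs(total) > 1e-10:
        raise MetalFFError(
            f"residual charges sum to {total:.3e} e after removing the "
            "saturation hydrogens")

    top = _restrict_topology(bonded, n0)
    for i, rec in enumerate(top.atoms):
        rec.charge = float(q_template[i])

    for i, atom in enumerate(sub.atoms):
        atom.partial_charge = float(q_template[i])

    return Template(
        name=name or f"{metal_symbol}{formal_charge}_{lj_source}",
        structure=sub,
        saturated_structure=saturated,
        topology=top,
        residual_charges=dq_final,
        metal_index=m_new,
        metal_symbol=metal_symbol,
        formal_charge=int(formal_charge),
        lj_source=lj_source,
        improper_flag=improper_flag or bool(bonded.impropers()),
        truncation_level="none",
        metadata={"n_saturation_h": len(saturated) - n0},
    )


def _restrict_topology(top: Topology, n0: int) -> Topology:
    out = top.copy()
    out.atoms = out.atoms[:n0]
    out.bonds = [b for b in out.bonds if b.i < n0 and b.j < n0]
    out.angles = [a for a in out.angles
                  if a.i < n0 and a.j < n0 and a.k_idx < n0]
    out.dihedrals = [d for d in out.dihedrals
                     if all(x < n0 for x in (d.i, d.j, d.k_idx, d.l))]
    out.pairs = [(i, j, f) for i, j, f in out.pairs if i < n0 and j < n0]
    out.exclusions = {i: [j for j in js if j < n0]
                      for i, js in out.exclusions.items() if i < n0}
    return out
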