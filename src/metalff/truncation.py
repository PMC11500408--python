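"""Template truncation: shrink a template by a bond-distance cutoff so it
can stand in for a missing, larger template.

Atoms more than 1, 2 or 3 bonds from the metal are removed; their residual
charges are summed in exact (rational) arithmetic and redistributed in
equal shares over every remaining atom, including the metal, so the
template's zero-sum invariant survives to machine precision.  Bonded terms
referencing a removed atom are dropped without refitting.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np

from .core import MetalFFError, molecular_graph
from .sites import Template, saturate

__all__ = ["truncate_template", "TRUNCATION_SCHEMES"]

TRUNCATION_SCHEMES = ("none", "3", "2", "1")


def truncate_template(template: Template, scheme) -> Template:
    """Return a new template truncated at the given bond distance from the
    metal ('none', 3, 2 or 1).  'none' returns an unchanged copy."""
    scheme = str(scheme).lower()
    if scheme not in TRUNCATION_SCHEMES:
        raise ValueError(f"truncation scheme must be one of "
                         f"{TRUNCATION_SCHEMES}, got {scheme!r}")
    if scheme == "none":
        out = Template(
            name=template.name,
            structure=template.structure.copy(),
            saturated_structure=template.saturated_structure.copy(),
            topology=template.topology.copy(),
            residual_charges=template.residual_charges.copy(),
            metal_index=template.metal_index,
            metal_symbol=template.metal_symbol,
            formal_charge=template.formal_charge,
            lj_source=template.lj_source,
            improper_flag=template.improper_flag,
            truncation_level="none",
            metadata=dict(template.metadata),
        )
        return out
    cutoff = int(scheme)

    s = template.structure
    g = molecular_graph(s)
    dist = nx.single_source_shortest_path_length(
        g, template.metal_index, cutoff=cutoff)
    keep = sorted(dist)
    if len(keep) < 2:
        raise MetalFFError(
            f"truncation scheme {scheme} would remove every ligand atom")
    removed = [i for i in range(len(s)) if i not in dist]

    # exact redistribution of the removed residual charge
    q = [Fraction(float(v)) for v in template.residual_charges]
    removed_total = sum((q[i] for i in removed), Fraction(0))
    share = removed_total / len(keep)
    new_q = np.array([float(q[i] + share) for i in keep])

    sub, old_to_new = s.subset(keep)
    sat = saturate(sub)

    top = template.topology.copy()
    keep_set = set(keep)
    top.atoms = [a for i, a in enumerate(top.atoms) if i in keep_set]

    def remap_ok(indices):
        return all(i in keep_set for i in indices)

    top.bonds = [b for b in top.bonds if remap_ok((b.i, b.j))]
    for b in top.bonds:
        b.i, b.j = old_to_new[b.i], old_to_new[b.j]
    top.angles = [a for a in top.angles
                  if remap_ok((a.i, a.j, a.k_idx))]
    for a in top.angles:
        a.i, a.j, a.k_idx = (old_to_new[a.i], old_to_new[a.j],
                             old_to_new[a.k_idx])
    top.dihedrals = [d for d in top.dihedrals
                     if remap_ok((d.i, d.j, d.k_idx, d.l))]
    for d in top.dihedrals:
        d.i, d.j, d.k_idx, d.l = (old_to_new[d.i], old_to_new[d.j],
                                  old_to_new[d.k_idx], old_to_new[d.l])
    top.pairs = [(old_to_new[i], old_to_new[j], f)
                 for i, j, f in top.pairs if remap_ok((i, j))]
    top.exclusions = {
        old_to_new[i]: sorted(old_to_new[j] for j in js if j in keep_set)
        for i, js in top.exclusions.items() if i in keep_set
    }

    return Template(
        name=f"{template.name}~trunc{scheme}",
        structure=sub,
        saturated_structure=sat,
        topology=top,
        residual_charges=new_q,
        metal_index=old_to_new[template.metal_index],
        metal_symbol=template.metal_symbol,
        formal_charge=template.formal_charge,
        lj_source=template.lj_source,
        improper_flag=template.improper_flag,
        truncation_level=scheme,
        metadata={**template.metadata, "truncation": scheme},
    )
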