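"""On-disk template library.

A template is a directory holding plain-text artifacts:

    metadata.txt          key: value pairs (metal, charge, L-J source,
                          radius, improper flag, truncation level, flags)
    template.pdb          unsaturated template coordinates + CONECT bonds
    saturated.pdb         saturated template (with the added hydrogens)
    topology.top          bonded terms near the metal, GROMACS dialect
    residual_charges.dat  one "index element dq" row per template atom

A library is a directory of such directories; templates are selected by
(metal, charge, L-J source) in lexicographic directory-name order.
"""

from __future__ import annotations

import os

import numpy as np

from .core import LibraryError, MetalFFError
from .coordinates import read_coordinates, write_coordinates
from .sites import Template
from .topology import read_topology, write_topology

__all__ = ["save_template", "load_template", "load_library"]


def save_template(template: Template, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    write_coordinates(template.structure,
                      os.path.join(dirpath, "template.pdb"), format="pdb")
    write_coordinates(template.saturated_structure,
                      os.path.join(dirpath, "saturated.pdb"), format="pdb")
    write_topology(template.topology, os.path.join(dirpath, "topology.top"))
    with open(os.path.join(dirpath, "residual_charges.dat"), "w") as fh:
        fh.write("# index element residual_charge_e\n")
        for i, dq in enumerate(template.residual_charges):
            fh.write(f"{i} {template.structure.atoms[i].element} "
                     f"{dq:.17g}\n")
    link = [str(i) for i, a in enumerate(template.structure.atoms)
            if a.is_link_atom]
    added = [str(i) for i, a in enumerate(template.saturated_structure.atoms)
             if getattr(a, "is_added_h", False)]
    meta = {
        "name": template.name,
        "metal": template.metal_symbol,
        "charge": str(template.formal_charge),
        "metal_index": str(template.metal_index),
        "lj_source": template.lj_source,
        "radius_A": f"{template.radius:.6f}",
        "improper": "yes" if template.improper_flag else "no",
        "truncation": template.truncation_level,
        "link_atoms": ",".join(link),
        "saturation_hydrogens": ",".join(added),
    }
    with open(os.path.join(dirpath, "metadata.txt"), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}: {v}\n")


def _read_metadata(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or ":" not in line:
                continue
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


def load_template(dirpath: str) -> Template:
    meta_path = os.path.join(dirpath, "metadata.txt")
    if not os.path.exists(meta_path):
        raise LibraryError(f"not a template directory: {dirpath}")
    meta = _read_metadata(meta_path)
    structure = read_coordinates(os.path.join(dirpath, "template.pdb"))
    saturated = read_coordinates(os.path.join(dirpath, "saturated.pdb"))
    topology = read_topology(os.path.join(dirpath, "topology.top"))
    if topology.n_atoms != len(structure):
        raise MetalFFError(
            f"{dirpath}: topology covers {topology.n_atoms} atoms, "
            f"coordinates {len(structure)}")
    dq = np.zeros(len(structure))
    with open(os.path.join(dirpath, "residual_charges.dat")) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            dq[int(tok[0])] = float(tok[2])
    for i, a in enumerate(structure.atoms):
        a.partial_charge = topology.atoms[i].charge
    link = {int(t) for t in meta.get("link_atoms", "").split(",") if t}
    for i in link:
        structure.atoms[i].is_link_atom = True
    added = {int(t) for t in meta.get("saturation_hydrogens", "").split(",")
             if t}
    for i, a in enumerate(saturated.atoms):
        a.is_added_h = i in added
    return Template(
        name=meta.get("name", os.path.basename(os.path.normpath(dirpath))),
        structure=structure,
        saturated_structure=saturated,
        topology=topology,
        residual_charges=dq,
        metal_index=int(meta["metal_index"]),
        metal_symbol=meta["metal"],
        formal_charge=int(meta["charge"]),
        lj_source=meta.get("lj_source", "merz"),
        improper_flag=meta.get("improper", "no") == "yes",
        truncation_level=meta.get("truncation", "none"),
        metadata=meta,
    )


def load_library(root: str) -> list[Template]:
    """Load every template directory under ``root``, sorted by name."""
    if not os.path.isdir(root):
        raise LibraryError(f"template library directory not found: {root}")
    out = []
    for entry in sorted(os.listdir(root)):
        sub = os.path.join(root, entry)
        if os.path.isdir(sub) and os.path.exists(
                os.path.join(sub, "metadata.txt")):
            tmpl = load_template(sub)
            tmpl.name = entry
            out.append(tmpl)
    return sorted(out, key=lambda t: t.name)
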