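"""Coordinate file I/O: PDB / XYZ / GRO reading, PDB / XYZ writing.

Reading goes through MDAnalysis, so anything its readers accept for these
three formats is accepted here; CONECT records become bonds, otherwise the
bond set is left empty for the caller to perceive.  Writing is done with
explicit fixed-width formatting so that identical structures always produce
byte-identical files (PDB positions round-trip to 1e-3 Angstrom, XYZ to full
float precision).  Writers emit 1-based serials; readers return 0-based
indices.
"""

from __future__ import annotations

import logging
import os
import warnings

logging.getLogger("MDAnalysis").setLevel(logging.WARNING)


from .core import (
    Atom,
    MetalFFError,
    ParseError,
    Structure,
    normalize_element,
    COVALENT_RADII,
)

__all__ = ["read_coordinates", "write_coordinates"]

_READ_FORMATS = {"pdb", "xyz", "gro"}


def _infer_format(path: str, format: str | None) -> str:
    if format:
        return format.lower().lstrip(".")
    return os.path.splitext(path)[1].lower().lstrip(".")


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from an atom name like 'PD1' or 'CA'."""
    letters = "".join(c for c in name if c.isalpha())
    if not letters:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    two = normalize_element(letters[:2])
    if len(letters) >= 2 and two in COVALENT_RADII:
        return two
    one = normalize_element(letters[:1])
    if one in COVALENT_RADII:
        return one
    raise ParseError(f"cannot infer element from atom name {name!r}")


def _first_bad_line(path: str) -> int | None:
    """Locate the first structurally broken line of a simple XYZ file, for
    error messages (MDAnalysis exceptions do not carry line numbers)."""
    try:
        with open(path) as fh:
            lines = fh.readlines()
        if not lines:
            return 1
        n = int(lines[0])
        for k in range(n):
            lineno = 3 + k
            if lineno - 1 >= len(lines):
                return len(lines) + 1
            tok = lines[lineno - 1].split()
            if len(tok) < 4:
                return lineno
            [float(t) for t in tok[1:4]]
    except (ValueError, IndexError):
        return 1
    return None


def _read_xyz(path: str) -> Structure:
    """Direct XYZ parser: MDAnalysis stores float32 coordinates, while the
    XYZ round-trip contract is full float64 precision."""
    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:1: malformed XYZ atom count") from exc
    atoms = []
    for k in range(n):
        lineno = 3 + k
        if lineno - 1 >= len(lines):
            raise ParseError(f"{path}:{len(lines) + 1}: truncated XYZ file "
                             f"({n} atoms declared, {k} found)")
        tok = lines[lineno - 1].split()
        try:
            atoms.append(Atom(index=k, element=tok[0],
                              position=[float(t) for t in tok[1:4]]))
        except (IndexError, ValueError) as exc:
            raise ParseError(
                f"{path}:{lineno}: malformed XYZ record") from exc
    return Structure(atoms)


def read_coordinates(path: str, format: str | None = None) -> Structure:
    """Read a PDB/XYZ/GRO file into a Structure (atoms in file order)."""
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise ParseError(f"coordinate file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt not in _READ_FORMATS:
        raise MetalFFError(f"unsupported coordinate format {fmt!r}")
    if fmt == "xyz":
        return _read_xyz(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=fmt)
            n = len(u.atoms)
            positions = u.atoms.positions.copy()
            names = list(getattr(u.atoms, "names", [f"X{i}" for i in range(n)]))
            if hasattr(u.atoms, "elements"):
                elements = [normalize_element(e) if e else _element_from_name(nm)
                            for e, nm in zip(u.atoms.elements, names)]
            else:
                elements = [_element_from_name(nm) for nm in names]
            bond_pairs = []
            if hasattr(u, "bonds"):
                bond_pairs = [tuple(int(x) for x in b.indices) for b in u.bonds]
    except (MetalFFError, ParseError):
        raise
    except Exception as exc:
        lineno = _first_bad_line(path) if fmt == "xyz" else None
        where = f"{path}:{lineno}" if lineno else path
        raise ParseError(f"{where}: malformed {fmt.upper()} record ({exc})") from exc

    atoms = [Atom(index=i, element=el, name=str(nm), position=positions[i])
             for i, (el, nm) in enumerate(zip(elements, names))]
    structure = Structure(atoms)
    for i, j in bond_pairs:
        if not (structure.atoms[i].is_metal and structure.atoms[j].is_metal):
            structure.add_bond(i, j)
    return structure


def write_coordinates(structure: Structure, path: str,
                      format: str | None = None) -> None:
    """Write a Structure as PDB (with CONECT records) or XYZ."""
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(structure, path)
    elif fmt == "xyz":
        _write_xyz(structure, path)
    else:
        raise MetalFFError(f"unsupported output coordinate format {fmt!r}")


def _write_pdb(structure: Structure, path: str) -> None:
    lines = []
    for atom in structure.atoms:
        serial = atom.index + 1
        name = atom.name[:4]
        # PDB column rules: 4-char names start at col 13, shorter at col 14
        name_field = f"{name:<4s}" if len(name) == 4 else f" {name:<3s}"
        x, y, z = atom.position
        el = atom.element.upper().rjust(2)
        lines.append(
            f"HETATM{serial:>5d} {name_field} MOL A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el}"
        )
    adjacency: dict[int, list[int]] = {}
    for i, j in sorted(structure.bonds):
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)
    for i in sorted(adjacency):
        partners = sorted(adjacency[i])
        for start in range(0, len(partners), 4):
            chunk = partners[start:start + 4]
            lines.append("CONECT" + f"{i + 1:>5d}"
                         + "".join(f"{j + 1:>5d}" for j in chunk))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_xyz(structure: Structure, path: str) -> None:
    lines = [str(len(structure)), "generated by metalff"]
    for atom in structure.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element} {x:.17g} {y:.17g} {z:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
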