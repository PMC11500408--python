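"""GROMACS-dialect topology model, reader and writer.

The in-memory :class:`Topology` keeps geometry-bearing quantities in the
package's internal units -- Angstrom, degrees, kJ/mol -- so bond lengths and
force constants compose directly with the geometry code.  Conversion to the
nm-based GROMACS units happens only at the file boundary:

==================  ==================  =====================
quantity            internal            on disk (.top)
==================  ==================  =====================
bond r_eq           Angstrom            nm
bond k_b            kJ mol-1 A-2        kJ mol-1 nm-2
angle theta, k      deg, kJ/mol/rad2    deg, kJ/mol/rad2
improper xi, k      deg, kJ/mol/rad2    deg, kJ/mol/rad2
L-J sigma, eps      nm, kJ/mol          nm, kJ/mol
==================  ==================  =====================

Supported directives: defaults, atomtypes, moleculetype, atoms, bonds,
angles, dihedrals (funct 1 proper / funct 2 harmonic improper), pairs,
exclusions, system, molecules.  ``#include`` lines are resolved relative to
the including file.  Anything else raises :class:`TopologyError` naming the
directive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .core import ParseError, TopologyError

__all__ = [
    "TopologyAtom", "AtomType", "BondTerm", "AngleTerm", "DihedralTerm",
    "Topology", "read_topology", "write_topology",
]


@dataclass
class TopologyAtom:
    name: str
    type: str
    charge: float
    mass: float
    resnr: int = 1
    resname: str = "MOL"
    cgnr: int = 1


@dataclass
class AtomType:
    name: str
    atnum: int
    mass: float
    charge: float
    sigma: float      # nm
    epsilon: float    # kJ/mol
    ptype: str = "A"


@dataclass
class BondTerm:
    i: int
    j: int
    r_eq: float       # Angstrom
    k: float          # kJ mol-1 A-2
    funct: int = 1

    def key(self) -> tuple[int, int]:
        return (min(self.i, self.j), max(self.i, self.j))


@dataclass
class AngleTerm:
    i: int
    j: int
    k_idx: int
    theta_eq: float   # degrees
    k: float          # kJ mol-1 rad-2
    funct: int = 1

    def key(self) -> tuple[int, int, int]:
        i, j, k = self.i, self.j, self.k_idx
        return (min(i, k), j, max(i, k))


@dataclass
class DihedralTerm:
    """funct 1: periodic proper, params (phase deg, k kJ/mol, mult).
    funct 2: harmonic improper, params (xi_eq deg, k kJ/mol/rad2)."""

    i: int
    j: int
    k_idx: int
    l: int
    funct: int
    params: tuple

    def key(self):
        return (self.i, self.j, self.k_idx, self.l, self.funct)


@dataclass
class Topology:
    atoms: list[TopologyAtom] = field(default_factory=list)
    atomtypes: dict[str, AtomType] = field(default_factory=dict)
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    pairs: list[tuple[int, int, int]] = field(default_factory=list)
    exclusions: dict[int, list[int]] = field(default_factory=dict)
    defaults: tuple = (1, 2, "yes", 0.5, 0.8333)
    molecule_name: str = "MOL"
    nrexcl: int = 3
    system_name: str = "system"
    declared_charge: float | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        # pairwise summation keeps the 1e-10 charge-bookkeeping guarantees
        import math
        return math.fsum(a.charge for a in self.atoms)

    def propers(self) -> list[DihedralTerm]:
        return [d for d in self.dihedrals if d.funct == 1]

    def impropers(self) -> list[DihedralTerm]:
        return [d for d in self.dihedrals if d.funct == 2]

    def validate(self) -> None:
        n = self.n_atoms
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise TopologyError(f"bond ({b.i},{b.j}) out of range (n={n})")
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k_idx)):
                raise TopologyError(
                    f"angle ({a.i},{a.j},{a.k_idx}) out of range (n={n})")
        for d in self.dihedrals:
            if not all(0 <= x < n for x in (d.i, d.j, d.k_idx, d.l)):
                raise TopologyError(
                    f"dihedral ({d.i},{d.j},{d.k_idx},{d.l}) out of range")
            if d.funct not in (1, 2):
                raise TopologyError(f"unsupported dihedral funct {d.funct}")
        for at in self.atoms:
            if at.type not in self.atomtypes:
                raise TopologyError(f"atom type {at.type!r} undeclared")
        for t in self.atomtypes.values():
            if t.epsilon < 0 or t.sigma <= 0:
                raise TopologyError(
                    f"atomtype {t.name!r}: require sigma > 0, epsilon >= 0")
        if self.declared_charge is not None:
            if abs(self.total_charge - self.declared_charge) > 1e-6:
                raise TopologyError(
                    f"total charge {self.total_charge:.8f} deviates from the "
                    f"declared charge {self.declared_charge:.8f}")

    def copy(self) -> "Topology":
        import copy as _copy
        return _copy.deepcopy(self)

    def bond_index(self) -> dict[tuple[int, int], int]:
        return {b.key(): pos for pos, b in enumerate(self.bonds)}

    def angle_index(self) -> dict[tuple[int, int, int], int]:
        return {a.key(): pos for pos, a in enumerate(self.angles)}


_SUPPORTED = {
    "defaults", "atomtypes", "moleculetype", "atoms", "bonds", "angles",
    "dihedrals", "pairs", "exclusions", "system", "molecules",
}


def _collect_lines(path: str):
    """Yield (filename, lineno, stripped line) resolving #include
    directives relative to the parent file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#include"):
                target = line[len("#include"):].strip().strip('"').strip("'")
                sub = os.path.join(os.path.dirname(os.path.abspath(path)), target)
                if not os.path.exists(sub):
                    raise ParseError(
                        f"{path}:{lineno}: included file not found: {target}")
                yield from _collect_lines(sub)
                continue
            if line.startswith("#"):
                raise TopologyError(
                    f"{path}:{lineno}: unsupported preprocessor directive "
                    f"{line.split()[0]!r}")
            yield path, lineno, line


def read_topology(path: str) -> Topology:
    """Parse a GROMACS .top/.itp file (flat or with nested includes)."""
    top = Topology()
    top.atomtypes = {}
    section = None
    for fname, lineno, line in _collect_lines(path):
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            if section not in _SUPPORTED:
                raise TopologyError(
                    f"{fname}:{lineno}: unsupported directive [ {section} ]")
            continue
        if section is None:
            raise ParseError(f"{fname}:{lineno}: data before any [ section ]")
        tok = line.split()
        try:
            _parse_line(top, section, tok)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{fname}:{lineno}: malformed [ {section} ] "
                             f"record: {line!r} ({exc})") from exc
    top.validate()
    return top


def _parse_line(top: Topology, section: str, tok: list[str]) -> None:
    if section == "defaults":
        top.defaults = (int(tok[0]), int(tok[1]), tok[2],
                        float(tok[3]), float(tok[4]))
    elif section == "atomtypes":
        # name at.num mass charge ptype sigma epsilon
        t = AtomType(name=tok[0], atnum=int(tok[1]), mass=float(tok[2]),
                     charge=float(tok[3]), ptype=tok[4],
                     sigma=float(tok[5]), epsilon=float(tok[6]))
        top.atomtypes[t.name] = t
    elif section == "moleculetype":
        top.molecule_name = tok[0]
        top.nrexcl = int(tok[1])
    elif section == "atoms":
        # nr type resnr residue atom cgnr charge mass
        top.atoms.append(TopologyAtom(
            type=tok[1], resnr=int(tok[2]), resname=tok[3], name=tok[4],
            cgnr=int(tok[5]), charge=float(tok[6]), mass=float(tok[7])))
    elif section == "bonds":
        i, j, funct = int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2])
        if funct != 1:
            raise TopologyError(f"unsupported bond funct {funct}")
        top.bonds.append(BondTerm(i=i, j=j, r_eq=float(tok[3]) * 10.0,
                                  k=float(tok[4]) / 100.0))
    elif section == "angles":
        i, j, k, funct = (int(tok[0]) - 1, int(tok[1]) - 1,
                          int(tok[2]) - 1, int(tok[3]))
        if funct != 1:
            raise TopologyError(f"unsupported angle funct {funct}")
        top.angles.append(AngleTerm(i=i, j=j, k_idx=k,
                                    theta_eq=float(tok[4]), k=float(tok[5])))
    elif section == "dihedrals":
        idx = [int(t) - 1 for t in tok[:4]]
        funct = int(tok[4])
        if funct == 1:
            params = (float(tok[5]), float(tok[6]), int(tok[7]))
        elif funct == 2:
            params = (float(tok[5]), float(tok[6]))
        else:
            raise TopologyError(f"unsupported dihedral funct {funct}")
        top.dihedrals.append(DihedralTerm(*idx, funct=funct, params=params))
    elif section == "pairs":
        top.pairs.append((int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2])))
    elif section == "exclusions":
        owner = int(tok[0]) - 1
        top.exclusions.setdefault(owner, [])
        top.exclusions[owner].extend(int(t) - 1 for t in tok[1:])
    elif section == "system":
        top.system_name = " ".join(tok)
    elif section == "molecules":
        pass  # single-moleculetype dialect; count carried implicitly


def _g(x: float) -> str:
    """Full-precision float formatting (round-trips float64 exactly)."""
    return format(float(x), ".17g")


def write_topology(topology: Topology, path: str) -> None:
    topology.validate()
    lines: list[str] = []
    lines.append("[ defaults ]")
    lines.append("; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ")
    d = topology.defaults
    lines.append(f"{d[0]} {d[1]} {d[2]} {_g(d[3])} {_g(d[4])}")
    lines.append("")
    lines.append("[ atomtypes ]")
    lines.append("; name at.num mass charge ptype sigma epsilon")
    for name in sorted(topology.atomtypes):
        t = topology.atomtypes[name]
        lines.append(f"{t.name} {t.atnum} {_g(t.mass)} {_g(t.charge)} "
                     f"{t.ptype} {_g(t.sigma)} {_g(t.epsilon)}")
    lines.append("")
    lines.append("[ moleculetype ]")
    lines.append("; name nrexcl")
    lines.append(f"{topology.molecule_name} {topology.nrexcl}")
    lines.append("")
    lines.append("[ atoms ]")
    lines.append("; nr type resnr residue atom cgnr charge mass")
    for n, a in enumerate(topology.atoms, start=1):
        lines.append(f"{n} {a.type} {a.resnr} {a.resname} {a.name} "
                     f"{a.cgnr} {_g(a.charge)} {_g(a.mass)}")
    if topology.bonds:
        lines.append("")
        lines.append("[ bonds ]")
        lines.append("; i j funct r(nm) k(kJ/mol/nm2)")
        for b in topology.bonds:
            lines.append(f"{b.i + 1} {b.j + 1} {b.funct} "
                         f"{_g(b.r_eq / 10.0)} {_g(b.k * 100.0)}")
    if topology.angles:
        lines.append("")
        lines.append("[ angles ]")
        lines.append("; i j k funct theta(deg) k(kJ/mol/rad2)")
        for a in topology.angles:
            lines.append(f"{a.i + 1} {a.j + 1} {a.k_idx + 1} {a.funct} "
                         f"{_g(a.theta_eq)} {_g(a.k)}")
    if topology.dihedrals:
        lines.append("")
        lines.append("[ dihedrals ]")
        lines.append("; i j k l funct params (funct 1 proper, funct 2 improper)")
        for dh in topology.dihedrals:
            idx = f"{dh.i + 1} {dh.j + 1} {dh.k_idx + 1} {dh.l + 1}"
            if dh.funct == 1:
                p = f"{_g(dh.params[0])} {_g(dh.params[1])} {int(dh.params[2])}"
            else:
                p = f"{_g(dh.params[0])} {_g(dh.params[1])}"
            lines.append(f"{idx} {dh.funct} {p}")
    if topology.pairs:
        lines.append("")
        lines.append("[ pairs ]")
        for i, j, funct in topology.pairs:
            lines.append(f"{i + 1} {j + 1} {funct}")
    if topology.exclusions:
        lines.append("")
        lines.append("[ exclusions ]")
        for owner in sorted(topology.exclusions):
            partners = sorted(set(topology.exclusions[owner]))
            lines.append(" ".join(str(x + 1) for x in [owner] + partners))
    lines.append("")
    lines.append("[ system ]")
    lines.append(topology.system_name)
    lines.append("")
    lines.append("[ molecules ]")
    lines.append(f"{topology.molecule_name} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
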