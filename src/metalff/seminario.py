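"""Harmonic force constants from a Cartesian Hessian (modified Seminario),
graph-based symmetrization, and improper-dihedral fitting from 1D scans.

For a bonded pair (i, j) the 3x3 interatomic sub-block of the Hessian,
A = -H_ij, is eigen-decomposed and the force constant is the sum of the
eigenvalues projected on the bond direction,

    k_b = sum_m  lambda_m |u_ij . v_m| ,

averaged over the ij and ji blocks.  For an angle A-B-C each bond
contributes a partial constant k_AB = R_AB^2 * sum_m lambda_m |u_PA . v_m|
with u_PA the in-plane perpendicular to the bond, and

    1/k_theta = 1/k_AB + 1/k_CB .

The series combination needs each arm's projection to carry twice the
bending constant.  Measured on harmonic test systems, that factor of two
is supplied either by the eigenvector mixing of the stretch and bending
subspaces (single angles) or by a coplanar partner angle sharing the bond
(cis coordination angles), so the unscaled series is exact for right
coordination angles -- the geometry of square-planar and octahedral metal
sites -- and overestimates non-orthogonal organic angles by up to
~(1 + |cos theta_eq|); see the methods note.  ``angle_params`` accepts
per-arm divisors for callers who want to rescale shared-bond
contributions, but the template builder leaves them at 1.

Units: Hessian kJ mol-1 A-2, lengths A, angles deg, k_theta kJ mol-1 rad-2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    ATOMIC_MASSES,
    MetalFFError,
    ParseError,
    Structure,
    molecular_graph,
)
from .topology import (
    AngleTerm,
    AtomType,
    BondTerm,
    DihedralTerm,
    Topology,
    TopologyAtom,
)

__all__ = [
    "HessianData", "ScanData", "ImproperFit",
    "read_hessian", "write_hessian", "read_scan",
    "bond_params", "angle_params", "symmetrize", "fit_improper",
    "build_template_bonded", "SQUARE_PLANAR_DEFAULTS",
]

HARTREE_KJMOL = 2625.4996394798254
BOHR_A = 0.52917721092

# metals whose complexes are square-planar often enough that donor-centered
# improper dihedrals are parameterized by default
SQUARE_PLANAR_DEFAULTS = {("Rh", 1), ("Ir", 1), ("Pd", 2), ("Pt", 2),
                          ("Au", 3)}


@dataclass
class HessianData:
    """Mass-unweighted Cartesian Hessian plus the geometry it belongs to."""

    matrix: np.ndarray        # (3N, 3N), kJ mol-1 A-2
    geometry: Structure

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.geometry)
        if self.matrix.shape != (3 * n, 3 * n):
            raise MetalFFError(
                f"Hessian shape {self.matrix.shape} does not match "
                f"{n} atoms")
        scale = max(1.0, float(np.abs(self.matrix).max()))
        if np.abs(self.matrix - self.matrix.T).max() > 1e-6 * scale:
            raise MetalFFError("Hessian is not symmetric (relative 1e-6)")

    def block(self, i: int, j: int) -> np.ndarray:
        return self.matrix[3 * i:3 * i + 3, 3 * j:3 * j + 3]


@dataclass
class ScanData:
    """1D improper-dihedral scan: angles (deg) and energies (kJ/mol)."""

    angles: np.ndarray
    energies: np.ndarray
    quadruple: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.shape != self.energies.shape:
            raise MetalFFError("scan angles/energies length mismatch")
        if len(self.angles) < 5:
            raise MetalFFError("scan needs at least 5 points")
        if not np.all(np.isfinite(self.energies)):
            raise MetalFFError("scan energies must be finite")


@dataclass
class ImproperFit:
    xi_eq: float              # deg
    k: float                  # kJ mol-1 rad-2 (E = k (xi - xi_eq)^2 + E0)
    e0: float
    residual_rms: float
    stderr_k: float
    stderr_xi: float


# ---------------------------------------------------------------- file I/O

def write_hessian(hessian: HessianData, path: str) -> None:
    n = len(hessian.geometry)
    lines = ["# metalff hessian",
             "# units: kJ/mol/angstrom^2",
             f"# natoms: {n}"]
    for atom in hessian.geometry.atoms:
        x, y, z = atom.position
        lines.append(f"# atom {atom.element} {x:.17g} {y:.17g} {z:.17g}")
    for row in hessian.matrix:
        lines.append(" ".join(f"{v:.17g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hessian(path: str, geometry: Structure | None = None) -> HessianData:
    """Read the plain-text Hessian format (kJ/mol/A^2 with an embedded
    geometry) or an ORCA .hess file (Hartree/bohr^2; geometry taken from
    the $atoms block or supplied by the caller)."""
    with open(path) as fh:
        text = fh.read()
    if "$hessian" in text:
        return _read_orca_hess(text, path, geometry)
    lines = text.splitlines()
    atoms = []
    rows = []
    natoms = None
    from .core import Atom
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("# natoms:"):
            natoms = int(line.split(":")[1])
        elif line.startswith("# atom "):
            tok = line.split()
            atoms.append(Atom(index=len(atoms), element=tok[2],
                              position=[float(t) for t in tok[3:6]]))
        elif line.startswith("#") or not line.strip():
            continue
        else:
            try:
                rows.append([float(t) for t in line.split()])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad Hessian row "
                                 f"({exc})") from exc
    if geometry is None:
        if not atoms:
            raise ParseError(f"{path}: no geometry in header and none given")
        geometry = Structure(atoms)
    if natoms is not None and natoms != len(geometry):
        raise ParseError(f"{path}: natoms header {natoms} != geometry "
                         f"{len(geometry)}")
    return HessianData(matrix=np.array(rows, dtype=float), geometry=geometry)


def _read_orca_hess(text: str, path: str,
                    geometry: Structure | None) -> HessianData:
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip() == "$hessian")
    except StopIteration:  # pragma: no cover - guarded by caller
        raise ParseError(f"{path}: no $hessian block")
    dim = int(lines[start + 1])
    mat = np.zeros((dim, dim))
    i = start + 2
    while i < len(lines):
        header = lines[i].split()
        if not header or lines[i].lstrip().startswith("$"):
            break
        cols = [int(c) for c in header]
        for r in range(dim):
            tok = lines[i + 1 + r].split()
            for c, v in zip(cols, tok[1:]):
                mat[r, c] = float(v)
        i += 1 + dim
    mat *= HARTREE_KJMOL / BOHR_A ** 2
    if geometry is None:
        geometry = _read_orca_atoms(lines, path)
    return HessianData(matrix=mat, geometry=geometry)


def _read_orca_atoms(lines: list[str], path: str) -> Structure:
    from .core import Atom
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip() == "$atoms")
    except StopIteration:
        raise ParseError(f"{path}: ORCA .hess lacks $atoms; supply geometry")
    n = int(lines[start + 1])
    atoms = []
    for k in range(n):
        tok = lines[start + 2 + k].split()
        pos = np.array([float(t) for t in tok[2:5]]) * BOHR_A
        atoms.append(Atom(index=k, element=tok[0], position=pos))
    return Structure(atoms)


def read_scan(path: str) -> ScanData:
    """Two-column text scan: angle (deg), energy (kJ/mol)."""
    angles, energies = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            try:
                angles.append(float(tok[0]))
                energies.append(float(tok[1]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: bad scan row") from exc
    return ScanData(angles=np.array(angles), energies=np.array(energies))


# ------------------------------------------------------------ force constants

def _block_eigen(hessian: HessianData, i: int, j: int):
    """Eigenpairs of -H_ij and -H_ji (descending eigenvalues, normalized
    real eigenvectors)."""
    out = []
    for block in (-hessian.block(i, j), -hessian.block(j, i)):
        w, v = np.linalg.eig(block)
        w = np.real(w)
        v = np.real(v)
        order = np.argsort(w)[::-1]
        w = w[order]
        v = v[:, order]
        norms = np.linalg.norm(v, axis=0)
        norms[norms == 0] = 1.0
        out.append((w, v / norms))
    return out


def _projected_sum(w: np.ndarray, v: np.ndarray, u: np.ndarray) -> float:
    return float(np.sum(w * np.abs(u @ v)))


def bond_params(hessian: HessianData, i: int, j: int
                ) -> tuple[float, float]:
    """Equilibrium length (A) and force constant (kJ mol-1 A-2, for
    V = 1/2 k (r - r_eq)^2) of the i-j bond."""
    if i == j:
        raise ValueError("bond requires two distinct atoms")
    pos = hessian.geometry.positions
    rij = pos[j] - pos[i]
    r_eq = float(np.linalg.norm(rij))
    u = rij / r_eq
    eigens = _block_eigen(hessian, i, j)
    if max(w.max() for w, _ in eigens) <= 0:
        raise MetalFFError(
            f"pair ({i}, {j}): interatomic Hessian block has no positive "
            "eigenvalue; the atoms do not interact like a bond")
    k = float(np.mean([_projected_sum(w, v, u) for w, v in eigens]))
    return r_eq, k


def _angle_geometry(pos: np.ndarray, i: int, j: int, k: int):
    a = pos[i] - pos[j]
    c = pos[k] - pos[j]
    ra = np.linalg.norm(a)
    rc = np.linalg.norm(c)
    ua, uc = a / ra, c / rc
    cos_t = float(np.clip(np.dot(ua, uc), -1.0, 1.0))
    theta = math.degrees(math.acos(cos_t))
    un = np.cross(uc, ua)
    n = np.linalg.norm(un)
    if n < 1e-10:
        raise MetalFFError(f"angle ({i},{j},{k}) is collinear")
    un /= n
    u_pa = np.cross(un, ua)
    u_pa /= np.linalg.norm(u_pa)
    u_pc = np.cross(uc, un)
    u_pc /= np.linalg.norm(u_pc)
    return ra, rc, ua, uc, u_pa, u_pc, theta


def _outer_apex_eigen(hessian: HessianData, outer: int, apex: int):
    """Eigenpairs of -H_(outer,apex), the block the angle projection
    uses (descending eigenvalues, normalized real eigenvectors)."""
    block = -hessian.block(outer, apex)
    w, v = np.linalg.eig(block)
    w = np.real(w)
    v = np.real(v)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    norms = np.linalg.norm(v, axis=0)
    norms[norms == 0] = 1.0
    return w, v / norms


def angle_params(hessian: HessianData, i: int, j: int, k: int,
                 scale_a: float = 1.0, scale_c: float = 1.0
                 ) -> tuple[float, float]:
    """Equilibrium angle (deg) and force constant (kJ mol-1 rad-2, for
    V = 1/2 k (theta - theta_eq)^2) of the i-j-k angle (apex j).

    Each arm contributes through the (outer atom, apex) Hessian block
    projected on the in-plane perpendicular of that arm; the two arms
    combine in series.  The projection is exact for right angles in the
    stiff-bond limit and acquires a positive bias that grows with
    |cos theta_eq| (see the methods note).  ``scale_a``/``scale_c`` are
    the modified-Seminario divisors (1 when the arm's bond supports no
    other angle at this apex)."""
    pos = hessian.geometry.positions
    ra, rc, ua, uc, u_pa, u_pc, theta = _angle_geometry(pos, i, j, k)
    if abs(theta - 180.0) < 1.0:
        raise MetalFFError(
            f"angle ({i},{j},{k}) within 1 deg of linear ({theta:.2f})")
    w_a, v_a = _outer_apex_eigen(hessian, i, j)
    k_ab = ra ** 2 * _projected_sum(w_a, v_a, u_pa) / scale_a
    w_c, v_c = _outer_apex_eigen(hessian, k, j)
    k_cb = rc ** 2 * _projected_sum(w_c, v_c, u_pc) / scale_c
    if k_ab <= 0 or k_cb <= 0:
        raise MetalFFError(f"angle ({i},{j},{k}): nonpositive bond "
                           "contribution")
    k_theta = 1.0 / (1.0 / k_ab + 1.0 / k_cb)
    return theta, float(k_theta)


# ------------------------------------------------------------ symmetrization

def _wl_colors(structure: Structure, rounds: int | None = None
               ) -> list[int]:
    """Weisfeiler-Lehman node colors: automorphism-invariant environment
    classes refined from element labels to a fixed point."""
    n = len(structure)
    nbrs = [structure.neighbors(i) for i in range(n)]
    labels = sorted({a.element for a in structure.atoms})
    colors = [labels.index(a.element) for a in structure.atoms]
    if rounds is None:
        rounds = n
    for _ in range(rounds):
        keys = [(colors[i], tuple(sorted(colors[j] for j in nbrs[i])))
                for i in range(n)]
        uniq = sorted(set(keys))
        new = [uniq.index(k) for k in keys]
        if new == colors:
            break
        colors = new
    return colors


def symmetrize(params: Topology, structure: Structure) -> Topology:
    """Average (k, eq) over classes of bonds/angles/impropers whose atom
    environments are graph-equivalent.  Idempotent."""
    colors = _wl_colors(structure)
    out = params.copy()

    groups: dict[tuple, list[BondTerm]] = {}
    for b in out.bonds:
        key = tuple(sorted((colors[b.i], colors[b.j])))
        groups.setdefault(key, []).append(b)
    for terms in groups.values():
        r = float(np.mean([t.r_eq for t in terms]))
        kk = float(np.mean([t.k for t in terms]))
        for t in terms:
            t.r_eq, t.k = r, kk

    agroups: dict[tuple, list[AngleTerm]] = {}
    for a in out.angles:
        key = (colors[a.j], tuple(sorted((colors[a.i], colors[a.k_idx]))))
        agroups.setdefault(key, []).append(a)
    for terms in agroups.values():
        th = float(np.mean([t.theta_eq for t in terms]))
        kk = float(np.mean([t.k for t in terms]))
        for t in terms:
            t.theta_eq, t.k = th, kk

    igroups: dict[tuple, list[DihedralTerm]] = {}
    for d in out.dihedrals:
        if d.funct != 2:
            continue
        key = (colors[d.i], colors[d.j],
               tuple(sorted((colors[d.k_idx], colors[d.l]))))
        igroups.setdefault(key, []).append(d)
    for terms in igroups.values():
        xi = float(np.mean([t.params[0] for t in terms]))
        kk = float(np.mean([t.params[1] for t in terms]))
        for t in terms:
            t.params = (xi, kk)
    return out


# ------------------------------------------------------------ improper fit

def fit_improper(scan: ScanData) -> ImproperFit:
    """Least-squares fit of E(xi) = k (xi - xi_eq)^2 + E0 to a 1D scan.
    xi in degrees on input, k in kJ mol-1 rad-2."""
    x = np.radians(scan.angles)
    y = scan.energies
    coeffs, cov = np.polyfit(x, y, 2, cov=True)
    a, b, c = (float(v) for v in coeffs)
    span = float(x.max() - x.min())
    scale = max(float(np.ptp(y)), 1e-300)
    if a <= 0 or a * span ** 2 < 1e-8 * scale:
        raise MetalFFError(
            f"improper scan is not convex (quadratic coefficient "
            f"{a:.3g} kJ/mol/rad^2)")
    xi_eq = -b / (2 * a)
    e0 = c - b ** 2 / (4 * a)
    resid = y - np.polyval(coeffs, x)
    var_a = float(cov[0, 0])
    var_b = float(cov[1, 1])
    cov_ab = float(cov[0, 1])
    # delta method for xi_eq = -b/(2a)
    d_da = b / (2 * a ** 2)
    d_db = -1.0 / (2 * a)
    var_xi = (d_da ** 2 * var_a + d_db ** 2 * var_b
              + 2 * d_da * d_db * cov_ab)
    return ImproperFit(
        xi_eq=math.degrees(xi_eq),
        k=a,
        e0=e0,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        stderr_k=math.sqrt(max(var_a, 0.0)),
        stderr_xi=math.degrees(math.sqrt(max(var_xi, 0.0))),
    )


# ------------------------------------------------ template bonded assembly

def _near_metal_atoms(structure: Structure, metal_index: int) -> set[int]:
    near = {metal_index}
    near.update(structure.neighbors(metal_index))
    return near


def build_template_bonded(hessian: HessianData, metal_index: int,
                          formal_charge: int,
                          improper_flag: bool = False,
                          improper_scan: ScanData | None = None) -> Topology:
    """Bond and angle terms for all bonded pairs/triples of the template
    involving the metal or an atom bonded to it, from the Hessian by the
    modified Seminario method; donor-centered improper dihedrals when
    requested or when the metal defaults to square-planar.  Proper
    dihedrals through the metal are never parameterized."""
    structure = hessian.geometry
    metal = structure.atoms[metal_index]
    near = _near_metal_atoms(structure, metal_index)

    top = Topology()
    for atom in structure.atoms:
        tname = f"T{atom.element}"
        if tname not in top.atomtypes:
            top.atomtypes[tname] = AtomType(
                name=tname, atnum=0,
                mass=ATOMIC_MASSES.get(atom.element, 0.0),
                charge=0.0, sigma=0.3, epsilon=0.0)
        top.atoms.append(TopologyAtom(
            name=atom.name, type=tname, charge=atom.partial_charge,
            mass=ATOMIC_MASSES.get(atom.element, 0.0)))

    bond_list = sorted(structure.bonds)
    for (i, j) in bond_list:
        if i in near or j in near:
            r_eq, k = bond_params(hessian, i, j)
            top.bonds.append(BondTerm(i=i, j=j, r_eq=r_eq, k=k))

    angle_triples = []
    for j in range(len(structure)):
        nbrs = structure.neighbors(j)
        for ai in range(len(nbrs)):
            for ci in range(ai + 1, len(nbrs)):
                i, k = nbrs[ai], nbrs[ci]
                if i in near or j in near or k in near:
                    angle_triples.append((i, j, k))
    pos = structure.positions
    for (i, j, k) in angle_triples:
        try:
            theta, kt = angle_params(hessian, i, j, k)
        except MetalFFError as exc:
            warnings.warn(f"skipping angle ({i},{j},{k}): {exc}")
            continue
        top.angles.append(AngleTerm(i=i, j=j, k_idx=k, theta_eq=theta, k=kt))

    want_impropers = improper_flag or (
        (metal.element, int(formal_charge)) in SQUARE_PLANAR_DEFAULTS)
    if want_impropers:
        if improper_scan is None:
            raise MetalFFError(
                "improper dihedrals requested (flag or square-planar default "
                f"for {metal.element}{formal_charge:+d}) but no 1D scan was "
                "supplied")
        fit = fit_improper(improper_scan)
        donors = [j for j in structure.neighbors(metal_index)
                  if not structure.atoms[j].is_metal]
        for d in donors:
            others = [x for x in donors if x != d]
            # the two donors closest to cis (smallest d-M-x angles)
            def cis_angle(x):
                va = pos[d] - pos[metal_index]
                vb = pos[x] - pos[metal_index]
                cos_t = np.dot(va, vb) / (
                    np.linalg.norm(va) * np.linalg.norm(vb))
                return math.degrees(math.acos(np.clip(cos_t, -1, 1)))
            others.sort(key=lambda x: (cis_angle(x), x))
            if len(others) < 2:
                continue
            a, b = sorted(others[:2])
            # GROMACS funct 2 is V = 1/2 k (xi - xi0)^2; the fit is
            # E = k (xi - xi0)^2, so the emitted constant is doubled
            top.dihedrals.append(DihedralTerm(
                i=d, j=metal_index, k_idx=a, l=b, funct=2,
                params=(fit.xi_eq, 2.0 * fit.k)))
    top.molecule_name = "TEMPLATE"
    return top
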