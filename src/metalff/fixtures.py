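"""Synthetic fixtures: idealized metal sites, toy harmonic force fields
with analytic/finite-difference Hessians, point-charge ESP grids, and
scrambled conformers with known ground truth.

Geometries are idealized (exact 90/180 degree coordination angles, planar
rings) so that symmetry-based assertions are exact.  Every generator is
deterministic under its explicit seeds and reads nothing from disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    ATOMIC_MASSES,
    Atom,
    BOHR_TO_ANGSTROM,
    MetalFFError,
    Structure,
    vdw_radius,
)
from .resp import ESPGrid
from .seminario import HessianData, ScanData
from .sites import saturate, ligand_components
from .topology import AtomType, BondTerm, AngleTerm, Topology, TopologyAtom

__all__ = [
    "make_square_planar_site", "make_octahedral_site", "make_pd2l4_cage",
    "toy_ff_hessian", "point_charge_esp", "scramble", "make_improper_scan",
    "toy_topology", "FixtureAssets", "build_fixture_template",
    "default_bond_constant", "default_angle_constant",
]

RING_SIDE = 1.39          # A, aromatic C-C/C-N
METAL_DONOR = 2.0         # A


def _finish_structure(structure: Structure) -> Structure:
    """Saturate a heavy-atom skeleton and promote the added hydrogens to
    ordinary atoms."""
    out = saturate(structure)
    for a in out.atoms:
        a.is_added_h = False
        a.name = f"{a.element}{a.index + 1}"
    return out


def _ring_atoms(n_ring: int, donor: str, axis: np.ndarray,
                perp: np.ndarray, metal_pos: np.ndarray,
                start: int) -> tuple[list[Atom], list[tuple[int, int]]]:
    """Regular n-gon ring with the donor at the vertex nearest the metal,
    in the plane spanned by ``axis`` and ``perp``."""
    circum = RING_SIDE / (2.0 * math.sin(math.pi / n_ring))
    center = metal_pos + (METAL_DONOR + circum) * axis
    atoms = []
    bonds = []
    for k in range(n_ring):
        theta = math.pi + 2.0 * math.pi * k / n_ring
        pos = center + circum * (math.cos(theta) * axis
                                 + math.sin(theta) * perp)
        el = donor if k == 0 else "C"
        atoms.append(Atom(index=start + k, element=el, position=pos))
        bonds.append((start + k, start + (k + 1) % n_ring))
    return atoms, bonds


def make_square_planar_site(metal: str = "Pd", charge: int = 2,
                            donor: str = "N", n_ring_atoms: int = 6,
                            seed: int = 0
                            ) -> tuple[Structure, Topology]:
    """Metal at the origin with four planar aromatic donor rings at 2.0 A
    along +-x and +-y (ring planes contain the z axis), emulating a
    tetrakis(pyridine) building block.  Returns the structure and a toy
    metal-free force-field topology."""
    z = np.array([0.0, 0.0, 1.0])
    atoms = [Atom(index=0, element=metal, position=np.zeros(3))]
    bonds: list[tuple[int, int]] = []
    for axis in ([1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]):
        axis = np.array(axis, dtype=float)
        start = len(atoms)
        ring, ring_bonds = _ring_atoms(n_ring_atoms, donor, axis, z,
                                       np.zeros(3), start)
        atoms.extend(ring)
        bonds.extend(ring_bonds)
        bonds.append((0, start))          # metal-donor bond
    s = Structure(atoms, bonds, formal_charge=charge)
    s = _finish_structure(s)
    s.formal_charge = charge
    top = toy_topology(s, metal_charges={0: charge}, seed=seed)
    return s, top


def make_octahedral_site(metal: str = "Fe", charge: int = 2,
                         bidentate: int = 3, seed: int = 0
                         ) -> tuple[Structure, Topology]:
    """Octahedral metal with ``bidentate`` ethylenediamine-like chelates
    (N-C-C-N), donors at 2.1 A on cis axis pairs."""
    if not 1 <= bidentate <= 3:
        raise ValueError("bidentate must be 1..3")
    axis_pairs = [
        (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
        (np.array([0, 0, 1.0]), np.array([-1.0, 0, 0])),
        (np.array([0, -1.0, 0]), np.array([0, 0, -1.0])),
    ][:bidentate]
    p, q, r = 2.432, 1.410, 0.25   # chelate carbon coordinates (A)
    mn = 2.1
    atoms = [Atom(index=0, element=metal, position=np.zeros(3))]
    bonds: list[tuple[int, int]] = []
    for a_ax, b_ax in axis_pairs:
        c_ax = np.cross(a_ax, b_ax)
        i0 = len(atoms)
        atoms.append(Atom(index=i0, element="N", position=mn * a_ax))
        atoms.append(Atom(index=i0 + 1, element="C",
                          position=p * a_ax + q * b_ax + r * c_ax))
        atoms.append(Atom(index=i0 + 2, element="C",
                          position=q * a_ax + p * b_ax - r * c_ax))
        atoms.append(Atom(index=i0 + 3, element="N", position=mn * b_ax))
        bonds += [(0, i0), (i0, i0 + 1), (i0 + 1, i0 + 2),
                  (i0 + 2, i0 + 3), (0, i0 + 3)]
    s = Structure(atoms, bonds, formal_charge=charge)
    s = _finish_structure(s)
    s.formal_charge = charge
    top = toy_topology(s, metal_charges={0: charge}, seed=seed)
    return s, top


def make_pd2l4_cage(seed: int = 0, pd_separation: float = 5.0
                    ) -> tuple[Structure, Topology]:
    """A lantern-type dimetallic cage: two Pd(2+) centers bridged by four
    ditopic bis(pyridine) ligands (two pyridines joined through their para
    carbons), each metal square-planar with four N donors."""
    z = np.array([0.0, 0.0, 1.0])
    atoms = [Atom(index=0, element="Pd", position=np.zeros(3)),
             Atom(index=1, element="Pd",
                  position=np.array([0.0, 0.0, pd_separation]))]
    bonds: list[tuple[int, int]] = []
    for axis in ([1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]):
        axis = np.array(axis, dtype=float)
        s0 = len(atoms)
        ring_a, bonds_a = _ring_atoms(6, "N", axis, z, np.zeros(3), s0)
        atoms.extend(ring_a)
        bonds.extend(bonds_a)
        bonds.append((0, s0))
        s1 = len(atoms)
        ring_b, bonds_b = _ring_atoms(6, "N", axis, -z,
                                      np.array([0.0, 0.0, pd_separation]), s1)
        atoms.extend(ring_b)
        bonds.extend(bonds_b)
        bonds.append((1, s1))
        bonds.append((s0 + 3, s1 + 3))    # para-para inter-ring bond
    s = Structure(atoms, bonds, formal_charge=4)
    s = _finish_structure(s)
    s.formal_charge = 4
    top = toy_topology(s, metal_charges={0: 2, 1: 2}, seed=seed)
    return s, top


# ------------------------------------------------------------ toy topology

def default_bond_constant(el_a: str, el_b: str) -> float:
    """Toy harmonic bond constants, kJ mol-1 A-2 (V = 1/2 k dx^2)."""
    pair = frozenset((el_a, el_b))
    if "H" in pair:
        return 1500.0
    for el in pair:
        if el not in ("C", "N", "O", "S", "H"):
            return 400.0          # metal-donor coordination bond
    return 2200.0


def default_angle_constant(*_els: str) -> float:
    """Toy harmonic angle constant, kJ mol-1 rad-2."""
    return 300.0


def toy_topology(structure: Structure, metal_charges: dict[int, int],
                 seed: int = 0) -> Topology:
    """A metal-free toy force field for a fixture structure: harmonic
    bonds/angles among non-metal atoms at the fixture geometry, small
    deterministic ligand charges summing to zero per ligand, metal atoms
    carried as charge-only particles at their formal charge."""
    rng = np.random.default_rng(seed)
    top = Topology()
    pos = structure.positions
    for atom in structure.atoms:
        tname = f"F{atom.element}"
        if tname not in top.atomtypes:
            top.atomtypes[tname] = AtomType(
                name=tname, atnum=0,
                mass=ATOMIC_MASSES.get(atom.element, 1.0),
                charge=0.0, sigma=0.30, epsilon=0.40)
        top.atoms.append(TopologyAtom(
            name=atom.name, type=tname, charge=0.0,
            mass=ATOMIC_MASSES.get(atom.element, 1.0)))
    for m, q in metal_charges.items():
        top.atoms[m].charge = float(q)
    for comp in ligand_components(structure):
        raw = rng.normal(0.0, 0.05, size=len(comp))
        raw -= raw.mean()
        for i, qv in zip(comp, raw):
            top.atoms[i].charge = float(qv)
    metals = {i for i, a in enumerate(structure.atoms) if a.is_metal}
    for (i, j) in sorted(structure.bonds):
        if i in metals or j in metals:
            continue
        r = float(np.linalg.norm(pos[i] - pos[j]))
        k = default_bond_constant(structure.atoms[i].element,
                                  structure.atoms[j].element)
        top.bonds.append(BondTerm(i=i, j=j, r_eq=r, k=k))
    for j in range(len(structure)):
        if j in metals:
            continue
        nbrs = [n for n in structure.neighbors(j) if n not in metals]
        for ai in range(len(nbrs)):
            for ci in range(ai + 1, len(nbrs)):
                i, k = nbrs[ai], nbrs[ci]
                va = pos[i] - pos[j]
                vc = pos[k] - pos[j]
                cos_t = float(np.clip(
                    np.dot(va, vc)
                    / (np.linalg.norm(va) * np.linalg.norm(vc)), -1, 1))
                top.angles.append(AngleTerm(
                    i=i, j=j, k_idx=k,
                    theta_eq=math.degrees(math.acos(cos_t)),
                    k=default_angle_constant()))
    top.validate()
    return top


# ---------------------------------------------------------------- Hessians

def _toy_terms(structure: Structure, bond_constants, angle_constants):
    """Normalize constant specs into per-term dictionaries."""
    bonds = sorted(structure.bonds)
    if np.isscalar(bond_constants):
        bmap = {b: float(bond_constants) for b in bonds}
    else:
        bmap = {tuple(sorted(k)): float(v) for k, v in bond_constants.items()}
        if set(bmap) != set(bonds):
            raise MetalFFError(
                "bond constants do not match the structure's bond set")
    pos_all = structure.positions

    def _theta(i, j, k):
        va, vc = pos_all[i] - pos_all[j], pos_all[k] - pos_all[j]
        cos_t = float(np.clip(np.dot(va, vc) / (np.linalg.norm(va)
                                                * np.linalg.norm(vc)),
                              -1, 1))
        return math.degrees(math.acos(cos_t))

    angles = []
    for j in range(len(structure)):
        nbrs = structure.neighbors(j)
        for ai in range(len(nbrs)):
            for ci in range(ai + 1, len(nbrs)):
                angles.append((nbrs[ai], j, nbrs[ci]))
    if angle_constants is None:
        amap = {}
    elif np.isscalar(angle_constants):
        # harmonic bending is undefined on linear triples; force fields
        # leave them out, and so does the generator
        amap = {a: float(angle_constants) for a in angles
                if abs(_theta(*a) - 180.0) > 2.0}
    else:
        amap = {}
        for (i, j, k), v in angle_constants.items():
            key = (i, j, k) if (i, j, k) in angles else (k, j, i)
            if key not in angles:
                raise MetalFFError(f"angle ({i},{j},{k}) not in structure")
            if abs(_theta(*key) - 180.0) <= 2.0:
                raise MetalFFError(
                    f"angle ({i},{j},{k}) is collinear; a harmonic bending "
                    "term is undefined there")
            amap[key] = float(v)
    pos = structure.positions
    bterms = [(i, j, kk, float(np.linalg.norm(pos[i] - pos[j])))
              for (i, j), kk in sorted(bmap.items())]
    aterms = []
    for (i, j, k), kk in sorted(amap.items()):
        va, vc = pos[i] - pos[j], pos[k] - pos[j]
        cos_t = float(np.clip(np.dot(va, vc) / (np.linalg.norm(va)
                                                * np.linalg.norm(vc)), -1, 1))
        aterms.append((i, j, k, kk, math.acos(cos_t)))
    return bterms, aterms


def _toy_gradient(pos: np.ndarray, bterms, aterms) -> np.ndarray:
    g = np.zeros_like(pos)
    for i, j, k, r0 in bterms:
        d = pos[i] - pos[j]
        r = np.linalg.norm(d)
        f = k * (r - r0) / r
        g[i] += f * d
        g[j] -= f * d
    for i, j, k, kk, t0 in aterms:
        a = pos[i] - pos[j]
        c = pos[k] - pos[j]
        ra, rc = np.linalg.norm(a), np.linalg.norm(c)
        ua, uc = a / ra, c / rc
        cos_t = float(np.clip(np.dot(ua, uc), -1, 1))
        sin_t = math.sqrt(max(1.0 - cos_t ** 2, 1e-12))
        theta = math.acos(cos_t)
        dt_di = (cos_t * ua - uc) / (ra * sin_t)
        dt_dk = (cos_t * uc - ua) / (rc * sin_t)
        pref = kk * (theta - t0)
        g[i] += pref * dt_di
        g[k] += pref * dt_dk
        g[j] -= pref * (dt_di + dt_dk)
    return g


def toy_ff_hessian(structure: Structure, bond_constants,
                   angle_constants=None, mode: str = "fd",
                   step: float = 1e-4) -> HessianData:
    """Hessian of the toy force field V = sum 1/2 k_b (r - r0)^2 +
    sum 1/2 k_th (theta - theta0)^2 with equilibrium values at the input
    geometry.  ``analytic`` mode (bond-only systems) assembles the exact
    k u u^T blocks; ``fd`` central-differences the analytic gradient with
    the given step (A)."""
    bterms, aterms = _toy_terms(structure, bond_constants, angle_constants)
    n = len(structure)
    pos = structure.positions
    if mode == "analytic":
        if aterms:
            raise MetalFFError(
                "analytic mode supports bond-only toy force fields")
        h = np.zeros((3 * n, 3 * n))
        for i, j, k, r0 in bterms:
            d = pos[i] - pos[j]
            u = d / np.linalg.norm(d)
            blk = k * np.outer(u, u)
            h[3*i:3*i+3, 3*i:3*i+3] += blk
            h[3*j:3*j+3, 3*j:3*j+3] += blk
            h[3*i:3*i+3, 3*j:3*j+3] -= blk
            h[3*j:3*j+3, 3*i:3*i+3] -= blk
    elif mode == "fd":
        h = np.zeros((3 * n, 3 * n))
        flat = pos.copy()
        for d in range(3 * n):
            plus = flat.copy()
            plus[d // 3, d % 3] += step
            minus = flat.copy()
            minus[d // 3, d % 3] -= step
            gp = _toy_gradient(plus, bterms, aterms).ravel()
            gm = _toy_gradient(minus, bterms, aterms).ravel()
            h[:, d] = (gp - gm) / (2.0 * step)
        h = 0.5 * (h + h.T)
    else:
        raise ValueError("mode must be 'analytic' or 'fd'")
    return HessianData(matrix=h, geometry=structure.copy())


# ---------------------------------------------------------------- ESP grids

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def point_charge_esp(structure: Structure, charges,
                     shells=(1.4, 1.6, 1.8, 2.0), density: float = 1.0,
                     seed: int = 0) -> ESPGrid:
    """Connolly-style ESP grid around the structure, with potentials from
    the given point charges (exact Coulomb sums).  Shell radii are the
    scale factors times the van der Waals radius; about ``density`` points
    per square Angstrom survive the exclusion test.  Atomic units."""
    charges = np.asarray(charges, dtype=float)
    if len(charges) != len(structure):
        raise MetalFFError("one charge per atom required")
    total = float(np.sum(charges))
    if abs(total - round(total)) > 1e-6:
        raise MetalFFError(f"charges sum to non-integer {total}")
    rng = np.random.default_rng(seed)
    pos = structure.positions
    radii = np.array([vdw_radius(a.element) for a in structure.atoms])
    pts = []
    for scale in shells:
        rot = Rotation.random(rng=rng).as_matrix()
        for a in range(len(structure)):
            r = scale * radii[a]
            n = max(4, int(round(density * 4.0 * math.pi * r * r)))
            sphere = _fibonacci_sphere(n) @ rot.T
            cand = pos[a] + r * sphere
            d = np.linalg.norm(cand[:, None, :] - pos[None, :, :], axis=2)
            keep = np.all(d >= scale * radii[None, :] - 1e-9, axis=1)
            pts.append(cand[keep])
    points_a = np.vstack(pts)
    points = points_a / BOHR_TO_ANGSTROM
    nuclei = pos / BOHR_TO_ANGSTROM
    d = np.linalg.norm(points[:, None, :] - nuclei[None, :, :], axis=2)
    potentials = (1.0 / d) @ charges
    return ESPGrid(points=points, potentials=potentials, nuclei=nuclei,
                   elements=[a.element for a in structure.atoms],
                   total_charge=int(round(total)))


# ------------------------------------------------------------- scrambling

def scramble(structure: Structure, permute_seed: int = 0,
             rigid_seed: int = 0, noise_sigma: float = 0.0
             ) -> tuple[Structure, np.ndarray]:
    """Random atom-order permutation plus rigid motion plus optional
    Gaussian coordinate noise.  Returns the scrambled structure and the
    ground-truth map ``perm`` with ``perm[old_index] = new_index``."""
    n = len(structure)
    rng_p = np.random.default_rng(permute_seed)
    order = rng_p.permutation(n)           # new position k holds old order[k]
    perm = np.empty(n, dtype=int)
    for new, old in enumerate(order):
        perm[old] = new
    rng_r = np.random.default_rng(rigid_seed)
    rot = Rotation.random(rng=rng_r)
    shift = rng_r.uniform(-5.0, 5.0, size=3)
    noise = (rng_r.normal(0.0, noise_sigma, size=(n, 3))
             if noise_sigma > 0 else np.zeros((n, 3)))
    atoms = []
    for new, old in enumerate(order):
        a = structure.atoms[old].copy()
        a.index = new
        a.position = rot.apply(a.position) + shift + noise[new]
        atoms.append(a)
    out = Structure(atoms, formal_charge=structure.formal_charge)
    for i, j in structure.bonds:
        out.add_bond(int(perm[i]), int(perm[j]))
    return out, perm


def make_improper_scan(k: float = 85.0, xi_eq: float = 0.0,
                       e0: float = 0.0, n: int = 9, width: float = 20.0,
                       sigma: float = 0.0, seed: int = 0) -> ScanData:
    """Synthetic 1D improper scan E = k (xi - xi_eq)^2 + e0 (+ noise),
    xi in degrees, k in kJ mol-1 rad-2."""
    angles = np.linspace(xi_eq - width, xi_eq + width, n)
    energies = k * np.radians(angles - xi_eq) ** 2 + e0
    if sigma > 0:
        energies = energies + np.random.default_rng(seed).normal(
            0.0, sigma, size=n)
    return ScanData(angles=angles, energies=energies)


# -------------------------------------------------- full fixture assembly

@dataclass
class FixtureAssets:
    """Everything needed to exercise the full pipeline on one fixture."""

    structure: Structure
    topology: Topology
    template: "object"            # sites.Template
    saturated: Structure
    hessian: HessianData
    template_grid: ESPGrid
    fragment_grids: list[ESPGrid]
    fragment_charges_full: np.ndarray
    improper_scan: ScanData | None
    metal_indices: list[int]
    formal_charge: int


def _true_charges(structure: Structure, metal_charge_map: dict[int, float],
                  isolated: bool) -> np.ndarray:
    """Deterministic 'true' point charges: chemistry-flavored per-element
    values, saturation hydrogens at zero, each ligand shifted on its heavy
    atoms so ligand sums are integers (0 when isolated)."""
    base = {"N": -0.40, "O": -0.45, "C": 0.08, "H": 0.06, "S": -0.2}
    q = np.zeros(len(structure))
    for i, a in enumerate(structure.atoms):
        if getattr(a, "is_added_h", False):
            q[i] = 0.0
        elif a.is_metal:
            q[i] = metal_charge_map.get(i, 0.0)
        else:
            q[i] = base.get(a.element, 0.0)
    for comp in ligand_components(structure):
        target = 0.0
        if not isolated:
            metal_total = sum(metal_charge_map.values())
            formal = structure.formal_charge
            n_lig = len(ligand_components(structure))
            target = (formal - metal_total) / n_lig
        heavy = [i for i in comp
                 if structure.atoms[i].element != "H"]
        shift = (target - float(np.sum(q[comp]))) / len(heavy)
        for i in heavy:
            q[i] += shift
    return q


def build_fixture_template(kind: str = "square_planar", metal: str = "Pd",
                           charge: int = 2, lj_source: str = "merz",
                           seed: int = 7, improper_k: float = 85.0
                           ) -> FixtureAssets:
    """Generate a fixture site, synthesize its Hessian / ESP inputs, build
    the corresponding template through the real pipeline, and rewrite the
    toy topology's ligand charges to the fragment RESP charges so that the
    self-patching identity (patched charges == template charges) is exact."""
    from .build import build_template, prepare_saturated_template

    if kind == "square_planar":
        structure, topology = make_square_planar_site(
            metal=metal, charge=charge, seed=seed)
        metal_idx = [0]
    elif kind == "octahedral":
        structure, topology = make_octahedral_site(
            metal=metal, charge=charge, seed=seed)
        metal_idx = [0]
    elif kind == "pd2l4":
        structure, topology = make_pd2l4_cage(seed=seed)
        metal, charge = "Pd", 2
        metal_idx = [0, 1]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    sub, saturated, m_new = prepare_saturated_template(structure, metal_idx[0])

    # synthetic QM stand-ins at the saturated-template geometry
    bond_k = {tuple(sorted(b)): default_bond_constant(
        saturated.atoms[b[0]].element, saturated.atoms[b[1]].element)
        for b in saturated.bonds}
    metal_bonds = {b for b in bond_k
                   if saturated.atoms[b[0]].is_metal
                   or saturated.atoms[b[1]].is_metal}
    for b in metal_bonds:
        bond_k[b] = 400.0
    hessian = toy_ff_hessian(saturated, bond_k,
                             angle_constants=300.0, mode="fd")

    # charge-transfer ground truth: metal keeps 70% of its formal charge
    q_metal_true = 0.7 * charge
    sat_charge_map = {m_new: q_metal_true}
    sat_formal = charge  # saturated template total = metal + neutral ligands
    saturated.formal_charge = sat_formal
    q_true_template = _true_charges(saturated, sat_charge_map,
                                    isolated=False)
    template_grid = point_charge_esp(saturated, q_true_template,
                                     seed=seed + 1)

    fragment_grids = []
    for comp in ligand_components(saturated):
        frag, _ = saturated.subset(comp)
        frag.formal_charge = 0
        q_frag_true = _true_charges(frag, {}, isolated=True)
        fragment_grids.append(point_charge_esp(frag, q_frag_true,
                                               seed=seed + 2))

    scan = None
    from .seminario import SQUARE_PLANAR_DEFAULTS
    if (metal, charge) in SQUARE_PLANAR_DEFAULTS:
        scan = make_improper_scan(k=improper_k, xi_eq=0.0, seed=seed)

    template = build_template(
        structure, metal_idx[0], charge, hessian, template_grid,
        fragment_grids, lj_source=lj_source, improper_scan=scan,
        name=f"{metal.lower()}{charge}_{lj_source}_{kind}")

    # re-derive the fragment RESP charges and write them into the toy
    # topology so the input force field matches the isolated ligands
    from .resp import fit_resp, symmetrize_charges
    q_frag_full = np.zeros(len(saturated))
    q_frag_full[m_new] = float(charge)
    for comp, grid in zip(ligand_components(saturated), fragment_grids):
        added = [k for k, i in enumerate(comp)
                 if getattr(saturated.atoms[i], "is_added_h", False)]
        qf = fit_resp(grid, zero_constrained=added, a=0.0005)
        for i, qv in zip(comp, qf):
            q_frag_full[i] = qv
    q_frag_full = symmetrize_charges(q_frag_full, saturated)

    # map saturated-template atoms back to input-structure atoms (the first
    # len(sub) saturated atoms are the backbone/link atoms in subset order)
    backbone_parent = sorted(
        set(range(len(structure)))
        & set(_parent_indices(structure, metal_idx[0])))
    for local, parent in enumerate(backbone_parent):
        if structure.atoms[parent].is_metal:
            continue
        topology.atoms[parent].charge = float(q_frag_full[local])
    # keep remaining ligand atoms' charges but rebalance each ligand of the
    # input so ligand sums stay integral (zero)
    for comp in ligand_components(structure):
        inside = [i for i in comp if i in set(backbone_parent)]
        outside = [i for i in comp if i not in set(backbone_parent)]
        if not outside:
            continue
        total = math.fsum(topology.atoms[i].charge for i in comp)
        shift = total / len(outside)
        for i in outside:
            topology.atoms[i].charge -= shift

    return FixtureAssets(
        structure=structure, topology=topology, template=template,
        saturated=saturated, hessian=hessian, template_grid=template_grid,
        fragment_grids=fragment_grids, fragment_charges_full=q_frag_full,
        improper_scan=scan, metal_indices=metal_idx, formal_charge=charge)


def _parent_indices(structure: Structure, metal_index: int) -> list[int]:
    from .sites import _backbone_indices
    backbone, link = _backbone_indices(structure, metal_index)
    return sorted(backbone | link)
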