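"""Restrained ESP (RESP) charge fitting, residual charges, symmetrization.

The fitter minimizes

    chi^2 = sum_p ( V_p - sum_a q_a / |p - r_a| )^2
            + a * sum_{a not H} ( sqrt(q_a^2 + b^2) - b )

in atomic units, subject to a fixed total charge, equality within
equivalence classes and q = 0 on zero-constrained atoms (the link atoms of
a saturated template).  The hyperbolic restraint is handled by iterated
linear KKT solves; the standard two-stage protocol refits only the
equivalence-merged atoms at the stronger stage-2 restraint.

Residual charges Dq = q(complex) - q(isolated fragments) encode the
metal-to-ligand charge transfer; because both charge sets sum to the same
total, the residuals sum to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    BOHR_TO_ANGSTROM,
    ConvergenceError,
    MetalFFError,
    ParseError,
    Structure,
    graphs_isomorphic,
)

__all__ = [
    "ESPGrid", "read_esp_grid", "write_esp_grid",
    "fit_resp", "fit_resp_two_stage",
    "residual_charges", "symmetrize_charges",
]

MIN_GRID_DISTANCE_BOHR = 1.2


@dataclass
class ESPGrid:
    """ESP sample: grid points (bohr), potentials (hartree/e), nuclear
    positions (bohr), element symbols and the molecular total charge."""

    points: np.ndarray
    potentials: np.ndarray
    nuclei: np.ndarray
    elements: list[str]
    total_charge: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        n_at = len(self.nuclei)
        if len(self.elements) != n_at:
            raise MetalFFError("element list does not match nuclei")
        if len(self.points) != len(self.potentials):
            raise MetalFFError("grid points/potentials length mismatch")
        if len(self.points) < n_at + 1:
            raise MetalFFError(
                f"need at least natoms+1 = {n_at + 1} grid points, got "
                f"{len(self.points)}")
        d = np.linalg.norm(
            self.points[:, None, :] - self.nuclei[None, :, :], axis=2)
        if d.min() < MIN_GRID_DISTANCE_BOHR:
            raise MetalFFError(
                f"grid point within {d.min():.3f} bohr of a nucleus "
                f"(minimum {MIN_GRID_DISTANCE_BOHR})")

    @property
    def n_atoms(self) -> int:
        return len(self.nuclei)

    def nuclei_angstrom(self) -> np.ndarray:
        return self.nuclei * BOHR_TO_ANGSTROM


def write_esp_grid(grid: ESPGrid, path: str) -> None:
    lines = [f"# natoms {grid.n_atoms}", f"# charge {grid.total_charge}"]
    for el, (x, y, z) in zip(grid.elements, grid.nuclei):
        lines.append(f"# nucleus {el} {x:.17g} {y:.17g} {z:.17g}")
    lines.append(f"# npoints {len(grid.points)}")
    for (x, y, z), v in zip(grid.points, grid.potentials):
        lines.append(f"{x:.17g} {y:.17g} {z:.17g} {v:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_esp_grid(path: str) -> ESPGrid:
    """Read the text grid format: '# nucleus El x y z' header rows (bohr)
    then one 'x y z V' row per point (bohr, hartree/e)."""
    nuclei, elements, pts, pots = [], [], [], []
    charge = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                tok = line[1:].split()
                if tok and tok[0] == "charge":
                    charge = int(tok[1])
                elif tok and tok[0] == "nucleus":
                    elements.append(tok[1])
                    nuclei.append([float(t) for t in tok[2:5]])
                continue
            tok = line.split()
            try:
                pts.append([float(t) for t in tok[:3]])
                pots.append(float(tok[3]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: bad grid row") from exc
    if not nuclei:
        raise ParseError(f"{path}: no '# nucleus' records")
    return ESPGrid(points=np.array(pts), potentials=np.array(pots),
                   nuclei=np.array(nuclei), elements=elements,
                   total_charge=charge)


def _solve_kkt(amat: np.ndarray, bvec: np.ndarray, cons: np.ndarray,
               d: np.ndarray) -> np.ndarray:
    n = amat.shape[0]
    m = cons.shape[0]
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = amat
    kkt[:n, n:] = cons.T
    kkt[n:, :n] = cons
    rhs = np.concatenate([bvec, d])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise MetalFFError(
            "singular constrained RESP system (conflicting or redundant "
            "constraints)") from exc
    return sol[:n]


def fit_resp(grid: ESPGrid, equivalences=(), zero_constrained=(),
             a: float = 0.0005, b: float = 0.1,
             frozen: dict[int, float] | None = None,
             maxiter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Restrained ESP charges (e).  ``equivalences`` is an iterable of
    atom-index groups forced to share one charge; ``zero_constrained``
    atoms are pinned at exactly zero; ``frozen`` pins atoms at given
    values (used by stage 2).  The hyperbolic restraint applies to
    non-hydrogen atoms."""
    x = 1.0 / np.linalg.norm(
        grid.points[:, None, :] - grid.nuclei[None, :, :], axis=2)
    n = grid.n_atoms
    a0 = 2.0 * (x.T @ x)
    b0 = 2.0 * (x.T @ grid.potentials)

    rows = [np.ones(n)]
    d = [float(grid.total_charge)]
    for idx in zero_constrained:
        r = np.zeros(n)
        r[idx] = 1.0
        rows.append(r)
        d.append(0.0)
    if frozen:
        for idx, val in sorted(frozen.items()):
            r = np.zeros(n)
            r[idx] = 1.0
            rows.append(r)
            d.append(float(val))
    for group in equivalences:
        group = sorted(group)
        for other in group[1:]:
            r = np.zeros(n)
            r[group[0]] = 1.0
            r[other] = -1.0
            rows.append(r)
            d.append(0.0)
    cons = np.array(rows)
    d = np.array(d)

    restrained = np.array([el != "H" for el in grid.elements], dtype=float)
    q = _solve_kkt(a0, b0, cons, d)
    if a == 0:
        return q
    for _ in range(maxiter):
        diag = a * restrained / np.sqrt(q ** 2 + b ** 2)
        q_new = _solve_kkt(a0 + np.diag(diag), b0, cons, d)
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    raise ConvergenceError(
        f"RESP restraint iteration did not converge in {maxiter} steps")


def fit_resp_two_stage(grid: ESPGrid, equivalences, zero_constrained=(),
                       a1: float = 0.0005, a2: float = 0.001,
                       b: float = 0.1) -> np.ndarray:
    """Standard two-stage RESP: stage 1 fits all atoms without equivalences
    at the weak restraint; stage 2 refits only the atoms of the equivalence
    groups (typically merged H / CH groups) at the stronger restraint with
    the remaining charges frozen."""
    q1 = fit_resp(grid, equivalences=(), zero_constrained=zero_constrained,
                  a=a1, b=b)
    eq = [sorted(g) for g in equivalences if len(g) > 1]
    if not eq:
        return q1
    refit = sorted({i for g in eq for i in g})
    frozen = {i: float(q1[i]) for i in range(grid.n_atoms)
              if i not in refit and i not in set(zero_constrained)}
    return fit_resp(grid, equivalences=eq,
                    zero_constrained=zero_constrained, a=a2, b=b,
                    frozen=frozen)


def residual_charges(template_charges: np.ndarray,
                     fragments: list[tuple[list[int], np.ndarray]],
                     metal_index: int,
                     metal_formal_charge: int) -> np.ndarray:
    """Per-atom residual Dq = q(template) - q(fragment).  ``fragments``
    are (template-atom indices, fragment charges) pairs that, together
    with the metal (its own fragment at the integer formal charge), must
    partition the template atoms exactly."""
    template_charges = np.asarray(template_charges, dtype=float)
    n = len(template_charges)
    frag_q = np.full(n, np.nan)
    frag_q[metal_index] = float(metal_formal_charge)
    for indices, charges in fragments:
        charges = np.asarray(charges, dtype=float)
        if len(indices) != len(charges):
            raise MetalFFError("fragment index/charge length mismatch")
        for idx, qv in zip(indices, charges):
            if idx == metal_index or not np.isnan(frag_q[idx]):
                raise MetalFFError(
                    f"fragments do not partition the template: atom {idx} "
                    "covered twice (or is the metal)")
            frag_q[idx] = qv
    if np.isnan(frag_q).any():
        missing = np.nonzero(np.isnan(frag_q))[0]
        raise MetalFFError(
            f"fragments do not partition the template: atoms "
            f"{missing.tolist()} uncovered")
    dq = template_charges - frag_q
    total = math.fsum(dq.tolist())
    if abs(total) > 1e-10:
        raise MetalFFError(
            f"residual charges sum to {total:.3e} e (template total and "
            "fragment totals disagree)")
    return dq


def symmetrize_charges(charges: np.ndarray, structure: Structure,
                       ligands: list[list[int]] | None = None) -> np.ndarray:
    """Average charges over corresponding atoms of graph-isomorphic
    ligands.  The total charge is conserved.  Idempotent."""
    from .sites import ligand_components

    charges = np.asarray(charges, dtype=float).copy()
    if ligands is None:
        ligands = ligand_components(structure)
    g = structure.graph()

    def subgraph(comp):
        sg = g.subgraph(comp).copy()
        return sg

    remaining = list(range(len(ligands)))
    while remaining:
        ref = remaining.pop(0)
        group = [(ref, {i: i for i in ligands[ref]})]
        still = []
        for other in remaining:
            iso = graphs_isomorphic(subgraph(ligands[ref]),
                                    subgraph(ligands[other]))
            if iso is not None:
                group.append((other, iso))
            else:
                still.append(other)
        remaining = still
        if len(group) == 1:
            continue
        for atom in ligands[ref]:
            vals = [charges[iso[atom]] for _, iso in group]
            mean = math.fsum(vals) / len(vals)
            for _, iso in group:
                charges[iso[atom]] = mean
    return charges
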