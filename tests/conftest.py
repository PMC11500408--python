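import math

import numpy as np
import pytest
from hypothesis import settings

from metalff.core import Atom, Structure
from metalff.fixtures import build_fixture_template

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sq_assets():
    """Square-planar Pd(2+) tetrakis(pyridine) fixture with its template
    built through the full pipeline."""
    return build_fixture_template("square_planar", metal="Pd", charge=2,
                                  seed=7)


@pytest.fixture(scope="session")
def pd2l4_assets():
    """Lantern-type [Pd2L4](4+) cage fixture (two square-planar sites
    bridged by four ditopic bis(pyridine) ligands)."""
    return build_fixture_template("pd2l4", seed=11)


@pytest.fixture(scope="session")
def oct_assets():
    """Octahedral Fe(2+) tris-chelate fixture."""
    return build_fixture_template("octahedral", metal="Fe", charge=2,
                                  seed=13)


@pytest.fixture(scope="session")
def fixture_templates(sq_assets, pd2l4_assets, oct_assets):
    return [sq_assets.template, pd2l4_assets.template, oct_assets.template]


def make_pyridine(origin=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)) -> Structure:
    """A free planar pyridine ring (no hydrogens) for graph tests."""
    origin = np.asarray(origin, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, perp)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    atoms = []
    bonds = []
    center = origin + 1.39 * axis
    for k in range(6):
        theta = math.pi + 2 * math.pi * k / 6
        pos = center + 1.39 * (math.cos(theta) * axis
                               + math.sin(theta) * perp)
        el = "N" if k == 0 else "C"
        atoms.append(Atom(index=k, element=el, position=pos))
        bonds.append((k, (k + 1) % 6))
    return Structure(atoms, bonds)


def brute_force_isomorphism(g1, g2):
    """Independent element-preserving graph-isomorphism oracle: plain
    backtracking over adjacency, no library matcher."""
    nodes1 = sorted(g1.nodes)
    nodes2 = sorted(g2.nodes)
    if len(nodes1) != len(nodes2):
        return None
    adj1 = {n: set(g1.neighbors(n)) for n in nodes1}
    adj2 = {n: set(g2.neighbors(n)) for n in nodes2}
    el1 = {n: g1.nodes[n]["element"] for n in nodes1}
    el2 = {n: g2.nodes[n]["element"] for n in nodes2}

    def extend(mapping, used):
        if len(mapping) == len(nodes1):
            return dict(mapping)
        n1 = nodes1[len(mapping)]
        for n2 in nodes2:
            if n2 in used or el1[n1] != el2[n2]:
                continue
            ok = True
            for m1, m2 in mapping.items():
                if (m1 in adj1[n1]) != (m2 in adj2[n2]):
                    ok = False
                    break
            if not ok:
                continue
            mapping[n1] = n2
            used.add(n2)
            result = extend(mapping, used)
            if result is not None:
                return result
            del mapping[n1]
            used.discard(n2)
        return None

    return extend({}, set())


def independent_fd_hessian(structure, bond_terms, angle_terms, step=1e-5):
    """Independent oracle: double central difference of an independently
    written toy-FF energy (V = 1/2 k dx^2 terms)."""
    pos0 = structure.positions.copy()
    n = pos0.size

    def energy(flat):
        p = flat.reshape(-1, 3)
        e = 0.0
        for (i, j, k, r0) in bond_terms:
            r = math.dist(p[i], p[j])
            e += 0.5 * k * (r - r0) ** 2
        for (i, j, kk, k_th, t0) in angle_terms:
            a = p[i] - p[j]
            c = p[kk] - p[j]
            cos_t = np.dot(a, c) / (np.linalg.norm(a) * np.linalg.norm(c))
            t = math.acos(max(-1.0, min(1.0, cos_t)))
            e += 0.5 * k_th * (t - t0) ** 2
        return e

    flat = pos0.ravel()
    h = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            pp = flat.copy(); pp[a] += step; pp[b] += step
            pm = flat.copy(); pm[a] += step; pm[b] -= step
            mp = flat.copy(); mp[a] -= step; mp[b] += step
            mm = flat.copy(); mm[a] -= step; mm[b] -= step
            val = (energy(pp) - energy(pm) - energy(mp) + energy(mm)) / (
                4 * step * step)
            h[a, b] = h[b, a] = val
    return h
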