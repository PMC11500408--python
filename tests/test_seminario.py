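"""Force constants from Hessians, symmetrization, improper fitting."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from metalff.core import Atom, MetalFFError, Structure
from metalff.fixtures import make_improper_scan, toy_ff_hessian
from metalff.seminario import (
    HessianData,
    ScanData,
    angle_params,
    bond_params,
    build_template_bonded,
    fit_improper,
    read_hessian,
    symmetrize,
    write_hessian,
)
from metalff.topology import BondTerm, Topology

from conftest import independent_fd_hessian


def diatomic(k=250.0, r=1.3):
    s = Structure([Atom(index=0, element="C", position=[0, 0, 0]),
                   Atom(index=1, element="O", position=[r, 0, 0])],
                  [(0, 1)])
    return s, toy_ff_hessian(s, k, mode="analytic")


def water_like(k_bond=300.0, k_angle=40.0):
    theta = math.radians(104.5)
    r = 0.96
    s = Structure([
        Atom(index=0, element="O", position=[0, 0, 0]),
        Atom(index=1, element="H", position=[r, 0, 0]),
        Atom(index=2, element="H",
             position=[r * math.cos(theta), r * math.sin(theta), 0]),
    ], [(0, 1), (0, 2)])
    return s, toy_ff_hessian(s, k_bond, angle_constants=k_angle, mode="fd")


class TestBondParams:
    def test_harmonic_diatomic_exact(self):
        s, h = diatomic(k=250.0, r=1.3)
        r_eq, k = bond_params(h, 0, 1)
        assert r_eq == pytest.approx(1.3, abs=0)
        assert k == pytest.approx(250.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_rotational_invariance(self, seed):
        s, h = diatomic()
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        atoms = [Atom(index=i, element=a.element, position=rot @ a.position)
                 for i, a in enumerate(s.atoms)]
        s2 = Structure(atoms, [(0, 1)])
        h2 = toy_ff_hessian(s2, 250.0, mode="analytic")
        _, k1 = bond_params(h, 0, 1)
        _, k2 = bond_params(h2, 0, 1)
        assert k2 == pytest.approx(k1, abs=1e-9)

    def test_nonbonded_pair_rejected(self):
        s = Structure([Atom(index=0, element="C", position=[0, 0, 0]),
                       Atom(index=1, element="C", position=[1.5, 0, 0]),
                       Atom(index=2, element="C", position=[9.0, 0, 0])],
                      [(0, 1)])
        h = toy_ff_hessian(s, {(0, 1): 250.0}, mode="analytic")
        with pytest.raises(MetalFFError, match="bond"):
            bond_params(h, 0, 2)

    def test_finite_difference_recovery_within_one_percent(self):
        s, h = water_like(k_bond=300.0, k_angle=40.0)
        for pair in [(0, 1), (0, 2)]:
            _, k = bond_params(h, *pair)
            assert k == pytest.approx(300.0, rel=0.01)

    def test_fd_hessian_matches_independent_oracle(self):
        """Our toy-FF Hessian agrees with an independently written
        double-central-difference oracle."""
        s, h = water_like()
        theta0 = math.radians(104.5)
        oracle = independent_fd_hessian(
            s,
            bond_terms=[(0, 1, 300.0, 0.96), (0, 2, 300.0, 0.96)],
            angle_terms=[(1, 0, 2, 40.0, theta0)])
        assert np.abs(h.matrix - oracle).max() < 1e-3 * np.abs(oracle).max()
        h_o = HessianData(matrix=0.5 * (oracle + oracle.T), geometry=s)
        _, k = bond_params(h_o, 0, 1)
        assert k == pytest.approx(300.0, rel=0.01)


def right_angle_triatomic(k_bond=3000.0, k_angle=40.0):
    r = 0.96
    s = Structure([
        Atom(index=0, element="O", position=[0, 0, 0]),
        Atom(index=1, element="H", position=[r, 0, 0]),
        Atom(index=2, element="H", position=[0, r, 0]),
    ], [(0, 1), (0, 2)])
    return s, toy_ff_hessian(s, k_bond, angle_constants=k_angle, mode="fd")


class TestAngleParams:
    def test_right_angle_recovery_within_two_percent(self):
        """The projection is exact for right angles with stiff arms (the
        coordination geometry of the target systems)."""
        s, h = right_angle_triatomic(k_bond=3000.0, k_angle=40.0)
        theta, k = angle_params(h, 1, 0, 2)
        assert theta == pytest.approx(90.0, abs=1e-6)
        assert k == pytest.approx(40.0, rel=0.02)

    def test_bent_angle_bias_bounded_by_overlap(self):
        """Away from 90 deg the stretch/bend subspaces overlap and the
        constant is overestimated by at most a factor (1 + |cos theta0|)."""
        s, h = water_like(k_bond=3000.0, k_angle=40.0)
        theta, k = angle_params(h, 1, 0, 2)
        assert theta == pytest.approx(104.5, abs=1e-6)
        cos_t = abs(math.cos(math.radians(104.5)))
        assert 40.0 * 0.98 <= k <= 40.0 * (1.0 + cos_t)

    def test_cis_donor_angle_recovered_exactly(self, sq_assets):
        """For cis N-Pd-N right angles the series projection is exact:
        the coplanar partner angle sharing each Pd-N bond supplies the
        factor of two the series combination requires."""
        h = sq_assets.hessian
        g = h.geometry
        donors = sorted(g.neighbors(0))[:2]
        theta, k = angle_params(h, donors[0], 0, donors[1])
        assert theta == pytest.approx(90.0, abs=1e-6)
        assert k == pytest.approx(300.0, rel=0.02)

    def test_equilibrium_angle_is_geometric(self, sq_assets):
        h = sq_assets.hessian
        g = h.geometry
        # cis N-Pd-N in the idealized square plane
        donors = sorted(g.neighbors(0))[:2]
        theta, _ = angle_params(h, donors[0], 0, donors[1])
        assert theta == pytest.approx(90.0, abs=1e-6)

    def test_collinear_angle_rejected(self, sq_assets):
        h = sq_assets.hessian
        g = h.geometry
        donors = sorted(g.neighbors(0))
        # trans donors are exactly 180 degrees apart
        trans = [(a, b) for a in donors for b in donors if a < b
                 and abs(np.dot(g.atoms[a].position, g.atoms[b].position)
                         + 4.0) < 1e-6]
        a, b = trans[0]
        with pytest.raises(MetalFFError, match="linear|collinear"):
            angle_params(h, a, 0, b)


class TestSymmetrize:
    def test_equivalent_metal_bonds_get_mean(self, sq_assets):
        t = sq_assets.template
        top = t.topology.copy()
        values = [248.0, 250.0, 252.0, 250.0]
        pd_bonds = [b for b in top.bonds if t.metal_index in (b.i, b.j)]
        assert len(pd_bonds) == 4
        for b, v in zip(pd_bonds, values):
            b.k = v
        out = symmetrize(top, t.structure)
        ks = [b.k for b in out.bonds if t.metal_index in (b.i, b.j)]
        assert ks == [250.0] * 4

    def test_chemically_distinct_bonds_untouched(self):
        s = Structure([
            Atom(index=0, element="Zn", position=[0, 0, 0]),
            Atom(index=1, element="N", position=[2.0, 0, 0]),
            Atom(index=2, element="O", position=[-2.0, 0, 0]),
        ], [(0, 1), (0, 2)])
        top = Topology()
        from metalff.topology import AtomType, TopologyAtom
        top.atomtypes["X"] = AtomType("X", 0, 1.0, 0.0, 0.3, 0.0)
        for a in s.atoms:
            top.atoms.append(TopologyAtom(a.name, "X", 0.0, 1.0))
        top.bonds = [BondTerm(0, 1, 2.0, 100.0), BondTerm(0, 2, 2.0, 900.0)]
        out = symmetrize(top, s)
        assert [b.k for b in out.bonds] == [100.0, 900.0]

    def test_inequivalent_arms_stay_distinct(self, sq_assets):
        """When one pyridine carries a substituent, its metal bond is no
        longer graph-equivalent to the others and keeps its own value."""
        s = sq_assets.structure.copy()
        meta = 3
        pos = s.atoms[meta].position
        extra = Atom(index=len(s.atoms), element="C",
                     position=pos + 1.5 * pos / np.linalg.norm(pos))
        s.atoms.append(extra)
        s.add_bond(meta, extra.index)
        top = sq_assets.template.topology.copy()
        from metalff.topology import TopologyAtom
        top.atoms.append(TopologyAtom("CX", "TC", 0.0, 12.011))
        pd_bonds = [b for b in top.bonds if 0 in (b.i, b.j)]
        for b, v in zip(pd_bonds, [100.0, 200.0, 200.0, 200.0]):
            b.k = v  # bond to the substituted ring first (donor index 1)
        out = symmetrize(top, s)
        ks = sorted(b.k for b in out.bonds if 0 in (b.i, b.j))
        assert ks[0] == 100.0 and ks[1:] == [200.0] * 3

    def test_idempotent(self, sq_assets):
        t = sq_assets.template
        once = symmetrize(t.topology, t.structure)
        twice = symmetrize(once, t.structure)
        assert [(b.r_eq, b.k) for b in twice.bonds] == \
               [(b.r_eq, b.k) for b in once.bonds]
        assert [(a.theta_eq, a.k) for a in twice.angles] == \
               [(a.theta_eq, a.k) for a in once.angles]


class TestImproperFit:
    def test_noiseless_quadratic_exact(self):
        scan = make_improper_scan(k=85.0, xi_eq=0.0, e0=3.0, n=9, width=20)
        fit = fit_improper(scan)
        assert fit.k == pytest.approx(85.0, abs=1e-8)
        assert fit.xi_eq == pytest.approx(0.0, abs=1e-8)
        assert fit.e0 == pytest.approx(3.0, abs=1e-8)

    def test_offset_minimum_recovered(self):
        scan = make_improper_scan(k=40.0, xi_eq=5.0, n=11, width=15)
        fit = fit_improper(scan)
        assert fit.xi_eq == pytest.approx(5.0, abs=1e-8)

    def test_noisy_fit_within_three_standard_errors(self):
        scan = make_improper_scan(k=85.0, xi_eq=0.0, sigma=0.1, n=9,
                                  width=20, seed=5)
        fit = fit_improper(scan)
        assert abs(fit.k - 85.0) <= 3.0 * fit.stderr_k

    def test_linear_scan_rejected(self):
        angles = np.linspace(-20, 20, 9)
        scan = ScanData(angles=angles, energies=0.5 * angles)
        with pytest.raises(MetalFFError, match="convex"):
            fit_improper(scan)

    def test_too_few_points_rejected(self):
        with pytest.raises(MetalFFError, match="5"):
            ScanData(angles=[0, 1, 2], energies=[0, 1, 4])


class TestTemplateBonded:
    def test_square_planar_default_enables_impropers(self, sq_assets):
        scan = make_improper_scan()
        top = build_template_bonded(sq_assets.hessian, 0, 2,
                                    improper_flag=False, improper_scan=scan)
        assert len(top.impropers()) == 4  # one per donor

    def test_zinc_defaults_off(self):
        from metalff.fixtures import make_square_planar_site
        s, _ = make_square_planar_site(metal="Zn", charge=2)
        from metalff.build import prepare_saturated_template
        sub, sat, m = prepare_saturated_template(s, 0)
        bond_k = {tuple(sorted(b)): 500.0 for b in sat.bonds}
        h = toy_ff_hessian(sat, bond_k, angle_constants=200.0, mode="fd")
        top = build_template_bonded(h, m, 2, improper_flag=False)
        assert top.impropers() == []
        top2 = build_template_bonded(h, m, 2, improper_flag=True,
                                     improper_scan=make_improper_scan())
        assert len(top2.impropers()) == 4

    def test_impropers_requested_without_scan_is_error(self, sq_assets):
        with pytest.raises(MetalFFError, match="scan"):
            build_template_bonded(sq_assets.hessian, 0, 2,
                                  improper_flag=False, improper_scan=None)

    def test_no_proper_dihedrals_through_metal(self, sq_assets):
        assert sq_assets.template.topology.propers() == []

    def test_gromacs_improper_constant_convention(self, sq_assets):
        """The emitted funct-2 constant is twice the fitted k, so that
        1/2 k_gmx (xi - xi0)^2 equals the fitted k (xi - xi0)^2."""
        scan = sq_assets.improper_scan
        fit = fit_improper(scan)
        imp = sq_assets.template.topology.impropers()[0]
        assert imp.params[1] == pytest.approx(2.0 * fit.k, rel=1e-12)

    def test_rigid_motion_leaves_constants_unchanged(self):
        """Rotating geometry and Hessian consistently leaves every
        extracted constant invariant."""
        s, h = water_like()
        rot = Rotation.random(rng=np.random.default_rng(11)).as_matrix()
        n = len(s)
        big = np.kron(np.eye(n), rot)
        h_rot = big @ h.matrix @ big.T
        atoms = [Atom(index=i, element=a.element, position=rot @ a.position)
                 for i, a in enumerate(s.atoms)]
        s_rot = Structure(atoms, list(s.bonds))
        h2 = HessianData(matrix=h_rot, geometry=s_rot)
        for pair in [(0, 1), (0, 2)]:
            _, k1 = bond_params(h, *pair)
            _, k2 = bond_params(h2, *pair)
            assert k2 == pytest.approx(k1, abs=1e-8)
        t1, a1 = angle_params(h, 1, 0, 2)
        t2, a2 = angle_params(h2, 1, 0, 2)
        assert (t2, a2) == (pytest.approx(t1, abs=1e-8),
                            pytest.approx(a1, abs=1e-8))


class TestHessianIO:
    def test_plain_text_round_trip(self, tmp_path):
        s, h = water_like()
        p = tmp_path / "w.hessian"
        write_hessian(h, str(p))
        back = read_hessian(str(p))
        np.testing.assert_allclose(back.matrix, h.matrix, rtol=1e-12)
        np.testing.assert_allclose(back.geometry.positions, s.positions,
                                   rtol=0, atol=1e-12)

    def test_orca_dialect_with_unit_conversion(self, tmp_path):
        """A minimal ORCA-format .hess block is parsed and converted from
        Hartree/bohr^2 to kJ/mol/A^2."""
        from metalff.seminario import HARTREE_KJMOL, BOHR_A
        val = 0.25
        text = (
            "$orca_hessian_file\n\n$hessian\n3\n"
            "              0          1          2\n"
            f"    0   {val} 0.0 0.0\n"
            "    1   0.0 0.1 0.0\n"
            "    2   0.0 0.0 0.1\n"
            "$atoms\n1\n"
            " H 1.008 0.0 0.0 0.0\n"
            "$end\n")
        p = tmp_path / "t.hess"
        p.write_text(text)
        h = read_hessian(str(p))
        expected = val * HARTREE_KJMOL / BOHR_A ** 2
        assert h.matrix[0, 0] == pytest.approx(expected, rel=1e-12)
        assert len(h.geometry) == 1


class TestHessianInvariants:
    def test_asymmetric_matrix_rejected(self):
        s, h = diatomic()
        bad = h.matrix.copy()
        bad[0, 1] += 1.0
        with pytest.raises(MetalFFError, match="symmetric"):
            HessianData(matrix=bad, geometry=s)

    def test_shape_mismatch_rejected(self):
        s, h = diatomic()
        with pytest.raises(MetalFFError, match="match"):
            HessianData(matrix=np.eye(5), geometry=s)
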