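"""RESP charge fitting, residual charges and charge symmetrization."""

import math

import numpy as np
import pytest

from metalff.core import Atom, MetalFFError, Structure
from metalff.fixtures import point_charge_esp
from metalff.resp import (
    ESPGrid,
    fit_resp,
    fit_resp_two_stage,
    read_esp_grid,
    residual_charges,
    symmetrize_charges,
    write_esp_grid,
)


@pytest.fixture()
def diatomic_grid():
    s = Structure([Atom(index=0, element="N", position=[0, 0, 0]),
                   Atom(index=1, element="C", position=[1.3, 0, 0])],
                  [(0, 1)])
    return s, point_charge_esp(s, [0.4, -0.4], seed=3)


@pytest.fixture()
def five_atom_grid():
    """Linear C4N chain with a designated link atom."""
    atoms = [Atom(index=i, element="C" if i else "N",
                  position=[1.45 * i, 0.2 * (i % 2), 0.0])
             for i in range(5)]
    s = Structure(atoms, [(i, i + 1) for i in range(4)])
    q = np.array([-0.3, 0.2, -0.1, 0.2, 0.0])
    return s, point_charge_esp(s, q, seed=5), q


class TestFitResp:
    def test_inverse_crime_unrestrained(self, diatomic_grid):
        """With a = 0 the generating point charges are an exact solution
        of the (overdetermined, consistent) inverse problem."""
        _, grid = diatomic_grid
        q = fit_resp(grid, a=0.0)
        np.testing.assert_allclose(q, [0.4, -0.4], atol=1e-6)

    def test_total_charge_constraint(self, five_atom_grid):
        _, grid, _ = five_atom_grid
        q = fit_resp(grid, a=0.0005)
        assert math.fsum(q.tolist()) == pytest.approx(0.0, abs=1e-10)

    def test_zero_constrained_link_atom(self, five_atom_grid):
        _, grid, _ = five_atom_grid
        q = fit_resp(grid, zero_constrained=[4], a=0.0005)
        assert q[4] == 0.0
        assert math.fsum(q.tolist()) == pytest.approx(0.0, abs=1e-10)

    def test_restraint_shrinks_charges_monotonically(self, five_atom_grid):
        _, grid, _ = five_atom_grid
        norms = [np.abs(fit_resp(grid, a=a)).sum()
                 for a in (0.0, 0.0005, 0.001, 0.005, 0.02)]
        assert all(n2 <= n1 + 1e-12 for n1, n2 in zip(norms, norms[1:]))

    def test_equivalence_classes_share_one_charge(self, five_atom_grid):
        _, grid, _ = five_atom_grid
        q = fit_resp(grid, equivalences=[(1, 3)], a=0.0005)
        assert q[1] == pytest.approx(q[3], abs=1e-12)

    def test_two_stage_refits_only_merged_groups(self, five_atom_grid):
        _, grid, _ = five_atom_grid
        q1 = fit_resp(grid, a=0.0005)
        q2 = fit_resp_two_stage(grid, equivalences=[(1, 3)])
        assert q2[1] == pytest.approx(q2[3], abs=1e-12)
        # atoms outside the merged group keep their stage-1 charges
        assert q2[0] == pytest.approx(q1[0], abs=1e-12)
        assert q2[2] == pytest.approx(q1[2], abs=1e-12)

    def test_hydrogen_not_restrained(self):
        """The hyperbolic restraint applies to heavy atoms only, so an H
        charge is not shrunk toward zero faster than its heavy partner."""
        s = Structure([Atom(index=0, element="C", position=[0, 0, 0]),
                       Atom(index=1, element="H", position=[1.09, 0, 0])],
                      [(0, 1)])
        grid = point_charge_esp(s, [-0.2, 0.2], seed=9)
        q_weak = fit_resp(grid, a=0.0)
        q_strong = fit_resp(grid, a=0.05)
        shrink_c = abs(q_weak[0]) - abs(q_strong[0])
        shrink_h = abs(q_weak[1]) - abs(q_strong[1])
        # H only moves through the total-charge constraint
        assert shrink_c > 0
        assert shrink_h <= shrink_c + 1e-9

    def test_conflicting_constraints_are_singular(self, five_atom_grid):
        _, grid, _ = five_atom_grid
        with pytest.raises(MetalFFError, match="singular"):
            # same atom pinned to two different values
            fit_resp(grid, zero_constrained=[0],
                     frozen={0: 0.5}, a=0.0005)


class TestResidualCharges:
    def test_identical_charges_give_zero(self):
        q = np.array([1.2, -0.3, -0.3, -0.3, -0.3])
        frags = [([1, 2], q[[1, 2]]), ([3, 4], q[[3, 4]])]
        dq = residual_charges(q, frags, 0, metal_formal_charge=1.2)
        np.testing.assert_array_equal(dq, np.zeros(5))

    def test_metal_charge_transfer_arithmetic(self):
        """A template metal charge of 1.2 against a formal 2+ fragment
        gives a metal residual of -0.8."""
        q_tmpl = np.array([1.2, 0.7, 0.7])
        frags = [([1, 2], np.array([0.3, 0.3]))]
        dq = residual_charges(q_tmpl, frags, 0, metal_formal_charge=2)
        assert dq[0] == pytest.approx(-0.8)
        assert math.fsum(dq.tolist()) == pytest.approx(0.0, abs=1e-10)

    def test_partition_mismatch_rejected(self):
        q = np.zeros(4)
        with pytest.raises(MetalFFError, match="partition"):
            residual_charges(q, [([1, 2], np.zeros(2))], 0, 0)
        with pytest.raises(MetalFFError, match="partition"):
            residual_charges(q, [([1, 2], np.zeros(2)),
                                 ([2, 3], np.zeros(2))], 0, 0)

    def test_inconsistent_totals_rejected(self):
        q_tmpl = np.array([1.0, 0.5])
        with pytest.raises(MetalFFError, match="sum"):
            residual_charges(q_tmpl, [([1], np.array([0.0]))], 0, 1)

    def test_built_templates_sum_to_zero(self, fixture_templates):
        for t in fixture_templates:
            assert math.fsum(t.residual_charges.tolist()) == pytest.approx(
                0.0, abs=1e-10)


class TestSymmetrizeCharges:
    def test_identical_ligands_equalized(self, sq_assets):
        s = sq_assets.template.saturated_structure
        from metalff.sites import ligand_components
        ligands = ligand_components(s)
        rng = np.random.default_rng(2)
        q = rng.normal(0, 0.2, len(s))
        out = symmetrize_charges(q, s)
        assert math.fsum(out.tolist()) == pytest.approx(
            math.fsum(q.tolist()), abs=1e-12)
        # donor charges across the four rings coincide
        donors = [comp[0] for comp in ligands]
        donor_n = [i for i in donors if s.atoms[i].element == "N"]
        vals = {round(out[i], 12) for i in
                (i for comp in ligands for i in comp
                 if s.atoms[i].element == "N")}
        assert len(vals) == 1

    def test_distinct_species_untouched(self):
        atoms = [Atom(index=0, element="Zn", position=[0, 0, 0]),
                 Atom(index=1, element="N", position=[2, 0, 0]),
                 Atom(index=2, element="O", position=[-2, 0, 0])]
        s = Structure(atoms, [(0, 1), (0, 2)])
        q = np.array([2.0, -0.4, -0.6])
        out = symmetrize_charges(q, s)
        np.testing.assert_array_equal(out, q)

    def test_idempotent(self, sq_assets):
        s = sq_assets.template.saturated_structure
        q = np.random.default_rng(4).normal(0, 0.2, len(s))
        once = symmetrize_charges(q, s)
        twice = symmetrize_charges(once, s)
        np.testing.assert_allclose(twice, once, atol=1e-15)


class TestESPGridContract:
    def test_too_few_points_rejected(self):
        with pytest.raises(MetalFFError, match="grid points"):
            ESPGrid(points=np.zeros((2, 3)), potentials=np.zeros(2),
                    nuclei=np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                    elements=["C", "C"], total_charge=0)

    def test_point_too_close_to_nucleus_rejected(self):
        pts = np.array([[0.5, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]])
        with pytest.raises(MetalFFError, match="bohr"):
            ESPGrid(points=pts, potentials=np.zeros(4),
                    nuclei=np.array([[0.0, 0, 0]]), elements=["C"],
                    total_charge=0)

    def test_file_round_trip(self, diatomic_grid, tmp_path):
        _, grid = diatomic_grid
        p = tmp_path / "g.esp"
        write_esp_grid(grid, str(p))
        back = read_esp_grid(str(p))
        np.testing.assert_array_equal(back.points, grid.points)
        np.testing.assert_array_equal(back.potentials, grid.potentials)
        np.testing.assert_array_equal(back.nuclei, grid.nuclei)
        assert back.elements == grid.elements
        assert back.total_charge == grid.total_charge
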