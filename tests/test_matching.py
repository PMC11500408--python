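"""Template selection, site reduction and permutation mapping."""

import itertools

import networkx as nx
import numpy as np
import pytest

from metalff.core import Atom, NoMatchError, Structure
from metalff.fixtures import scramble
from metalff.matching import (
    AtomMapping,
    accept_mapping,
    kabsch_rmsd,
    map_heavy_atoms,
    reconstruct_hydrogens,
    reduce_site,
    select_template,
)
from metalff.sites import build_sites


def _rebuild_site(structure, metal_symbol, charge):
    s = structure.copy()
    s.formal_charge = charge
    return build_sites(s, {metal_symbol: charge})[0]


def assert_inverted_up_to_symmetry(template, perm, to_parent, tol=1e-6):
    """The recovered bijection must equal the applied scramble up to a
    geometry-preserving automorphism of the template (idealized fixtures
    have exact point-group symmetry, so several permutations superpose
    with zero RMSD)."""
    inv = np.empty(len(perm), dtype=int)
    inv[perm] = np.arange(len(perm))
    sigma = {t: int(inv[s]) for t, s in to_parent.items()}
    assert sorted(sigma) == list(range(len(template.structure)))
    els = template.structure.elements
    assert all(els[sigma[t]] == els[t] for t in sigma)
    bonds = template.structure.bonds
    assert {tuple(sorted((sigma[i], sigma[j]))) for i, j in bonds} == bonds
    order = sorted(sigma)
    pos = template.structure.positions
    assert kabsch_rmsd(pos[[sigma[t] for t in order]], pos[order]) < tol


def _map_template_onto(template, structure):
    site = _rebuild_site(structure, template.metal_symbol,
                         template.formal_charge)
    pruned, pruned_to_site = reduce_site(site, template)
    mapping = map_heavy_atoms(pruned, template)
    mapping = reconstruct_hydrogens(mapping, pruned, template)
    to_parent = {t: site.site_to_parent[pruned_to_site[s]]
                 for t, s in mapping.pairs.items()}
    return mapping, to_parent


class TestSelectTemplate:
    def test_matching_and_missing_keys(self, fixture_templates):
        lib = fixture_templates
        hit = select_template(lib, "Pd", 2, "merz")
        assert hit is not None and hit.metal_symbol == "Pd"
        assert select_template(lib, "Pd", 2, "zhang") is None
        assert select_template(lib, "Ag", 1, "merz") is None

    def test_lexicographic_tie_break(self, sq_assets):
        a = sq_assets.template
        import copy
        b = copy.deepcopy(a)
        a2 = copy.deepcopy(a)
        b.name = "zzz_template"
        a2.name = "aaa_template"
        assert select_template([b, a2], "Pd", 2, "merz").name == \
            "aaa_template"


class TestReduceSite:
    def test_remote_substituents_cut_by_distance(self, pd2l4_assets):
        """Bridging-ligand atoms beyond the template footprint are pruned;
        the pruned site has exactly the template's atom content."""
        t = pd2l4_assets.template
        site = build_sites(pd2l4_assets.structure, {"Pd": 2})[0]
        pruned, _ = reduce_site(site, t)
        assert len(pruned) == len(t.structure)
        assert sorted(a.element for a in pruned.atoms) == \
            sorted(a.element for a in t.structure.atoms)

    def test_substituted_ring_pruned_to_bare_template(self, sq_assets):
        """A site whose pyridines carry an extra substituent maps onto the
        bare-pyridine template after pruning."""
        s = sq_assets.structure.copy()
        # attach a methyl carbon to one meta carbon of each ring, replacing
        # nothing (the ring H stays; the methyl is an extra heavy branch)
        ring_starts = [1, 7, 13, 19]
        for start in ring_starts:
            meta = start + 2
            pos = s.atoms[meta].position
            out = pos / np.linalg.norm(pos)
            c = Atom(index=len(s.atoms), element="C",
                     position=pos + 1.5 * out)
            s.atoms.append(c)
            s.add_bond(meta, c.index)
        site = _rebuild_site(s, "Pd", 2)
        pruned, _ = reduce_site(site, sq_assets.template)
        heavy = [a.element for a in pruned.atoms if a.element != "H"]
        assert sorted(heavy) == sorted(
            a.element for a in sq_assets.template.structure.atoms
            if a.element != "H")

    def test_template_larger_than_site_is_no_match(self, sq_assets,
                                                   oct_assets):
        """A template linker that is not a subgraph of any site linker
        signals no-match."""
        site = build_sites(oct_assets.structure, {"Fe": 2})[0]
        t = sq_assets.template
        import copy
        t = copy.deepcopy(t)
        t.metal_symbol = "Fe"  # force the metal check to pass
        with pytest.raises(NoMatchError):
            reduce_site(site, t)


class TestHeavyAtomMapping:
    @pytest.mark.parametrize("permute_seed,rigid_seed", [(1, 2), (5, 9)])
    def test_scramble_inverted_exactly(self, fixture_templates,
                                       permute_seed, rigid_seed):
        for template in fixture_templates:
            scrambled, perm = scramble(template.structure, permute_seed,
                                       rigid_seed, noise_sigma=0.0)
            mapping, to_parent = _map_template_onto(template, scrambled)
            assert mapping.rmsd < 1e-6
            assert_inverted_up_to_symmetry(template, perm, to_parent)

    def test_noise_keeps_permutation(self, sq_assets):
        """0.3 A coordinate noise does not change the recovered
        permutation and the RMSD reports the noise level."""
        t = sq_assets.template
        clean, perm = scramble(t.structure, 3, 4, noise_sigma=0.0)
        noisy, perm2 = scramble(t.structure, 3, 4, noise_sigma=0.3)
        np.testing.assert_array_equal(perm, perm2)
        mapping, to_parent = _map_template_onto(t, noisy)
        assert all(to_parent[i] == perm[i] for i in to_parent)
        assert 0.1 < mapping.rmsd < 0.6

    def test_rigid_motion_invariance(self, sq_assets):
        t = sq_assets.template
        a, _ = scramble(t.structure, 0, 1, 0.0)
        b, _ = scramble(t.structure, 0, 2, 0.0)  # same order, other motion
        m_a, _ = _map_template_onto(t, a)
        m_b, _ = _map_template_onto(t, b)
        assert abs(m_a.rmsd - m_b.rmsd) < 1e-9

    def test_self_match_is_identity(self, fixture_templates):
        for t in fixture_templates:
            mapping, to_parent = _map_template_onto(t, t.structure)
            assert mapping.rmsd < 1e-12
            assert all(to_parent[i] == i for i in to_parent)

    def test_c2_symmetric_linker_tie_is_deterministic(self, sq_assets):
        """Each pyridine has a mirror automorphism; the degenerate-RMSD tie
        is resolved to the same permutation on every run."""
        t = sq_assets.template
        from metalff.matching import _heavy_graph
        from metalff.sites import ligand_components
        comp = ligand_components(t.structure)[0]
        g = _heavy_graph(t.structure, comp)
        gm = nx.isomorphism.GraphMatcher(
            g, g, node_match=lambda a, b: a["element"] == b["element"])
        autos = list(gm.isomorphisms_iter())
        assert len(autos) == 2  # identity + ring mirror
        m1, p1 = _map_template_onto(t, t.structure)
        m2, p2 = _map_template_onto(t, t.structure)
        assert p1 == p2 and m1.rmsd == m2.rmsd

    def test_staged_search_equals_brute_force(self):
        """On a 3-ligand instance, the staged search minimum equals brute
        force over all element-preserving atom permutations."""
        atoms = [Atom(index=0, element="Pd", position=[0, 0, 0])]
        bonds = []
        for ax in ([1, 0, 0], [0, 1, 0], [0, 0, 1]):
            ax = np.array(ax, dtype=float)
            i = len(atoms)
            atoms.append(Atom(index=i, element="N", position=2.0 * ax))
            atoms.append(Atom(index=i + 1, element="C",
                              position=3.3 * ax + np.array([0.2, 0.3, 0.1])))
            bonds += [(0, i), (i, i + 1)]
        ref = Structure(atoms, bonds, formal_charge=2)

        from metalff.sites import Template
        from metalff.topology import Topology, TopologyAtom, AtomType
        top = Topology()
        top.atomtypes["X"] = AtomType("X", 0, 1.0, 0.0, 0.3, 0.0)
        for a in ref.atoms:
            top.atoms.append(TopologyAtom(a.name, "X", 0.0, 1.0))
        template = Template(
            name="toy", structure=ref, saturated_structure=ref.copy(),
            topology=top, residual_charges=np.zeros(len(ref)),
            metal_index=0, metal_symbol="Pd", formal_charge=2)

        noisy, perm = scramble(ref, 2, 3, noise_sigma=0.05)
        site = _rebuild_site(noisy, "Pd", 2)
        pruned, p2s = reduce_site(site, template)
        staged = map_heavy_atoms(pruned, template)

        # brute force: every element-preserving bijection
        pos = pruned.positions
        els = [a.element for a in pruned.atoms]
        n_idx = [i for i, e in enumerate(els) if e == "N"]
        c_idx = [i for i, e in enumerate(els) if e == "C"]
        m_idx = els.index("Pd")
        t_n = [i for i in range(1, 7, 2)]
        t_c = [i for i in range(2, 7, 2)]
        t_pos = template.structure.positions
        best = np.inf
        for pn in itertools.permutations(n_idx):
            for pc in itertools.permutations(c_idx):
                order = [0] + t_n + t_c
                image = [m_idx] + list(pn) + list(pc)
                r = kabsch_rmsd(pos[image], t_pos[order])
                best = min(best, r)
        assert staged.rmsd == pytest.approx(best, abs=1e-9)


class TestHydrogenReconstruction:
    def test_full_bijection_covers_template(self, sq_assets):
        t = sq_assets.template
        scrambled, perm = scramble(t.structure, 8, 9, 0.0)
        mapping, to_parent = _map_template_onto(t, scrambled)
        assert len(mapping.pairs) == len(t.structure)

    def test_swapped_methylene_hydrogens_resolved(self, oct_assets):
        """Distance-minimal assignment recovers H labels even after the
        scramble permutes them within each CH2/NH2 group."""
        t = oct_assets.template
        scrambled, perm = scramble(t.structure, 21, 22, 0.0)
        mapping, to_parent = _map_template_onto(t, scrambled)
        assert mapping.rmsd < 1e-6
        assert_inverted_up_to_symmetry(t, perm, to_parent)

    def test_missing_hydrogen_is_no_match(self, sq_assets):
        t = sq_assets.template
        s = t.structure.copy()
        # delete one ring hydrogen
        h = max(i for i, a in enumerate(s.atoms) if a.element == "H")
        keep = [i for i in range(len(s)) if i != h]
        sub, _ = s.subset(keep)
        site = _rebuild_site(sub, "Pd", 2)
        with pytest.raises(NoMatchError):
            pruned, p2s = reduce_site(site, t)
            mapping = map_heavy_atoms(pruned, t)
            reconstruct_hydrogens(mapping, pruned, t)


class TestAcceptance:
    @pytest.mark.parametrize("rmsd,expected", [
        (0.4, True),
        (1.999, True),
        (2.0, False),   # strict <
        (2.5, False),
    ])
    def test_threshold_is_strict(self, rmsd, expected):
        m = AtomMapping(pairs={}, rmsd=rmsd)
        assert accept_mapping(m) is expected

    def test_custom_threshold(self):
        m = AtomMapping(pairs={}, rmsd=1.0)
        assert accept_mapping(m, threshold=1.0) is False
        assert accept_mapping(m, threshold=1.0001) is True
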