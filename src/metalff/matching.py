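"""Template selection, site reduction and atom-order mapping.

The atom bijection between a template and a metal site is found in two
stages.  Heavy atoms first: every assignment of template ligands to site
ligands is combined with every element- and adjacency-preserving
isomorphism of the paired ligand graphs, each candidate correspondence is
Kabsch-superposed, and the candidate with the lowest heavy-atom RMSD wins
(ties broken by the lexicographically smallest permutation).  Hydrogens are
then reconstructed per mapped heavy atom by distance-minimal assignment.
A mapping is accepted when its RMSD is strictly below the threshold
(default 2 A).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .core import MetalFFError, NoMatchError, Structure
from .sites import MetalSite, Template, ligand_components

__all__ = [
    "AtomMapping", "select_template", "reduce_site", "map_heavy_atoms",
    "reconstruct_hydrogens", "accept_mapping", "kabsch_rmsd",
]

DEFAULT_RMSD_THRESHOLD = 2.0  # Angstrom, strict <


@dataclass
class AtomMapping:
    """Bijection template-atom index -> target-structure atom index."""

    pairs: dict[int, int]
    rmsd: float
    ligand_permutation: list[tuple[int, int]] = field(default_factory=list)

    def as_array(self, n_template: int) -> np.ndarray:
        out = np.full(n_template, -1, dtype=int)
        for t, s in self.pairs.items():
            out[t] = s
        return out


def select_template(library, metal_symbol: str, charge: int,
                    lj_source: str) -> Template | None:
    """First template matching metal symbol, formal charge and L-J source,
    in lexicographic name order; None when absent."""
    matches = [
        t for t in library
        if t.metal_symbol.lower() == metal_symbol.strip().lower()
        and t.formal_charge == int(charge)
        and t.lj_source.lower() == lj_source.strip().lower()
    ]
    if not matches:
        return None
    return min(matches, key=lambda t: t.name)


def matching_templates(library, metal_symbol: str, charge: int,
                       lj_source: str) -> list[Template]:
    """All matching templates in lexicographic name order."""
    matches = [
        t for t in library
        if t.metal_symbol.lower() == metal_symbol.strip().lower()
        and t.formal_charge == int(charge)
        and t.lj_source.lower() == lj_source.strip().lower()
    ]
    return sorted(matches, key=lambda t: t.name)


def _heavy_graph(structure: Structure, indices) -> nx.Graph:
    g = nx.Graph()
    idx = [i for i in indices if structure.atoms[i].element != "H"]
    for i in idx:
        g.add_node(i, element=structure.atoms[i].element)
    sel = set(idx)
    for i, j in structure.bonds:
        if i in sel and j in sel:
            g.add_edge(i, j)
    return g


def reduce_site(site: MetalSite, template: Template
                ) -> tuple[Structure, list[int]]:
    """Cut the site to the template's footprint: keep atoms within
    (template radius + 2 A) of the metal, then prune each site linker to
    the heavy-atom subgraph matching a template linker.  Returns the pruned
    structure and, for each pruned atom, its index in the site structure."""
    if site.metal_symbol != template.metal_symbol:
        raise MetalFFError(
            f"site metal {site.metal_symbol} != template metal "
            f"{template.metal_symbol}")
    s = site.structure
    mpos = s.atoms[site.metal_site_index].position
    cutoff = template.radius + 2.0
    within = {a.index for a in s.atoms
              if np.linalg.norm(a.position - mpos) <= cutoff}
    within.add(site.metal_site_index)

    # heavy-atom linker graphs on both sides
    tmpl_linkers = ligand_components(template.structure)
    site_linkers_all = ligand_components(s)
    site_linkers = [[i for i in comp if i in within]
                    for comp in site_linkers_all]
    site_linkers = [c for c in site_linkers if c]

    tmpl_graphs = [_heavy_graph(template.structure, comp)
                   for comp in tmpl_linkers]
    site_graphs = [_heavy_graph(s, comp) for comp in site_linkers]

    node_match = nx.isomorphism.categorical_node_match("element", None)

    def best_image(sg: nx.Graph, tg: nx.Graph) -> set[int] | None:
        """Induced-subgraph image of tg inside sg closest to the metal
        (deterministic: distance score, then lexicographic)."""
        gm = nx.isomorphism.GraphMatcher(sg, tg, node_match=node_match)
        best = None
        for count, iso in enumerate(gm.subgraph_isomorphisms_iter()):
            image = frozenset(iso)
            score = (sum(float(np.linalg.norm(s.atoms[i].position - mpos))
                         for i in image), tuple(sorted(image)))
            if best is None or score < best[0]:
                best = (score, image)
            if count >= 500:
                break
        return set(best[1]) if best else None

    def find_assignment(t_idx: int, used: set[int], images: list):
        if t_idx == len(tmpl_graphs):
            return images
        tg = tmpl_graphs[t_idx]
        for s_idx, sg in enumerate(site_graphs):
            if s_idx in used or sg.number_of_nodes() < tg.number_of_nodes():
                continue
            image = best_image(sg, tg)
            if image is None:
                continue
            result = find_assignment(
                t_idx + 1, used | {s_idx}, images + [image])
            if result is not None:
                return result
        return None

    images = find_assignment(0, set(), [])
    if images is None:
        raise NoMatchError(
            "a template linker is not a subgraph of any site linker within "
            "the distance cutoff")

    keep: set[int] = {site.metal_site_index}
    for image in images:
        keep |= image
        # retain hydrogens attached to matched heavy atoms
        for i in image:
            for j in s.neighbors(i):
                if s.atoms[j].element == "H" and j in within:
                    keep.add(j)
    pruned, old_to_new = s.subset(keep)
    pruned_to_site = sorted(keep)
    return pruned, pruned_to_site


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between point sets a and b over rigid motions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate/exact fits
        _, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd) / np.sqrt(len(a))


def kabsch_transform(target: np.ndarray, source: np.ndarray):
    """Rotation R and translation t minimizing |target - (R source + t)|."""
    tc = target.mean(axis=0)
    sc = source.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(target - tc, source - sc)
    return rot, tc, sc


def map_heavy_atoms(pruned_site: Structure, template: Template,
                    site_metal_index: int | None = None) -> AtomMapping:
    """Best heavy-atom bijection template -> pruned site over all ligand
    assignments x per-ligand graph isomorphisms, by Kabsch RMSD."""
    s = pruned_site
    if site_metal_index is None:
        metals = [a.index for a in s.atoms if a.is_metal]
        if len(metals) != 1:
            raise MetalFFError("pruned site must contain exactly one metal")
        site_metal_index = metals[0]
    t_metal = template.metal_index

    t_elems = sorted(a.element for a in template.structure.atoms
                     if a.element != "H")
    s_elems = sorted(a.element for a in s.atoms if a.element != "H")
    if t_elems != s_elems:
        raise NoMatchError(
            "heavy-atom element multisets differ between pruned site and "
            "template")

    tmpl_linkers = ligand_components(template.structure)
    site_linkers = ligand_components(s)
    if len(tmpl_linkers) != len(site_linkers):
        raise NoMatchError("ligand counts differ after pruning")

    node_match = nx.isomorphism.categorical_node_match("element", None)
    tmpl_graphs = [_heavy_graph(template.structure, c) for c in tmpl_linkers]
    site_graphs = [_heavy_graph(s, c) for c in site_linkers]

    # cache all isomorphisms for each (template ligand, site ligand) pair
    iso_cache: dict[tuple[int, int], list[dict]] = {}
    for ti, tg in enumerate(tmpl_graphs):
        for si, sg in enumerate(site_graphs):
            if tg.number_of_nodes() != sg.number_of_nodes():
                iso_cache[ti, si] = []
                continue
            gm = nx.isomorphism.GraphMatcher(tg, sg, node_match=node_match)
            iso_cache[ti, si] = [dict(m) for m in gm.isomorphisms_iter()]

    t_heavy = sorted(i for i, a in enumerate(template.structure.atoms)
                     if a.element != "H" and i != t_metal)
    t_pos = template.structure.positions
    s_pos = s.positions

    best: tuple[float, tuple, dict, list] | None = None
    n_lig = len(tmpl_graphs)
    for assignment in itertools.permutations(range(n_lig)):
        if any(not iso_cache[ti, assignment[ti]] for ti in range(n_lig)):
            continue
        pools = [iso_cache[ti, assignment[ti]] for ti in range(n_lig)]
        for combo in itertools.product(*pools):
            pairs = {t_metal: site_metal_index}
            for iso in combo:
                pairs.update(iso)
            order = [t_metal] + t_heavy
            src = t_pos[order]
            dst = s_pos[[pairs[t] for t in order]]
            rmsd = kabsch_rmsd(dst, src)
            perm = tuple(pairs[t] for t in order)
            cand = (rmsd, perm, pairs,
                    [(ti, assignment[ti]) for ti in range(n_lig)])
            if best is None or rmsd < best[0] - 1e-12 or (
                    abs(rmsd - best[0]) <= 1e-12 and perm < best[1]):
                best = cand
    if best is None:
        raise NoMatchError("no ligand-graph isomorphism between template "
                           "and pruned site")
    rmsd, _, pairs, lig_perm = best
    return AtomMapping(pairs=pairs, rmsd=rmsd, ligand_permutation=lig_perm)


def reconstruct_hydrogens(mapping: AtomMapping, pruned_site: Structure,
                          template: Template) -> AtomMapping:
    """Extend a heavy-atom mapping over hydrogens.  For the hydrogens bonded
    to each mapped heavy atom, the assignment minimizing the summed distance
    after superposition is chosen; an H-count mismatch is a no-match."""
    s = pruned_site
    t = template.structure
    heavy_pairs = dict(mapping.pairs)

    order = sorted(heavy_pairs)
    src = t.positions[order]
    dst = s.positions[[heavy_pairs[i] for i in order]]
    rot, tc, sc = kabsch_transform(dst, src)

    pairs = dict(heavy_pairs)
    for t_heavy, s_heavy in sorted(heavy_pairs.items()):
        t_hs = [j for j in t.neighbors(t_heavy) if t.atoms[j].element == "H"]
        s_hs = [j for j in s.neighbors(s_heavy) if s.atoms[j].element == "H"]
        if len(t_hs) != len(s_hs):
            raise NoMatchError(
                f"hydrogen count mismatch on mapped heavy atom pair "
                f"({t_heavy} -> {s_heavy}): template {len(t_hs)} H, "
                f"site {len(s_hs)} H")
        if not t_hs:
            continue
        t_h_pos = rot.apply(t.positions[t_hs] - sc) + tc
        s_h_pos = s.positions[s_hs]
        cost = np.linalg.norm(
            t_h_pos[:, None, :] - s_h_pos[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            pairs[t_hs[r]] = s_hs[c]

    order = sorted(pairs)
    full_rmsd = kabsch_rmsd(s.positions[[pairs[i] for i in order]],
                            t.positions[order])
    return AtomMapping(pairs=pairs, rmsd=full_rmsd,
                       ligand_permutation=mapping.ligand_permutation)


def accept_mapping(mapping: AtomMapping,
                   threshold: float = DEFAULT_RMSD_THRESHOLD) -> bool:
    """True iff the mapping RMSD is strictly below the threshold."""
    return mapping.rmsd < threshold
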