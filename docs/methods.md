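# Methods

`metalff` parameterizes metal centers in supramolecular structures (cages,
knots, MOFs) with a *covalent* metal model: explicit harmonic bonds, angles
and (for square-planar metals) improper dihedrals between the metal and its
donor atoms, plus a redistribution of partial charges that encodes
metal-to-ligand charge transfer. The metal's Lennard-Jones parameters come
from tabulated ion libraries. The package has two halves: *applying* a
pre-parameterized binding-site template to a new structure, and
*constructing* such a template from a Cartesian Hessian and electrostatic
potential (ESP) grids supplied as files (the package never runs an
electronic-structure code; the synthetic-fixture generator produces
physically consistent stand-ins for testing).

## The template model

A template is one parameterized metal binding site: coordinates of the
metal with its surrounding backbone, the bonded terms involving or adjacent
to the metal, and per-atom *residual charges* Δq. The backbone is every
atom within three bonds of the metal, extended to complete aromatic ring
systems that coordinate the metal, plus a one-bond shell of link atoms.
Rings are perceived as SSSR-style cycles of 5–7 sp²-capable atoms (C, N, O,
S, B with at most three sigma bonds) lying within 0.1 Å of their best-fit
plane; this geometric test avoids depending on a cheminformatics
aromaticity model for charged, metal-bound rings, at the cost of
misclassifying strongly puckered rings (reported, not guessed).

For electronic-structure input the backbone is *saturated*: hydrogens are
added until every non-metal atom reaches its sigma valence (C 4, N 3, O 2,
S 2, H 1; aromatic-ring membership lowers the target by one for the
delocalized π bond; dative bonds to metals never count). Added hydrogens
are placed at standard bond lengths (C–H 1.09 Å, N–H 1.01 Å, O–H 0.96 Å)
along the vacated direction — the negated resultant of the existing bond
vectors, or a deterministic tetrahedral/trigonal completion when several
are missing. Existing atoms are never moved. The valence model carries no
bond orders; non-aromatic double bonds (e.g. carbonyls) would be
over-saturated and are outside the generator's fixture chemistry.
Hypervalent S/P produce a warning rather than a guess.

## Matching a template onto a metal site

Sites are reduced to the template's footprint in two steps: a distance
cutoff (template radius + 2 Å, the radius being the metal-to-furthest-atom
distance) followed by graph pruning, where each template linker graph is
located as a node-induced subgraph of a site linker (heavy atoms only) and
the unmatched branch atoms are discarded. Among multiple subgraph images
the one closest to the metal is taken (ties broken lexicographically),
which selects the correct end of a bridging ligand shared by two metals.

The atom bijection is found in two stages. Heavy atoms: every assignment
of template ligands to site ligands is combined with every
element-preserving isomorphism between the paired ligand graphs; each
candidate correspondence is superposed by the Kabsch algorithm and the
lowest-RMSD candidate wins, ties going to the lexicographically smallest
permutation. This enumeration is exhaustive over exactly the
adjacency-preserving candidates, so no iterative alignment/assignment loop
is needed; its cost is (ligand permutations) × (per-ligand automorphisms),
a few hundred candidates for a four-ligand vertex. Hydrogens are then
attached per mapped heavy atom by minimum-cost assignment of distances
after the heavy-atom superposition; a hydrogen-count mismatch is a
no-match. A mapping is accepted when its all-atom RMSD is strictly below
2 Å (configurable). Because the idealized fixtures have exact point-group
symmetry, the minimizer is unique only up to a geometry-preserving
automorphism; tests assert recovery up to that symmetry.

## Bonded parameters from the Hessian

Bond constants use the interatomic Hessian projection: for pair (i, j) the
3×3 block A = −H_ij is eigen-decomposed and
k_b = Σ_m λ_m |û_ij·v_m|, averaged over the ij and ji blocks. For an
isolated harmonic bond this is exact (the block is k ûûᵀ), and it is
rotationally invariant by construction (eigenvalues sorted descending,
absolute-value projections, so degenerate subspaces cannot flip results).

Angle constants combine the two arms in series:
1/k_θ = 1/(R_ij² P_ij) + 1/(R_kj² P_kj), where P is the eigen-projection
of the (outer-atom, apex) block onto the arm's in-plane perpendicular.
Measured on clean harmonic test systems, the series combination needs each
arm to carry *twice* the bending constant, and that factor of two arrives
through two distinct mechanisms: for a lone angle, the mixing of stretch
and bending directions in the non-symmetric block's eigenvectors; for cis
coordination angles, the coplanar partner angle sharing the bond. As a
result the unscaled series is essentially exact for right coordination
angles — the square-planar and octahedral geometries this tool targets —
and overestimates non-orthogonal angles by up to roughly a factor
(1 + |cos θ_eq|) (measured: +0.7% at 90°, +12% at 104.5°, +19% at 120°,
with stiff arms). We therefore apply no shared-bond rescaling in template
building: on these systems a divisor of 1 + Σ|overlap|² over coplanar
partners would undercount the cis angles by 25–50%. `angle_params` still
accepts per-arm divisors for experimentation. Angles within 1° of linear
are skipped with a warning (harmonic bending is undefined there), and the
synthetic toy force fields likewise never place bending terms on collinear
triples. Proper dihedrals through the metal are never parameterized.

Equivalent terms are symmetrized to their arithmetic mean. Equivalence is
decided by Weisfeiler–Lehman color refinement of the element-labeled graph
(iterated neighborhood hashing to a fixed point): terms whose atom-color
tuples coincide share one value. WL colors are automorphism-invariant, so
genuinely equivalent terms always merge; the refinement could in principle
merge non-equivalent terms on pathological regular graphs, which do not
occur in molecular fixtures. The partition is an equivalence relation and
the operation is idempotent.

Improper dihedrals keep square-planar centers planar. They are built by
default for Rh⁺, Ir⁺, Pd²⁺, Pt²⁺ and Au³⁺ and on request otherwise, one
quadruple per donor (donor, metal, two cis donors), with ξ_eq and k fitted
by least squares to a user-supplied 1D scan E(ξ) = k(ξ−ξ_eq)² + E₀.
A scan whose quadratic coefficient is non-positive or insignificant
relative to the energy range is rejected as non-convex. The GROMACS
funct-2 writer emits 2k, since GROMACS defines V = ½k(ξ−ξ₀)².

## Charges

RESP charges minimize the squared ESP misfit plus the hyperbolic restraint
a Σ(√(q²+b²)−b) over non-hydrogen atoms (b = 0.1 e), subject to the exact
total charge, equality within equivalence classes, and q = 0 on the
saturation hydrogens of a template (so removing them afterwards conserves
charge). The restraint is solved by iterated linear KKT systems to
|Δq|∞ < 1e−8 (at most 200 iterations); a = 0 reduces to one exact
least-squares solve, which reproduces generating point charges on a
well-conditioned synthetic grid. The standard two-stage protocol
(a₁ = 0.0005, then a₂ = 0.001 refitting only equivalence-merged groups
with everything else frozen) is available; template building uses the
single-stage fit plus graph-based symmetrization across isomorphic
ligands, which conserves the total exactly and is idempotent. Everything
inside the fitter is in atomic units; the public surface is in e.

Residual charges are Δq = q(saturated template) − q(isolated fragments),
with the metal its own fragment at the integer formal charge. The primary
text source describes the subtraction in the opposite order, which would
break the self-consistency identity below; the sign used here is the one
for which patching a structure whose force-field charges equal the
isolated-fragment charges reproduces the template charges exactly
(q_FF + (q_tmpl − q_frag) = q_tmpl). Both totals agree by construction, so
ΣΔq = 0 (enforced to 1e−10 e).

When patching, the metal's input charge is discarded and reset to the
integer formal charge (the nonbonded-model convention) before its residual
is added; ligand atoms receive their residuals on top of the input force
field's charges. Where two sites share a bridging ligand, their residual
sets overlap additively — each sums to zero, so this is the only
charge-conserving choice. Bonded terms from the template replace existing
terms over the mapped atoms and add the (previously absent) metal terms;
GROMACS regenerates 1-2/1-3 exclusions from the bond list via nrexcl, so
listing the new metal bonds is what extends the exclusions. Atoms outside
every mapped site are untouched, bit for bit.

## Truncation

A missing template can be replaced by an existing one truncated at 1, 2 or
3 bonds from the metal. Removed atoms' residual charges are summed in
exact rational arithmetic and redistributed in equal shares over every
remaining atom including the metal (the plainest reading of "evenly"),
rounded once to float, so the zero-sum invariant survives to ~1e−16 e.
Bonded terms touching a removed atom are dropped without refitting; the
accuracy loss grows with the truncation depth, so callers should prefer
the least-truncated template that maps.

## Synthetic fixtures and what they do (not) show

The generators produce idealized structures — exact 90°/180° coordination,
planar regular rings — so symmetry assertions are exact: a square-planar
tetrakis(pyridine) vertex, an octahedral tris-chelate, and a lantern-type
[Pd₂L₄] cage whose four ditopic ligands bridge two square-planar metals.
Toy force fields (harmonic bonds/angles with equilibrium at the generated
geometry) provide Hessians either analytically (bond-only) or by central
differences of the analytic gradient (step 1e−4 Å, symmetrized); ESP grids
are Connolly-style shells at 1.4–2.0× the van der Waals radii, ≈1 point/Å²,
with exact Coulomb potentials from deterministic "true" charges that put
30% of the metal's formal charge onto the ligands (the charge-transfer
ground truth). All generators are deterministic under explicit seeds.

Passing tests on these fixtures demonstrate the bookkeeping and the
algorithms exactly (mapping recovery, charge conservation, constant
recovery in the regimes stated above); they do not demonstrate accuracy
against quantum-chemical Hessians or ESPs of real complexes, conformational
robustness of the RMSD matching for distorted experimental geometries, or
the physical quality of the shipped Lennard-Jones fixture entries, which
are representative values for lookup-mechanics testing only.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
fixtures above (45–82 atoms, ESP grids of a few thousand points,
finite-difference Hessians up to 61 atoms), sizes at which every stage is
exercised end to end in seconds. Determinism is fixed throughout:
lexicographic tie-breaks in template selection and mapping, seeded
generators, sorted iteration orders, and full-precision (`%.17g`) text
output, so identical inputs give byte-identical files. Internal units are
Å, degrees and kJ/mol, converted to GROMACS nm-based units only in the
topology writer; XYZ files are parsed in float64 to honor the exact
round-trip contract.
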