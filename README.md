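# metalff

Force-field parameterization of metal centers in supramolecular
structures — metallocages, molecular knots, MOF fragments — for classical
molecular dynamics. Standard topology tools parameterize the organic
ligands but leave the metal as a bare charged sphere; `metalff` patches
such a metal-free GROMACS topology with a *covalent* (bonded) metal model
taken from a library of pre-parameterized binding-site **templates**, and
provides the complete toolchain for building new templates from
user-supplied quantum-chemical data (a Cartesian Hessian and ESP grids —
no electronic-structure code is run by the package).

It is aimed at computational chemists setting up MD simulations of
systems with repeating metal vertices, e.g. [Pd₂L₄]⁴⁺ lantern cages,
where one parameterized vertex can be transplanted to every equivalent
site of the structure.

## The model

For each metal site the topology receives

* **bonded terms** — harmonic bonds V = ½k_b(r−r₀)² between the metal and
  its donors, harmonic angles V = ½k_θ(θ−θ₀)², and, for square-planar
  metals (Pd²⁺, Pt²⁺, Rh⁺, Ir⁺, Au³⁺, on by default), harmonic improper
  dihedrals centered on the donor atoms. Constants are extracted from the
  Hessian **H** of the saturated template by interatomic-block projection
  (Seminario): k_b = Σ_m λ_m |û_ij·v_m| with (λ_m, v_m) the eigenpairs of
  −H_ij, and angles from the two arms' in-plane perpendicular projections
  combined in series. Equivalent terms are symmetrized via graph
  automorphism classes.
* **residual charges** — Δq = q_RESP(complex) − q_RESP(isolated
  fragments), a zero-sum per-atom correction encoding metal→ligand charge
  transfer, added on top of the ligand force field's charges (the metal is
  reset to its integer formal charge first).
* **metal Lennard-Jones parameters** from a tabulated ion library
  (merz / zhang / uff source tags).

Applying a template to a new structure reduces the site to the template's
footprint (distance cutoff = template radius + 2 Å, then graph pruning)
and finds the atom bijection by exhaustive search over ligand assignments
× ligand-graph isomorphisms, keeping the Kabsch-minimal RMSD mapping;
mappings with RMSD ≥ 2 Å are rejected and the next template is tried.
See `docs/methods.md` for the full treatment and the method's measured
accuracy envelope.

## Worked example

The package ships deterministic synthetic fixtures; the `fixtures`
subcommand writes a complete input set for a [Pd₂L₄]⁴⁺ lantern cage —
coordinates, a metal-free toy topology, and the Hessian/ESP files from
which its vertex template is built:

```bash
metalff fixtures -o demo --kind pd2l4 --seed 11
metalff parameterize -f demo/input.pdb -p demo/input.top \
    -metal_and_charge Pd 2 -LJ_type merz \
    -template-library demo/library -o demo/out
```

which prints

```
INFO site 0 (Pd+2): template pd2_merz_pd2l4, RMSD 0.0000 A, running total charge 4.000000 e
INFO site 1 (Pd+2): template pd2_merz_pd2l4, RMSD 0.0000 A, running total charge 4.000000 e
INFO wrote demo/out.pdb and demo/out.top; total charge 4.000000 e (unchanged)
```

Both square-planar Pd sites matched the library template with RMSD
0.0000 Å (the cage and the template share the same idealized vertex
geometry) and the total charge of 4 e is unchanged — the residual charges
only redistribute charge. `demo/out.top` now contains four Pd–N bonds per
metal, the N–Pd–N angle terms, donor-centered funct-2 impropers, and a
`FPd` atom type carrying the merz-library σ/ε instead of the input
placeholder:

```
FPd 0 106.42 0 A 0.23216820594737242 0.0060091444799999999
```

Building a template from scratch uses the same files explicitly:

```bash
metalff build-template -f demo/input.pdb -metal_and_charge Pd 2 \
    --hessian demo/saturated.hessian --esp demo/template.esp \
    --esp-fragments demo/fragment_*.esp \
    --improper-scan demo/improper_scan.dat -o mylib/pd2_merz
```

The same workflows are available as a Python API
(`metalff.build_template`, `metalff.map_heavy_atoms`,
`metalff.patch_bonded`, …).

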