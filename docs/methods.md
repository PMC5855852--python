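# Methods

This note records the scientific model behind `qsar3d`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
benchmark does and does not demonstrate.

## Model overview

The package implements comparative molecular field analysis for a
congeneric series: molecules sharing a common scaffold are rigidly
superposed, a lattice of interaction descriptors is computed around them,
and partial least squares relates those descriptors to activity (pEC50,
−log10 of the molar EC50). Two descriptor families are supported:
probe-interaction energies (Lennard-Jones + Coulomb, the CoMFA family)
and Gaussian similarity indices (the CoMSIA family, free of energy
singularities at atom positions).

## Alignment

Superposition uses the Kabsch algorithm over a user-supplied core
substructure (SMARTS); the rotation is constrained to det(R)=+1 so a
mirror image is never produced. The supported contract is an explicit
core pattern rather than automatic maximum-common-substructure search:
MCS tie-breaking is ill-defined across implementations, while a declared
core is reproducible and matches how practitioners drive Distill-style
alignment. Symmetry-equivalent substructure matches (e.g. the two
traversal directions of a phenyl ring) are resolved by taking the
lexicographically smallest atom-index tuple; the choice is logged. Cores
must contain ≥3 non-collinear atoms or the superposition is rejected as
degenerate. Alignment is idempotent to ≤1e-9 Å.

## Fields

**Lattice.** Origin = minimum corner of the union bounding box minus the
margin; dims = ⌈extent/spacing⌉+1 per axis. Defaults: spacing 2.0 Å
(the customary lattice resolution), margin 4.0 Å — large enough that
clamped steric shells never touch the boundary for drug-sized molecules.
Column order is (field, then lattice point in C order), fixed and
deterministic.

**Probe fields.** The probe is an sp³-carbon analogue: radius 1.52 Å,
charge +1.0 e, well depth 0.107 kcal/mol. Steric:
`Σ_i ε_ip[(R_ip/r)¹² − 2(R_ip/r)⁶]`, `R_ip = r_vdw,i + r_probe`,
`ε_ip = √(ε_i ε_probe)`, clamped at +30 kcal/mol (points inside 0.01 Å
of an atom are set to the cutoff directly). Electrostatic:
`Σ_i 332.17 q_i q_p/(ε(r) r)` with the distance-dependent dielectric
ε(r) = r; clamped at ±30 kcal/mol. The Coulomb constant
332.17 kcal·Å/(mol·e²) and ε(r) = r are the common Sybyl-lineage
conventions. At sterically excluded points (steric at the cutoff) the
electrostatic value carries no information about that molecule; it is
replaced by the column mean over the non-excluded molecules (switchable
to raw clamping via `FieldConfig(elec_excluded="clamp")`).

**Similarity fields.** `A_F(q) = −Σ_i w_p w_i exp(−α r_iq²)` with
α = 0.3 Å⁻² (the literature default for Gaussian distance dependence)
and property weights: steric r_vdw³, electrostatic partial charge,
hydrophobic the atom-typed score, donor/acceptor 0/1 indicators. These
fields are finite everywhere including atom centers.

**Column filtering and scaling.** Columns with sample standard deviation
below `min_sigma` are dropped — default 2.0 kcal/mol for probe fields
(energy-unit noise floor), 0.0 for similarity fields, whose magnitudes
are far smaller; exactly-constant columns are always dropped since they
carry no information and break scaling. With `block_scaling="block_std"`
(default) each field block is divided by its pooled column standard
deviation `√(mean_j s_j²)` so that no field dominates the regression
simply by its units; this mirrors the standard CoMFA block scaling.

## Partial least squares

PLS1 by NIPALS on column-centered X and centered y (y is not
variance-scaled — activities are already on a common log scale).
Leave-one-out cross-validation refits on each n−1 subset; one NIPALS
pass per left-out sample yields predictions at every component count, so
the LOO scan costs n fits rather than n·c. q²(c) = 1 − PRESS(c)/SS_tot
with SS_tot about the full training mean. The optimal number of
components is the argmax of q² up to `max_components` (default 10), ties
to the smaller model; a conservative "5% relative improvement" rule is
available (`onc_rule="improve_5pct"`) since commercial implementations
have used either. Note the conventional q² includes the "1 −" term; a
perfect model scores 1, and q² > 0.5 is customarily read as significant.

Fit statistics at the chosen count c: r² = 1 − RSS/SS_tot,
SEE = √(RSS/(n−c−1)), F = [r²/(1−r²)]·[(n−c−1)/c]; a perfect fit flags
F as infinite rather than failing. Field contributions are
Σ_j |b_j s_j| within the field over the total, in percent; they sum to
100 by construction.

At full rank PLS reproduces ordinary least squares — the test suite
checks this against a normal-equations oracle and, separately, against
an independent PLS implementation.

## External validation and table auditing

r²_pred = (SD − PRESS)/SD where SD sums squared deviations of the test
activities about the **training-set** mean. `audit_table` applies the
same formulas directly to a printed actual/predicted activity table, so
published model statistics can be recomputed from the table alone. The
packaged 33-compound N-benzylbenzamide PPARγ table reproduces its
published statistics to within ±0.01 on r-type values and ±1% on F; the
residual discrepancy (e.g. recomputed r²_pred 0.725 vs printed 0.722)
is consistent with the 3-decimal rounding of the printed predictions and
is surfaced in the audit comparison record rather than absorbed.

## Contour maps

The contoured quantity is STDEV\*COEFF: per active column, the product
of descriptor standard deviation and PLS coefficient, mapped to its
lattice point (masked columns are zero). Iso-levels default to the
80th/20th percentiles of the nonzero values — the customary display
convention; the true iso-values behind any particular published figure
are not recoverable, so only sign/percentile semantics are asserted.
Maps are computed on the scaled descriptor space and de-scaled by the
block factor for export (default), so values across fields share raw
field units. Export is a minimal OpenDX regular scalar field (origin,
deltas, counts, values in C order), readable by common visualizers.

## Synthetic generator

`SyntheticSpec`/`generate_set` emulate the statistical structure of a
congeneric QSAR study: a rigid N-benzylbenzamide-like core (embedded 3D
once with a fixed conformer seed — the geometry is part of the study
definition), three benzyl-ring decoration sites where hydrogens are
replaced by single-atom substituents from a palette (H, C, N, O, F, S,
Cl, Br) at typical bond lengths, activities
`pEC50 = 5.0 + Σ β·prop(substituent) + N(0, 0.1²)` with a purely steric
default plant (β = 0.25 and 0.15 pEC50/Å³-scaled units at sites 0 and
1), and a seed-deterministic 82/18 train/test split stratified by
activity tertile so both sets span the activity range. Each molecule is
scattered by a random rigid motion that the alignment stage must undo.
Defaults give 33 molecules (27 train / 6 test) with activities spanning
roughly 5–7.5 pEC50 units — the scale of a typical published series.

What the generator does **not** emulate: conformational flexibility,
real substituent chemistry (substituents are single-atom parameter
bundles), activity cliffs, measurement-error structure beyond i.i.d.
Gaussian noise, or inter-site cooperativity. Passing recovery tests
therefore demonstrates that the pipeline's statistics are internally
sound and that planted linear field effects are recovered — not that any
particular real series will yield a predictive model.

## Benchmark problem sizes

The acceptance computation uses 20 generated series of 30 molecules at
σ = 0.1 and reports medians; a single series builds in well under a
second, so the statistics are stable without larger designs. The table
audit is exact arithmetic on 33 rows.

## Known limitations

- Gasteiger PEOE σ-charges only; the Hückel π refinement of the combined
  scheme is not applied (the flag is the `assign_gasteiger_charges`
  entry point itself — swap in any charge column via MOL2 input).
- Donor/acceptor geometry is isotropic (no lone-pair directionality).
- Atom parameters are element-level tables (Tripos-like radii and well
  depths, an atom-typed hydrophobicity rule); both are replaceable CSVs.
- Rigid alignment only; conformer generation and torsional fitting are
  upstream of this package.
- Exact numeric agreement with proprietary field implementations is out
  of scope; what is reproduced is the statistical machinery (PLS, LOO,
  r²_pred, contributions) and documented field functional forms.
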