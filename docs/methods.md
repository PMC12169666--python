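# Methods

This note documents the models, numerical choices and limitations of
`ronsff`, in the order a user meets them: the parameter database, the
energy model, the conformer machinery, the thermodynamic
post-processing, topology emission, and the solution analyses.

## Parameter database

The database lives in three YAML files under `ronsff/data/`:
`atom_types.yaml` (nonbonded types), `c12_matrix.yaml` (repulsion-slot
selection), `molecules.yaml` (the 15 molecular topologies).  Units are
GROMACS conventions throughout: nm, kJ/mol, degrees at interfaces
(radians internally), charges in e, and the Coulomb prefactor
1/(4πε₀) = 138.935458 kJ·mol⁻¹·nm·e⁻².

**Multi-slot C12.**  GROMOS-family force fields give each atom type up
to three repulsive C12 parameters; which slot applies depends on the
partner (roughly: slot 1 for apolar partners, 2 for polar/hydrogen-bond
partners, 3 for charged contacts).  The cross C12 therefore cannot be
generated by a single combination rule; it is a table lookup followed
by a geometric product.  `combine_c12` raises an explicit
"unparametrized pair" error for a pair with no selection entry or no
bundled values — silent fallbacks would produce physically wrong
repulsion without any warning.

**Standard partner types.**  The four RONS-specific types (OP, OO, OQ,
NQ) carry their full published parameter sets.  The surrounding GROMOS
53A6 types are engine-side data; we bundle the subset needed by the
molecular topologies (H, O, OM, NR) plus the common solvent/validation
partners (OW, CH2, CH3, CH2r, C, N, OA, AR).  The selection matrix
covers the full partner list, including lipid (OML, CH3L) and ion
types, so extending the LJ table from an engine's 53A6 database
immediately yields the corresponding pair rows.  Slot-2/3 entries of
the bundled standard types should be cross-checked against the user's
engine database before production use; they affect emitted pair tables
only, not any quantity this package computes.

**Exclusions.**  Built from the bond graph: distance-1/2 pairs are
excluded; distance-3 pairs become 1-4 pairs (modified C12, full
charges) when the central bond carries a cosine-series torsion and are
fully excluded (both LJ and Coulomb) when it carries an RB torsion.
One species overrides this rule: in ONOO⁻ the terminal-oxygen pair is
fully excluded although its torsion is a cosine series.  The anion's
O–N–O–O potential was calibrated to place the trans form 13–15 kJ/mol
above cis in vacuum; the −0.335 e / −0.614 e terminal charges would
contribute a ~28 kJ/mol extra Coulomb penalty to the cis form if kept
as a 1-4 interaction and would invert that ordering.  The calibration
therefore subsumes the intramolecular terminal-oxygen interaction, and
the topology carries an `exclude_14` flag.

**Data provenance quirks.**  The HOONO N–O–O–H torsion is stored as a
four-term Fourier series with multiplicities 1–4; a degenerate
all-m=1 reading collapses to a single cosine and cannot produce the
observed perpendicular minima, while the 1–4 series reproduces the full
conformer ladder (see below).  The HNO3 reference angles are mutually
inconsistent by 0.02° in the planar closure (130.22 + 2×114.90 =
360.02), so the "all terms at minimum" reference retains a ~1e-4 kJ/mol
bending residual — harmless, but visible at tight tolerances.

## Energy model

`molecule_energy` evaluates all bonded terms plus nonbonded terms over
non-excluded pairs, returning a term-by-term breakdown whose `total` is
exactly the component sum.  Constrained bonds contribute zero energy
and their stretching constants are never used (they are placeholders
for engine compatibility; the models are meant to run with bond
constraints).  Improper force constants are interpreted per radian²;
the improper coordinate is the signed dihedral of the listed quadruple.
Dihedrals follow the IUPAC sign convention (cis = 0, value in
(−180°, 180°], sign flips under reflection); the RB argument is
φ − 180° exactly.  1-4 Coulomb interactions are full strength — only
C12 (and C6, via the 1-4 tables) is modified.

Pair parameters per species are cached keyed on the topology's types,
charges and exclusion lists, so repeated evaluations during
minimization cost only the geometry work.

## Conformer tools

**Rigid bonds by construction.**  Minimization runs in internal
coordinates: a placement tree (Z-matrix) is derived from the bond
graph, bond lengths are pinned at their reference values, and the free
variables are the placement angles and dihedrals.  For these ≤ 6-atom
molecules this satisfies the bond constraints exactly and keeps the
optimization smooth and low-dimensional (e.g. five variables for
HOONO).  The optimizer is BFGS with central-difference gradients
(step 1e-6 rad), a fixed start, and no randomness; results are
bit-reproducible.  Convergence is declared below a gradient norm of
1e-6 kJ·mol⁻¹·deg⁻¹; non-convergence is flagged on the result, never
silent.  Selected dihedrals can be pinned (removed from the variable
set) or restrained harmonically.

**HOONO conformer protocol.**  Starts are the ab initio reference
internals.  The four planar conformers (cis-cis, cis-trans, trans-cis,
trans-trans) are stationary in both dihedrals by symmetry and minimize
freely, as does trans-perp, a true minimum of the classical surface.
cis-gauche is not a separate minimum of the classical model — a free
minimization drains into the adjacent perp well — so cis-gauche and
cis-perp are characterized with the N–O–O–H dihedral held at the
nominal conformer values (50° and 90°), and the perp-perp ridge
structure with O–N–O–O held at 95°.  A result whose free dihedrals
drift more than 30° from the start is flagged as a basin escape.
Under this protocol the eight relative energies are
0 / 3.33 / 1.40 / 12.31 / 55.09 / 25.04 / 13.36 / 20.98 kJ/mol.

**Scans and fitting.**  `torsion_scan` evaluates either the bare
torsional potential or the fully relaxed molecule at pinned dihedral
values, walking the grid with continuation from the previous point.
`fit_dihedral_terms` least-squares fits a cosine series or RB
polynomial to a residual profile (target minus torsionless classical),
with a constant column absorbing the offset; a rank-deficient design
(e.g. multiplicities indistinguishable on the supplied grid) raises.

## Thermodynamic post-processing

TI solvation free energies are quadratures of tabulated ⟨∂H/∂λ⟩ curves,
one leg per interaction class (Coulomb decoupled first, then LJ), with
ΔG = −(∫C + ∫LJ).  The default is the composite trapezoid on the
supplied grid — the λ schedules these datasets come from (21- and
51-point) are dense enough that refitting would add model error, not
remove it; Simpson quadrature is available as an option.  Grids must be
strictly increasing in [0, 1] with both endpoints present.

The heat of vaporization is U_gas − U_liq + RT with
R = 8.314462618e-3 kJ·mol⁻¹·K⁻¹ and T defaulting to 298 K.

For a solute with cis and trans torsional conformers separated by a
barrier too high to cross on TI time scales, the observable hydration
free energy follows from a two-state cycle combining the per-conformer
hydration free energies with the gas-phase isomerization free energy
ΔG_i.  ΔG_i is derived from the bare torsional potential, by default as
the difference of the two basin minima (cis basin |φ| < 90°); a
Boltzmann-integral mode (−RT ln Z_cis/Z_trans over the basins) is also
provided and reduces to the minima mode as T → 0.  For HNO2 the minima
mode gives ΔG_i = 1.556 kJ/mol and, with per-conformer values −18.0
(trans) and −11.2 (cis) kJ/mol at 298 K, a weighted hydration free
energy of −17.0 kJ/mol.  The minima definition is the default because
the torsional wells here are narrow and similar in curvature, making
the partition-function correction small (≈0.3 kJ/mol for HNO2).

## Topology emission

Molecule blocks use standard .itp sections (atoms, constraints, angles
funct 2, proper dihedrals funct 1/funct 3, impropers funct 2, explicit
pairs with their C6/C12, explicit exclusions with `nrexcl 0`).  1-4
pairs are written with explicit parameters rather than left to
engine-side pairtype generation — the only dialect-safe way to honour
the modified 1-4 C12 values.  Nonbonded tables are emitted as explicit
per-pair rows for the same reason (multi-slot C12 defeats single
combination rules).  Numbers are printed at full precision (`%.10g`)
and emission is byte-stable under write → read → write.  C6/C12 form is
kept throughout; converting to σ/ε would destroy the multi-C12
semantics.  The 54A7 variant emits the same molecular parameters
(unchanged between frameworks) and omits pair rows for the types whose
LJ parameters the 54A7 engine database supplies (updated Na⁺/Cl⁻,
native lipid types), flagging them in the header.

The bundled reader parses exactly this dialect, rejects unknown
directives, and re-validates charge sums on load; it exists for
round-trip verification, not as a general parser.

## Solution analysis

RDFs are minimum-image pair histograms in orthorhombic boxes,
normalized per frame by the ideal-gas shell expectation
(4/3)π(r₊³−r₋³)·N_pairs/V, with r_max capped at half the smallest box
edge.  The default bin width (0.002 nm) resolves first-minimum
positions; it is configurable.  First-shell cutoffs are the first local
minimum after the global first peak of the curve smoothed with a fixed
3-bin moving average (a deterministic, documented choice; no smoothing
rule is standard).  The degree of ionization counts an ion as paired
when at least one counterion lies within the cutoff — coordination-
count variants are out of scope.  Analyses operate on a plain FrameSet
(positions, box, labels) fillable from multi-frame XYZ/GRO files.

The fixture generator emulates limiting cases with exact expectations:
ideal-gas frames (g(r) → 1), simple-cubic lattices (δ-peaks at known
shells), and ion/counterion sets with an exact constructed paired
fraction.  These fixtures validate the estimators' normalization and
counting; they do not emulate solvation-shell structure, concentration
effects or dynamics, so passing them says nothing about the physical
accuracy of any particular simulation — that is what the force-field
validation against liquid and solvation benchmarks is for, and it
requires external MD.

## Scope and limitations

* Single-molecule gas-phase energetics only: no periodic boundary
  conditions, cutoffs, PME or solvent in the energy model.  Condensed-
  phase observables (densities, solvation free energies) require
  running the emitted topologies in an MD engine; this package prepares
  inputs for and post-processes outputs of such runs.
* No conformer search: conformer lists are user-specified.
* No small-molecule typing engine: only the 15 bundled species plus
  user-supplied topologies in the same schema.
* The O2 and ·O2⁻ models have no polarizability or multipole sites;
  united-atom symmetry forces zero (O2) or half-charge (·O2⁻)
  distributions.
* The torsional-isomerization free energy uses the bare torsional
  potential; coupling to angle relaxation along the path is neglected
  (small for the narrow wells involved).
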