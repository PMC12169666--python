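# ronsff

A GROMOS-compatible united-atom force-field toolkit for **reactive
oxygen and nitrogen species (RONS)** — H2O2, O2, HO2·, HO·, O3, N2O4,
·NO2, ·NO, HOONO, HNO3, HNO2, NO3⁻, NO2⁻, ·O2⁻ and ONOO⁻.

RONS drive redox signalling, oxidative stress and aerosol chemistry,
but their transience makes them hard to probe experimentally; molecular
dynamics fills that gap when validated classical models exist.  This
package is for simulators who want to deploy such a parameter set in an
MD engine and for force-field developers who want to inspect, validate
and extend it.  It provides:

* **Parameter database** (`ronsff.params`) — the complete bonded and
  nonbonded parameter set for the 15 species as machine-readable YAML,
  with the multi-slot C12 combination logic and a validator.
* **Energy model** (`ronsff.energy`) — gas-phase potential-energy
  evaluation with a term-by-term breakdown.
* **Conformer tools** (`ronsff.conformers`) — rigid-bond minimization
  in internal coordinates, torsional scans, dihedral-term fitting.
* **Thermodynamics** (`ronsff.thermo`) — thermodynamic-integration
  quadrature, heat of vaporization, conformer-weighted hydration free
  energies.
* **Topology emission** (`ronsff.gmxio`) — GROMACS-dialect `.itp`
  blocks and explicit nonbonded tables (53A6 and 54A7 variants), with a
  strict round-trip reader.
* **Solution analysis** (`ronsff.analysis`) — minimum-image RDFs,
  first-shell cutoffs and ion-pairing degree of ionization.

## The model

The potential energy is the GROMOS functional form

```
V = Σ ¼ K_b (b² − b₀²)²                       bond stretching (constrained in practice)
  + Σ ½ K_θ (cos θ − cos θ₀)²                 angle bending
  + Σ ½ K_ξ (ξ − ξ₀)²                         improper (out-of-plane) dihedrals
  + Σ_i K_φi [1 + cos(m_i φ − φ₀i)]           proper dihedrals (cosine series)
    or Σ_{i=0..5} C_i cosⁱ(φ − 180°)          (Ryckaert–Bellemans form)
  + Σ_pairs C₁₂/r¹² − C₆/r⁶ + q_i q_j /(4πε₀ r)   nonbonded
```

Cross-type Lennard-Jones parameters use geometric combination,
`C₆(i,j) = √C₆(i,i)·√C₆(j,j)`, and likewise for C₁₂ — except that each
atom type carries up to three C₁₂ values and a selection matrix picks
the slot per pair (e.g. the OP–OQ pair combines OP's slot 2 with OQ's
slot 3).  First and second bonded neighbours are excluded; third
neighbours interact with modified C₁₂ ("1-4 pairs") when the connecting
torsion is a cosine series, and are fully excluded when it is an RB
torsion.

## Worked example

The skewed equilibrium of hydrogen peroxide and the HOONO conformer
ladder, straight from the library:

```python
import numpy as np
from ronsff import default_database, minimize_rigid_bonds

db = default_database()
h2o2 = db.get_topology("H2O2")
res = minimize_rigid_bonds(h2o2, {"dihedrals": {(3, 1, 0, 2): 60.0}}, db=db)
print(round(res.dihedrals[(2, 0, 1, 3)], 1))   # -> 112.5
```

The H–O–O–H dihedral relaxes to 112.5°, the skewed minimum of the
peroxide torsional potential (the planar cis and trans arrangements are
barriers of 30.45 and 4.51 kJ/mol).

```
$ rons-ff conformers HOONO
conformer     dE (kJ/mol)  ONOO (deg)  NOOH (deg)  converged
cis-cis              0.00         0.0         0.0  True
cis-gauche           3.33        -3.6        50.0  True
cis-perp             1.40        -2.5        90.0  True
cis-trans           12.31         0.0       180.0  True
perp-perp           55.09        95.0       102.4  True
trans-cis           25.04       180.0         0.0  True
trans-perp          13.36      -179.0       103.0  True
trans-trans         20.98       180.0       180.0  True
```

Each row is a rigid-bond energy minimization of peroxynitrous acid
started from the ab initio reference geometry of that conformer; `dE`
is the energy relative to the cis-cis global minimum, and the two
columns give the O–N–O–O and N–O–O–H dihedrals at convergence.  The
cis-cis form is stabilized by the intramolecular O···H contact; the
trans family sits 13–25 kJ/mol higher.

Other entry points: `rons-ff validate` (database invariants),
`rons-ff scan ONOO- 0 1 2 3` (torsional profiles), `rons-ff
ti-integrate --coulomb c.dat --lj lj.dat` (free-energy quadrature of
two-column λ files), `rons-ff write-topology HNO3` and `rons-ff
write-nonbonded --variant 54A7` (engine-ready parameter files),
`rons-ff rdf`/`ionpairs` (trajectory analyses).

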