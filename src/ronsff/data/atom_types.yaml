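# Nonbonded atom-type database, GROMOS-RONS force field.
#
# Units: mass in a.m.u.; sqrt_c6 in (kJ mol^-1 nm^6)^1/2;
# sqrt_c12 entries in (kJ mol^-1 nm^12)^1/2 (up to three slots per type,
# selected per pair via the C12 selection matrix in c12_matrix.yaml).
# sqrt_c6_14 / sqrt_c12_14 are the modified parameters used for
# third-neighbour (1-4) interactions across GROMOS-type proper dihedrals.
#
# The four RONS-specific types (OP, OO, OQ, NQ) carry the full published
# multi-slot C12 sets.  The `standard` section is the subset of the
# GROMOS 53A6 nonbonded database needed by the bundled molecule set and
# by the common solvent/validation partners (water OW, united-atom
# hydrocarbons, argon, Na+).  Users combining the RONS types with other
# 53A6 partner types should extend this file from their engine's full
# 53A6 tables; the selection matrix already covers every partner type.

rons_types:
  OP:
    mass: 15.999
    description: OH-group oxygen in hydrogen peroxide, oxyradicals and nitrogen oxyacids
    sqrt_c6: 0.04756
    sqrt_c12: [1.334e-3, 1.334e-3]
    sqrt_c6_14: 0.04756
    sqrt_c12_14: 1.334e-3
  OO:
    mass: 15.999
    description: oxygen in molecular oxygen and nitric oxide
    sqrt_c6: 0.018963
    sqrt_c12: [0.33329e-3]
  OQ:
    mass: 15.999
    description: oxygen in ozone, nitrogen oxides and nitrogen oxyacids
    sqrt_c6: 0.035765
    sqrt_c12: [1.000e-3, 0.834e-3, 1.784e-3]
    sqrt_c6_14: 0.035765
    sqrt_c12_14: 0.834e-3
  NQ:
    mass: 14.007
    description: nitrogen in nitrogen oxides and nitrogen oxyacids
    sqrt_c6: 0.035765
    sqrt_c12: [1.000e-3, 0.834e-3]

standard:
  # Polar hydrogen is LJ-null in GROMOS (pure Coulomb site).
  H:
    mass: 1.008
    description: polar hydrogen (LJ-null)
    sqrt_c6: 0.0
    sqrt_c12: [0.0]
    sqrt_c6_14: 0.0
    sqrt_c12_14: 0.0
  O:
    mass: 15.999
    description: carbonyl / terminal oxygen
    sqrt_c6: 0.04756
    sqrt_c12: [1.000e-3, 1.130e-3]
    sqrt_c6_14: 0.04756
    sqrt_c12_14: 1.000e-3
  OM:
    mass: 15.999
    description: negatively charged (carboxylate-like) oxygen
    sqrt_c6: 0.04756
    sqrt_c12: [0.8611e-3, 1.841e-3, 3.068e-3]
    sqrt_c6_14: 0.04756
    sqrt_c12_14: 0.8611e-3
  OA:
    mass: 15.999
    description: hydroxyl oxygen
    sqrt_c6: 0.04756
    sqrt_c12: [1.100e-3, 1.227e-3]
    sqrt_c6_14: 0.04756
    sqrt_c12_14: 1.100e-3
  OW:
    mass: 15.999
    description: SPC water oxygen
    sqrt_c6: 0.05116
    sqrt_c12: [1.623e-3, 1.623e-3, 1.623e-3]
    sqrt_c6_14: 0.05116
    sqrt_c12_14: 1.623e-3
  N:
    mass: 14.007
    description: amide/amine nitrogen
    sqrt_c6: 0.04936
    sqrt_c12: [1.523e-3, 1.943e-3]
    sqrt_c6_14: 0.04936
    sqrt_c12_14: 1.523e-3
  NR:
    mass: 14.007
    description: aromatic / planar-fragment nitrogen
    sqrt_c6: 0.04936
    sqrt_c12: [1.523e-3, 1.841e-3]
    sqrt_c6_14: 0.04936
    sqrt_c12_14: 1.523e-3
  C:
    mass: 12.011
    description: bare carbon
    sqrt_c6: 0.04838
    sqrt_c12: [2.222e-3]
  CH2:
    mass: 14.027
    description: united-atom CH2
    sqrt_c6: 0.08642
    sqrt_c12: [5.828e-3]
  CH3:
    mass: 15.035
    description: united-atom CH3
    sqrt_c6: 0.09805
    sqrt_c12: [5.162e-3]
  CH2r:
    mass: 14.027
    description: united-atom CH2 in rings (cyclohexane)
    sqrt_c6: 0.08018
    sqrt_c12: [5.077e-3]
  AR:
    mass: 39.948
    description: argon
    sqrt_c6: 0.07915
    sqrt_c12: [3.138e-3]
  DUM:
    mass: 0.0
    description: dummy site (LJ-null)
    sqrt_c6: 0.0
    sqrt_c12: [0.0]
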