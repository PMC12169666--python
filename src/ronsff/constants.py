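"""Physical constants and unit conventions.

The package works in GROMACS-compatible units throughout: lengths in
nm, energies in kJ/mol, angles in degrees at interfaces (radians
internally), charges in units of the elementary charge e.
"""

#: Coulomb prefactor 1/(4*pi*eps0), kJ mol^-1 nm e^-2.
COULOMB_FACTOR = 138.935458

#: Molar gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314462618e-3

#: Default temperature for thermodynamic post-processing, K.
T_DEFAULT = 298.0
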