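"""Physical constants and unit conversions.

All Hamiltonian matrix elements are stored in eV, transition dipoles in
atomic units, coordinates in Angstrom.  Every conversion in the package
goes through this table.
"""

HARTREE_EV = 27.211386245988
BOHR_ANGSTROM = 0.529177210903
ANGSTROM_BOHR = 1.0 / BOHR_ANGSTROM
EV_NM = 1239.8419843320026  # h*c in eV*nm
SPEED_OF_LIGHT_AU = 137.035999084
# 1 a.u. of rotational strength in units of 1e-40 erg*esu*cm/Gauss
ROTSTR_AU_TO_CGS40 = 471.44360

# Heavy-atom masses (u) for base centres of mass.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
}

# Defaults committed by the method description: empirical red shift that
# aligns the computed monomer spectrum with experiment, and the
# phenomenological Gaussian broadening.
DEFAULT_SHIFT_EV = -0.85
DEFAULT_SIGMA_EV = 0.21

# Default sizes of the adiabatic manifolds used when parametrizing from a
# quantum-chemistry upstream: pairs are projected onto 40 adiabatic states,
# 3-G strands / tetrads onto 30, 6-G strands onto 50.
DEFAULT_N_ADIABATIC_PAIR = 40
DEFAULT_N_ADIABATIC_STRAND = 30
DEFAULT_N_ADIABATIC_LONG_STRAND = 50
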