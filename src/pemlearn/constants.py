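"""Physical constants and unit conversions (CODATA-2018 values).

All internal sampling is done in Hartree atomic units (hbar = 1).
"""

# 1 hartree in eV
HARTREE_TO_EV = 27.211386245988

# 1 bohr in Angstrom
BOHR_TO_ANGSTROM = 0.529177210903

# wavenumber (cm^-1) to angular frequency / energy in atomic units
# (hbar = 1, so omega[au] is numerically the photon energy in hartree)
CM1_TO_AU = 4.556335252912e-6

# Boltzmann constant in hartree / kelvin
KB_AU = 3.166811563e-6

# atomic mass unit (dalton) in electron masses
AMU_TO_ME = 1822.888486209

# standard atomic masses (dalton) for the elements used in examples
ATOMIC_MASSES = {
    "H": 1.00794,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403,
}
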