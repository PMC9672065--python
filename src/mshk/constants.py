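"""Physical constants and unit conversions.

Internal unit system: length in Angstrom, time in fs, mass in amu,
energy in kcal/mol.  The single derived constant needed by the MD
integrators converts kcal/mol into the mechanical unit amu*A^2/fs^2.
"""

from __future__ import annotations

# CODATA 2018
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

_J_PER_KCAL = 4184.0
_AVOGADRO = 6.02214076e23
_AMU_KG = 1.66053906660e-27

# 1 amu * (A/fs)^2 expressed in J/mol
_MECH_J_PER_MOL = _AMU_KG * 1.0e10 * _AVOGADRO

#: kcal/mol -> amu * A^2 / fs^2
KCAL_MOL_TO_MECH = _J_PER_KCAL / _MECH_J_PER_MOL
#: amu * A^2 / fs^2 -> kcal/mol
MECH_TO_KCAL_MOL = 1.0 / KCAL_MOL_TO_MECH

#: Boltzmann constant in kcal/(mol K)
KB_KCAL_MOL = 0.001987204259

EV_TO_KCAL_MOL = 23.060547830619026
HARTREE_TO_KCAL_MOL = 627.5094740631

#: Standard atomic weights (amu) for the elements this package handles.
ATOMIC_MASSES = {
    1: 1.008,
    6: 12.011,
    7: 14.007,
    8: 15.999,
    9: 18.998,
    16: 32.06,
}

ELEMENT_SYMBOLS = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 16: "S"}
SYMBOL_TO_Z = {v: k for k, v in ELEMENT_SYMBOLS.items()}
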