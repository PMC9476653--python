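"""Unit system and physical constants.

Internal units throughout the package:

========== =================
length     angstrom (A)
energy     kJ/mol
charge     elementary charge e
dipole     e*A  (reported in debye where noted)
time       ps   (configs accept fs for timesteps)
mass       amu (g/mol)
velocity   A/ps
========== =================

All unit conversions are fixed here and nowhere else.
"""

from __future__ import annotations

import math

# Coulomb constant e^2/(4 pi eps0) expressed in kJ*A/(mol*e^2):
# 8.9875517923e9 N m^2/C^2 * (1.602176634e-19 C)^2 * 6.02214076e23 /mol
# = 1389.35457644 kJ*A/mol.
COULOMB = 1389.3545764438197

#: 1 e*A in debye.
EA_TO_DEBYE = 4.803205

#: Boltzmann constant in kJ/(mol*K).
KB = 0.008314462618153239

#: 1 amu*(A/ps)^2 in kJ/mol (kinetic-energy conversion).
MV2_TO_KJMOL = 0.01

#: 1 kJ/(mol*A^3) in atm (pressure conversion).
KJMOLA3_TO_ATM = 1.0e3 / 6.02214076e23 / 1.0e-30 / 101325.0

#: hbar in kJ*ps/mol  (1.0546e-34 J*s x N_A -> kJ/mol, s -> ps).
HBAR = 1.054571817e-34 * 6.02214076e23 * 1e-3 * 1e12

#: speed of light in cm/ps, for wavenumber conversion (0.0299792458).
C_CM_PER_PS = 2.99792458e8 * 100.0 * 1e-12

MASS_O = 15.999
MASS_H = 1.008
WATER_MASS = MASS_O + 2.0 * MASS_H

DEG = math.pi / 180.0
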