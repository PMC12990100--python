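"""Physical constants and the unit-conversion table.

Internal unit system (all modules):

=========  ==============  =========================================
quantity   internal unit   notes
=========  ==============  =========================================
length     angstrom (A)
time       femtosecond
energy     eV
mass       eV fs^2 A^-2    1 amu = 103.642697 eV fs^2 A^-2
charge     elementary e
field      V A^-1
force      e V A^-1        numerically identical to eV A^-1
current    e A^-2 fs^-1    density; -> A m^-2 multiply by CURRENT_SI
=========  ==============  =========================================

Every conversion factor used anywhere in the package lives here.
"""

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # mol^-1
KB_EV = 8.617333262e-5  # Boltzmann constant, eV K^-1
FARADAY = 96485.332  # C mol^-1
GAS_CONSTANT = 8.31446  # J mol^-1 K^-1
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # cm s^-1

# mass: 1 amu expressed in eV fs^2 A^-2
AMU_TO_INTERNAL = 1.66053906660e-27 / (ELEMENTARY_CHARGE * 1e-30 / 1e-20)

# Coulomb constant e^2/(4 pi eps0) in eV A
COULOMB_EV_A = 14.3996454

# diffusion: A^2 fs^-1 -> m^2 s^-1
D_TO_SI = 1e-20 / 1e-15

# current density: e A^-2 fs^-1 -> A m^-2
CURRENT_SI = ELEMENTARY_CHARGE / (1e-20 * 1e-15)

# field: V A^-1 -> V m^-1
FIELD_SI = 1e10

# conductivity slope (e A^-2 fs^-1 per V A^-1) -> S m^-1
CONDUCTIVITY_SI = CURRENT_SI / FIELD_SI

# speed of light in cm fs^-1 (for wavenumber <-> frequency conversion)
SPEED_OF_LIGHT_CM_FS = SPEED_OF_LIGHT_CM_S * 1e-15

WATER_MOLAR_MASS = 18.01528  # g mol^-1
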