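"""Physical constants and unit conversions.

Internal unit system follows classical-MD convention: lengths in Å,
time in fs, energy in kJ/mol, mass in amu (g/mol), charge in units of
the elementary charge.  Plasma quantities use eV for temperatures and
cm^-3 for densities, the units in which they are usually quoted.
"""

from scipy import constants as _c

# Coulomb constant e^2/(4 pi eps0) in kJ mol^-1 Å (per e^2)
KE_KJ_A = _c.e**2 / (4.0 * _c.pi * _c.epsilon_0) * _c.Avogadro / 1e3 * 1e10

# acceleration conversion: (kJ/mol/Å) / amu  ->  Å/fs^2
ACC_UNIT = 1e-4
# kinetic energy conversion: amu (Å/fs)^2 -> kJ/mol
KIN_UNIT = 1e4

BOLTZMANN_KJ_MOL_K = _c.k * _c.Avogadro / 1e3   # kJ/mol/K
EV_TO_KJ_MOL = _c.e * _c.Avogadro / 1e3          # 96.485...
EV_TO_K = _c.e / _c.k                            # 11604.5...

# Debye length prefactor: lambda_D [Å] = DEBYE_PREF * sqrt(T_e[eV] / n_e[cm^-3])
# from sqrt(eps0 * k_B T / (n e^2)); with T in eV this is sqrt(eps0 T_eV / (n_cm3 e))
import math as _math

DEBYE_PREF = _math.sqrt(_c.epsilon_0 / (_c.e * 1e6)) * 1e10  # ≈ 7.434e10 Å per sqrt(eV cm^3)

PLANCK_EVS = _c.h / _c.e                         # eV s
HC_EV_A = _c.h * _c.c / _c.e * 1e10              # eV Å (≈ 12398.4)

MASS_AMU = {"O": 15.999, "H": 1.008}
ATOMIC_NUMBER = {"O": 8, "H": 1}
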