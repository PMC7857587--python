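"""Physical constants shared by the DEER and PRE back-calculations.

CODATA 2018 values in SI units. The electron g-factor is the effective
isotropic g of a nitroxide radical, approximated by the free-electron value
as is conventional in DEER distance analysis.
"""

import numpy as np

#: vacuum permeability, N A^-2
MU_0 = 1.25663706212e-06
#: Bohr magneton, J T^-1
MU_B = 9.2740100783e-24
#: reduced Planck constant, J s
HBAR = 1.054571817e-34
#: Boltzmann constant, J K^-1
K_B = 1.380649e-23
#: electron g-factor (nitroxide, free-electron approximation)
G_E = 2.0023
#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.67522187e8
#: electron spin quantum number of a nitroxide
S_E = 0.5
#: molar gas constant, kJ mol^-1 K^-1 (kJ/mol -> kT conversions)
R_KJ_MOL = 8.3145e-3

#: dipolar-frequency prefactor (mu0/4pi) g^2 muB^2 / hbar, rad s^-1 m^3;
#: omega(r) = DIPOLAR_PREFACTOR / r^3 with r in metres
DIPOLAR_PREFACTOR = MU_0 / (4.0 * np.pi) * G_E**2 * MU_B**2 / HBAR

#: Solomon-Bloembergen transverse-PRE prefactor
#: (1/15) (mu0/4pi)^2 gammaI^2 g^2 muB^2 s_e(s_e+1), m^6 s^-2;
#: Gamma_2 = PRE_PREFACTOR * <r^-6> * [4 J'(0) + 3 J'(omega_I)] with the
#: radial factor <r^-6> in m^-6 split out of the spectral density J = <r^-6> J'
PRE_PREFACTOR = (
    (1.0 / 15.0)
    * (MU_0 / (4.0 * np.pi)) ** 2
    * GAMMA_H**2
    * G_E**2
    * MU_B**2
    * S_E
    * (S_E + 1.0)
)


def kt_kj_mol(temperature: float) -> float:
    """Thermal energy k_B T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_MOL * temperature
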