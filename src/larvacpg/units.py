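"""Unit contract and conversion constants.

All public interfaces use the following units, chosen to match the way the
model's parameters are conventionally printed:

==============  ==========================
quantity        unit
==============  ==========================
time            ms
voltage         mV
current         nA
conductance     mS cm^-2 (densities), uS (totals)
capacitance     uF cm^-2 (densities), nF (totals)
area            cm^2
[Ca2+]_i        nM
[Ca2+]_e        mM
temperature     K
==============  ==========================

With total conductance in uS and voltage in mV, Ohmic currents come out
directly in nA (uS * mV = nA), and with total capacitance in nF the membrane
time constant C/g is in ms (nF / uS = ms).  These two identities are the whole
reason for the choice; every conversion lives in this module and nowhere else.
"""

import math

# Physical constants (SI)
GAS_CONSTANT = 8.314462618  # J K^-1 mol^-1
FARADAY = 96485.33212  # C mol^-1
CA_VALENCE = 2

# Density -> total conversions for a membrane area given in cm^2:
#   g_total[uS] = g_density[mS cm^-2] * area[cm^2] * MS_TO_US
#   C_total[nF] = C_density[uF cm^-2] * area[cm^2] * UF_TO_NF
MS_TO_US = 1e3
UF_TO_NF = 1e3

MM_TO_NM = 1e6  # mM -> nM
V_TO_MV = 1e3

UM_TO_CM = 1e-4


def sphere_area_cm2(diameter_um: float) -> float:
    """Surface area of a spherical compartment, cm^2, from diameter in um.

    pi * d^2 is the sphere surface (equivalently 4 pi r^2).
    """
    d_cm = diameter_um * UM_TO_CM
    return math.pi * d_cm * d_cm


def nernst_prefactor_mv(temperature_k: float) -> float:
    """R*T / (z*F) for Ca2+ (z = 2), expressed in mV."""
    return GAS_CONSTANT * temperature_k / (CA_VALENCE * FARADAY) * V_TO_MV
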