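"""Physical constants and the unit conversions used across the package.

All CODATA 2018 values, taken from :mod:`scipy.constants` so the derived
numbers in the tests are reproducible to machine precision.

Unit contract (kept consistent everywhere):

* membrane potential        mV
* conductance               nS
* current                   pA          (nS x mV = pA, no factor needed)
* capacitance               pF / fF
* molar rate                mol s^-1, also reported as molecules s^-1
"""

from scipy import constants as _c

#: Faraday constant, C mol^-1
FARADAY = _c.physical_constants["Faraday constant"][0]

#: molar gas constant, J mol^-1 K^-1
R_GAS = _c.R

#: elementary charge, C
E_CHARGE = _c.e

#: Avogadro constant, mol^-1
AVOGADRO = _c.N_A

# scale factors into SI
PA_TO_A = 1e-12
MV_TO_V = 1e-3
PF_TO_F = 1e-12
FF_TO_F = 1e-15
NM_TO_CM = 1e-7
PL_TO_ML = 1e-9
UG_TO_G = 1e-6
PMOL_TO_MOL = 1e-12

#: 1 uF/cm^2 expressed in F/cm^2
UF_PER_CM2_TO_F_PER_CM2 = 1e-6
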