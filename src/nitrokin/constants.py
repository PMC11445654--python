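"""Physical constants and fixed empirical coefficients."""

import math

#: Molar mass of H2SO4, g/mol.
M_H2SO4 = 98.08

#: Molar gas constant, J/(mol K). Configurable via RunConfig.
R_GAS = 8.314

#: Offset between Celsius and kelvin scales.
CELSIUS_OFFSET = 273.15

LN10 = math.log(10.0)

#: Coefficients of the Marziano-type activity-coefficient polynomial for
#: -Mc(298 K) as a function of H2SO4 molarity, ascending powers c^1..c^5.
MC_POLY_COEFFS = (10.6, -2.73, 0.28, -1.27e-2, 2.16e-4)

#: Molarity interval (mol/L) over which the Mc polynomial was calibrated.
MC_CALIBRATION_RANGE = (15.2, 18.4)

#: Temperature-correction bracket for Mc: Mc(T) = Mc(298 K) * (A/T + B).
MC_TEMP_A = 200.0
MC_TEMP_B = 0.3292
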