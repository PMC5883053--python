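"""Physical constants and unit conversions used throughout the package.

All temperatures are stored in kelvin, all rates in s^-1, chemical shifts
in ppm, and RF field strengths in Hz.  The single place where ppm and Hz
meet is :func:`ppm_to_rad_per_s`.
"""

from __future__ import annotations

import math

#: Gas constant in kcal mol^-1 K^-1 (CODATA, converted from J).
R_GAS_KCAL: float = 1.987204e-3

#: gamma(15N)/gamma(1H) magnitude; multiplying the 1H spectrometer
#: frequency by this ratio yields the 15N Larmor frequency.
GAMMA_RATIO_15N_1H: float = 0.101329

#: Default 15N frequencies (MHz) of the two field strengths commonly used
#: for amide CEST/CPMG work (500 and 600 MHz 1H).
NITROGEN_FREQ_500: float = 500.0 * GAMMA_RATIO_15N_1H   # 50.66 MHz
NITROGEN_FREQ_600: float = 600.0 * GAMMA_RATIO_15N_1H   # 60.80 MHz

#: 0 degrees Celsius in kelvin.
ZERO_CELSIUS: float = 273.15

#: Scaling factor applied to 15N shift changes when combining 1H and 15N
#: chemical-shift perturbations into a single distance (Mulder scaling).
DEFAULT_R_SCALE: float = 6.3

TWO_PI: float = 2.0 * math.pi


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + ZERO_CELSIUS


def ppm_to_rad_per_s(delta_ppm: float, spectrometer_freq_mhz: float) -> float:
    """Convert a chemical-shift offset in ppm to angular frequency (rad/s).

    ``spectrometer_freq_mhz`` is the Larmor frequency of the observed
    nucleus in MHz, so 1 ppm corresponds to ``spectrometer_freq_mhz`` Hz.
    """
    return TWO_PI * delta_ppm * spectrometer_freq_mhz


def hz_to_rad_per_s(nu_hz: float) -> float:
    return TWO_PI * nu_hz
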