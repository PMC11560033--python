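"""Centralized unit conversion constants.

Working units throughout the package: Å for length, bar for pressure,
dyn/cm for surface tension, kcal/mol for energy, ns for time, degrees for
angles.
"""

import math

#: 1 bar·Å = 1e-5 N/m = 0.01 dyn/cm (surface tension from Lz·ΔP)
BAR_ANGSTROM_TO_DYN_PER_CM = 0.01

#: 1 bar·Å³ = 1e5 Pa · 1e-30 m³ = 1e-25 J → × N_A / 4184 = 1.4393e-5 kcal/mol
BAR_A3_TO_KCAL_PER_MOL = 1.4393e-5

#: (π/180)² — converts a kcal/(mol·rad²) force constant to kcal/(mol·deg²)
RAD2_TO_DEG2 = (math.pi / 180.0) ** 2


def force_constant_per_deg2(k_per_rad2: float) -> float:
    """Convert a harmonic force constant from kcal/(mol·rad²) to kcal/(mol·deg²)."""
    return k_per_rad2 * RAD2_TO_DEG2
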