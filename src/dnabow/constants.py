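"""Physical constants and unit conversions used across the package.

All mechanics are expressed in pN, nm and seconds; energies in pN·nm or
units of the thermal energy k_BT.  The default temperature is 22 °C, the
temperature at which the bow assay is operated.
"""

from __future__ import annotations

#: Boltzmann constant in pN·nm/K.
K_B = 0.0138065

#: Default assay temperature in kelvin (22 °C).
DEFAULT_TEMPERATURE = 295.15

#: Thermal energy at the default temperature, pN·nm (= 4.075 pN·nm).
KBT = K_B * DEFAULT_TEMPERATURE

#: Helical rise of B-form dsDNA, nm per base pair.
DS_RISE = 0.34

#: Default dsDNA persistence length, nm.
DS_PERSISTENCE = 50.0

#: Default ssDNA persistence length, nm.
SS_PERSISTENCE = 1.0

#: Default ssDNA contour length per nucleotide, nm.
SS_CONTOUR_PER_NT = 0.70

#: oxDNA-style simulation energy unit expressed in k_BT at 22 °C:
#: a hydrogen-bond energy of -0.1 simulation units is -1 k_BT.
SIM_ENERGY_UNIT_KBT = 10.0

#: oxDNA-style simulation length unit in nm (0.1 sim units = 0.085 nm).
SIM_LENGTH_UNIT_NM = 0.85

#: Gas constant in kcal/(mol·K), for nearest-neighbor tables.
R_KCAL = 1.98720425e-3


def kbt(temperature_K: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in pN·nm at the given temperature."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return K_B * temperature_K
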