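"""Physical constants and unit conventions.

All permeabilities are in cm/s, cell geometry (V0/A) in cm, osmolarities
user-facing in osmol/L (converted to mol/cm^3 wherever they multiply the
molar volume of water), temperatures user-facing in Celsius and internal
in kelvin, activation energies in kcal/mol.
"""

#: Molar volume of water, cm^3 mol^-1.
VW_CM3_PER_MOL = 18.0

#: Gas constant in kcal mol^-1 K^-1 (activation energies are reported in kcal).
R_KCAL_PER_MOL_K = 1.987e-3

#: pKa of propionic acid at 25 C, used by the weak-acid intracellular pH probe.
PKA_PROPIONIC = 4.87

#: Celsius -> kelvin offset.
CELSIUS_OFFSET = 273.15

#: osmol/L -> mol/cm^3.
OSM_TO_MOL_PER_CM3 = 1e-3


def celsius_to_kelvin(temperature_c: float) -> float:
    return temperature_c + CELSIUS_OFFSET
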