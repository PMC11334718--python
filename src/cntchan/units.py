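"""Physical constants and unit conversions.

Internal conventions: lengths in Å, times in ns, energies in kcal/mol,
charges in units of the elementary charge e, temperatures in K.
"""

#: Boltzmann constant, kcal/mol/K
KB_KCAL = 0.0019872

#: Coulomb constant e^2/(4*pi*eps0), kcal*Å/(mol*e^2)
COULOMB_KCAL_A = 332.06371

#: 1 kcal/mol per elementary charge, in volts
KCAL_PER_MOL_E_TO_V = 0.0433641

#: Avogadro's number times 1 mol/L, in molecules per Å^3
MOLAR_TO_PER_A3 = 6.02214076e-4

#: Bulk water number density at ambient conditions, molecules per Å^3
WATER_NUMBER_DENSITY = 0.0334


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature."""
    return KB_KCAL * temperature
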