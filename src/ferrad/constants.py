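"""Physical constants and unit helpers used across the package."""

AVOGADRO = 6.02214076e23  # mol^-1
GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1
ATM_PA = 101325.0

# conversion of bimolecular rate constants, M^-1 s^-1 -> m^3 mol^-1 s^-1
PER_MOLAR_TO_SI = 1.0e-3
# conversion of concentrations, mol m^-3 -> M
MOLM3_TO_MOLAR = 1.0e-3

MBAR_PA = 100.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15
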