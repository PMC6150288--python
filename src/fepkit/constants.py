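"""Physical constants and unit conventions.

All energies are kcal/mol, temperatures kelvin, distances angstrom.
"""

#: Gas constant in kcal/(mol*K).
R_KCAL_PER_MOL_K = 1.987204259e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 298.0


def kt(temperature: float) -> float:
    """Thermal energy R*T in kcal/mol for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL_PER_MOL_K * temperature
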