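"""Physical constants and unit conventions.

Energies are kJ/mol, lengths nm, times ps, temperatures K throughout.
"""

#: Molar gas constant / Boltzmann constant in molar units, kJ/mol/K.
KB = 0.0083144626

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
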