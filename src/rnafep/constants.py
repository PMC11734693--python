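"""Physical constants and shared defaults (kcal/mol unit system)."""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K: float = 0.0019872

#: Standard-state volume per molecule at 1 M, in cubic angstroms.
STANDARD_VOLUME_A3: float = 1661.0

#: Fraction of leading samples per lambda window treated as equilibration.
DEFAULT_DISCARD_FRACTION: float = 0.2


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
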