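"""Physical constants used throughout the package.

Energies are carried in kcal/mol to match the presentation conventions of
the ribozyme kinetics literature; :func:`ribopinch.energetics.kcal_to_kJ`
converts using the thermochemical calorie.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.98720e-3

#: Thermochemical calorie, J per cal (so kcal -> kJ multiplies by 4.184).
CAL_TO_J: float = 4.184

#: 37 degrees Celsius in Kelvin, the reference temperature for all
#: self-cleavage assays and nearest-neighbor free energies.
T_37C: float = 310.15


def rt(temperature: float = T_37C) -> float:
    """Thermal energy R*T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
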