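"""Unit conventions used package-wide.

Lengths are nanometres, times nanoseconds, energies kJ mol^-1 and
temperatures Kelvin.  The membrane normal is the +z axis.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (CODATA, molar form).
KB = 0.008314462618153241


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ mol^-1 for a temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
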