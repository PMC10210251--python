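"""Package-wide unit system: kcal/mol, Angstrom, picosecond, Kelvin, amu.

In this (AKMA-like) system a force of 1 kcal/mol/A acting on 1 amu produces
an acceleration of 4184/10 = 418.4 A/ps^2.
"""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: (kcal/mol/A) / amu  ->  A/ps^2
ACC = 418.4


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature


def beta(temperature: float) -> float:
    """Inverse temperature 1/(k_B*T) in mol/kcal."""
    return 1.0 / (KB * temperature)
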