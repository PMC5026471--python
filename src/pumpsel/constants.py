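"""Physical constants and unit conventions.

Energies are kcal/mol, distances Å, charges in units of the elementary
charge, temperatures in K.  Angles are degrees at every public interface
and radians internally.
"""

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB = 332.0716

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: Default simulation temperature (K)
T_DEFAULT = 303.15

#: Standard-state volume per molecule at 1 M, Å³
STD_VOLUME = 1661.0

#: Standard concentration C°, molecules/Å³
C_STANDARD = 1.0 / STD_VOLUME

#: ln(10), used in the pKa conversion ΔpKa = ΔΔG / (2.303 kBT)
LN10 = 2.303


def kbt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB * temperature
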