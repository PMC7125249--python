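"""Thermodynamic constants.

All energies in this package are kcal/mol, volumes in cubic angstrom,
charges in elementary charge units; there is no unit-conversion layer.
"""

from dataclasses import dataclass
import math

#: Molar gas constant in kcal mol^-1 K^-1 (CODATA).
R_KCAL_PER_MOL_K = 1.98720425864083e-3

#: Standard temperature used throughout, in kelvin.
T_STANDARD = 298.15


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature bundle threaded through all Boltzmann sums.

    Parameters
    ----------
    R : float
        Molar gas constant, kcal mol^-1 K^-1.
    T : float
        Absolute temperature, K. Must be positive.
    """

    R: float = R_KCAL_PER_MOL_K
    T: float = T_STANDARD

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"temperature must be positive, got {self.T}")
        if not (self.R > 0):
            raise ValueError(f"gas constant must be positive, got {self.R}")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.R * self.T

    @property
    def RT_ln10(self) -> float:
        """R*T*ln(10): conversion between kcal/mol and decadic log units."""
        return self.RT * math.log(10.0)


#: Default constants at 298.15 K.
STANDARD = ThermoConstants()
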