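"""Thermodynamic constants and state.

Energies are reported in kcal/mol, lengths in nm, following the unit
conventions of the enhanced-sampling community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Standard concentration, 1 mol/L expressed as one molecule per 1.660 nm^3.
STANDARD_CONC_NM3 = 1.0 / 1.660


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and derived inverse temperature.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    k_B : float
        Boltzmann constant in kcal mol^-1 K^-1.
    """

    temperature: float = 300.0
    k_B: float = KB_KCAL_PER_MOL_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.k_B <= 0:
            raise ValueError(f"k_B must be positive, got {self.k_B}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.k_B * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
        return 1.0 / self.kT
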