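"""Physical constants and the thermodynamic state used throughout.

Internal unit conventions: free energies in kJ/mol, distances in nm,
diffusion coefficients in nm^2/ps, friction in ps/nm^2, permeability
coefficients in cm/h, concentrations in g/L unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Default simulation temperature of the skin barrier model, K.
DEFAULT_TEMPERATURE = 305.15

#: Avogadro's number, mol^-1.
AVOGADRO = 6.02214076e23

#: Exact unit identity: 1 nm/ps = 3.6e8 cm/h.
NM_PER_PS_TO_CM_PER_H = 3.6e8

#: Liters per cubic nanometer.
L_PER_NM3 = 1e-24


@dataclass(frozen=True)
class Constants:
    """Thermodynamic state for Boltzmann factors.

    Attributes
    ----------
    temperature : float
        Absolute temperature in K. Defaults to the 305.15 K used for the
        skin barrier simulations (close to skin surface temperature).
    gas_constant : float
        Gas constant in J mol^-1 K^-1.
    """

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.gas_constant <= 0:
            raise ValueError("gas_constant must be positive")

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature / 1000.0

    @property
    def beta(self) -> float:
        """Thermodynamic beta, 1/(R*T), in mol/kJ."""
        return 1000.0 / (self.gas_constant * self.temperature)
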