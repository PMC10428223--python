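"""pH correction of permeability coefficients for ionizable permeants.

Only the neutral species is assumed to permeate the lipid barrier. The
neutral fraction follows the Henderson-Hasselbalch relation, so for a weak
acid the effective permeability is

    log10 K_P^e = log10 K_P^0 - log10(1 + 10**(pH - pKa)),

and for a weak base the exponent is (pKa - pH). At pH = pKa the shift is
exactly -log10(2); far below (acid) or above (base) the pKa the shift
vanishes, and in the fully ionized limit it falls by one log unit per pH
unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class IonizationInput:
    """Inputs for the neutral-fraction pH correction.

    ``log_kp0`` is the calculated (neutral-species) log10 permeability;
    ``pka_aq`` the aqueous pKa; ``ph`` the formulation pH; ``character``
    'acid' or 'base'.
    """

    log_kp0: float
    pka_aq: float
    ph: float
    character: str = "acid"

    def __post_init__(self) -> None:
        if not (0.0 < self.ph < 14.0):
            raise ValueError(f"pH must lie in (0, 14), got {self.ph}")
        if self.character not in ("acid", "base"):
            raise ValueError("character must be 'acid' or 'base'")


def ionization_shift(pka_aq: float, ph: float, character: str = "acid") -> float:
    """log10 neutral fraction: the (nonpositive) shift applied to log K_P."""
    if character == "acid":
        exponent = ph - pka_aq
    elif character == "base":
        exponent = pka_aq - ph
    else:
        raise ValueError("character must be 'acid' or 'base'")
    return -math.log10(1.0 + 10.0 ** exponent)


def ph_corrected_log_kp(inp: IonizationInput) -> float:
    """Effective log10 permeability after weighting by the neutral fraction."""
    return inp.log_kp0 + ionization_shift(inp.pka_aq, inp.ph, inp.character)
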