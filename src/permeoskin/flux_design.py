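"""Formulation-design guidance from the formulation-referenced PMF minimum.

Because the PMF is calibrated against the permeant's solvation free energy
in the formulation, the sign of its minimum tells which lever moves flux
(J = C_v * K_P):

* minimum below zero (solubility-limited): the permeant partitions into the
  barrier more favorably than it dissolves in the vehicle. Raising its
  formulation solubility with inert excipients lifts the PMF minimum toward
  zero without touching K_P, multiplying the attainable saturated-vehicle
  flux by up to exp(-beta * pmf_min);
* minimum above zero (barrier-limited): more solubility only raises the
  relative permeation barriers, so enhancers that lower the barrier itself
  are needed.

This analysis requires the formulation-calibrated profile; a min-anchored
(shifted) PMF has discarded exactly the information used here, so passing
one is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import Constants
from .profiles import Profile, ProfileValidationError

CAVEAT = (
    "The solubility-gain bound assumes that formulation solubility can be "
    "raised by inert excipients without altering the skin barrier. This is "
    "at odds with the classical expectation that maximum flux from saturated "
    "inert vehicles is independent of solubility, and should be checked in "
    "controlled steady-state permeation experiments."
)


@dataclass(frozen=True)
class DesignVerdict:
    """Classification of a permeant/formulation pair.

    ``max_solubility_gain`` bounds the flux multiplier obtainable by raising
    the PMF minimum to zero: exp(-beta * pmf_min) when the minimum is
    negative, else 1.
    """

    pmf_min: float
    regime: str
    max_solubility_gain: float
    caveat: str = CAVEAT

    def __post_init__(self) -> None:
        if self.regime not in ("solubility_limited", "barrier_limited"):
            raise ValueError(f"unknown regime {self.regime!r}")


def classify(pmf: Profile, constants: Constants | None = None) -> DesignVerdict:
    """Classify a formulation-referenced PMF and bound the solubility gain.

    Raises if the profile has been min-shifted (metadata key ``pmf_shift``):
    the two shift conventions are mutually exclusive.
    """
    constants = constants or Constants()
    if pmf.kind != "pmf":
        raise ProfileValidationError("expected a pmf profile")
    if "pmf_shift" in pmf.metadata:
        raise ProfileValidationError(
            "this PMF has been min-shifted; flux-design classification needs "
            "the formulation-calibrated profile"
        )
    pmf_min = float(pmf.values.min())
    if pmf_min < 0:
        regime = "solubility_limited"
        gain = math.exp(-constants.beta * pmf_min)
    else:
        regime = "barrier_limited"
        gain = 1.0
    return DesignVerdict(pmf_min=pmf_min, regime=regime, max_solubility_gain=gain)
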