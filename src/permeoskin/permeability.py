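"""Permeability coefficients from the inhomogeneous solubility-diffusion model.

The steady-state permeation resistance of a single bilayer is

    R = integral_0^L exp(beta * dG_transfer(z)) / D(z) dz,

where dG_transfer(z) is the transfer free energy relative to the permeant's
solvation free energy in the donor phase (kJ/mol), D(z) the local diffusion
coefficient (nm^2/ps) and beta = 1/RT. The stratum corneum is modeled as a
stack of n_bilayers ~ 30 +- 6 identical lipid bilayers in series, so

    K_P = 1 / (n_bilayers * R),

reported in cm/h. Steady-state flux from a formulation with permeant
concentration C_v is J = C_v * K_P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import Constants, NM_PER_PS_TO_CM_PER_H
from .profiles import Profile, ProfileValidationError


@dataclass
class PermeabilityResult:
    """A permeability coefficient with its resistance profile.

    Attributes
    ----------
    kp : float
        Permeability coefficient, cm/h.
    log_kp : float
        log10(kp).
    resistance_profile : Profile
        Cumulative resistance of the full n_bilayers stack, h/cm vs nm.
    n_bilayers : int
        Number of stacked bilayers assumed in series.
    stderr_log_kp : float or None
        One standard error of log_kp from per-point PMF uncertainty
        envelopes, when available.
    """

    kp: float
    log_kp: float
    resistance_profile: Profile
    n_bilayers: int
    stderr_log_kp: float | None = None

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ValueError("permeability coefficient must be positive")
        if abs(self.log_kp - np.log10(self.kp)) > 1e-12 * max(1.0, abs(self.log_kp)):
            raise ValueError("log_kp inconsistent with kp")


def _resistance_integrand(pmf: Profile, diffusion: Profile,
                          constants: Constants) -> np.ndarray:
    if pmf.kind != "pmf":
        raise ProfileValidationError(f"expected pmf profile, got {pmf.kind!r}")
    if diffusion.kind != "diffusion":
        raise ProfileValidationError(
            f"expected diffusion profile, got {diffusion.kind!r}"
        )
    if pmf.z[0] < diffusion.z[0] - 1e-9 or pmf.z[-1] > diffusion.z[-1] + 1e-9:
        raise ProfileValidationError(
            "diffusion grid does not cover the PMF grid; cannot resample"
        )
    # resample D onto the PMF grid so the free-energy exponential is never
    # interpolated
    d_on_pmf = np.interp(pmf.z, diffusion.z, diffusion.values)
    if np.any(d_on_pmf <= 0):
        raise ProfileValidationError("diffusion must be strictly positive")
    return np.exp(constants.beta * pmf.values) / d_on_pmf  # ps/nm^2


def resistance_profile(pmf: Profile, diffusion: Profile,
                       constants: Constants | None = None) -> Profile:
    """Cumulative single-bilayer permeation resistance R(z), h/cm.

    Trapezoidal cumulative integral of exp(beta*dG)/D from the lower grid
    edge; the final value is the total single-bilayer resistance.
    """
    constants = constants or Constants()
    integrand = _resistance_integrand(pmf, diffusion, constants)
    cum = cumulative_trapezoid(integrand, pmf.z, initial=0.0)  # ps/nm
    cum_h_per_cm = cum / NM_PER_PS_TO_CM_PER_H
    return Profile(
        z=pmf.z.copy(), values=cum_h_per_cm, kind="resistance",
        metadata={"steps": list(pmf.metadata.get("steps", [])) + ["resistance_profile"],
                  "units": "h/cm"},
    )


def permeability_coefficient(pmf: Profile, diffusion: Profile,
                             constants: Constants | None = None,
                             n_bilayers: int = 30,
                             pmf_stderr: np.ndarray | None = None) -> PermeabilityResult:
    """Permeability coefficient K_P = 1/(n_bilayers * R_single), cm/h.

    Parameters
    ----------
    pmf : Profile
        Min-shifted transfer free-energy profile (kJ/mol).
    diffusion : Profile
        Local diffusion coefficient (nm^2/ps); resampled onto the PMF grid.
    n_bilayers : int
        Bilayers stacked in series; the stratum corneum estimate is 30 +- 6.
    pmf_stderr : ndarray, optional
        Per-point standard error of the PMF (e.g. from replicate averaging).
        Propagated conservatively by recomputing K_P on the dG +- sigma(z)
        envelopes; half the spread in log10 K_P is reported as stderr_log_kp.
    """
    constants = constants or Constants()
    if n_bilayers < 1:
        raise ValueError("n_bilayers must be >= 1")
    r_single = resistance_profile(pmf, diffusion, constants)
    total = float(r_single.values[-1])
    if total <= 0:
        raise ValueError("total resistance must be positive")
    stack = r_single.replace(values=r_single.values * n_bilayers,
                             step=f"stack(n_bilayers={n_bilayers})")
    kp = 1.0 / (n_bilayers * total)
    stderr = None
    if pmf_stderr is not None:
        sigma = np.asarray(pmf_stderr, dtype=float)
        if sigma.shape != pmf.values.shape:
            raise ValueError("pmf_stderr must match the PMF grid")
        hi = pmf.replace(values=pmf.values + sigma)
        lo = pmf.replace(values=pmf.values - sigma)
        kp_lo = 1.0 / (n_bilayers * resistance_profile(hi, diffusion, constants).values[-1])
        kp_hi = 1.0 / (n_bilayers * resistance_profile(lo, diffusion, constants).values[-1])
        stderr = 0.5 * abs(np.log10(kp_hi) - np.log10(kp_lo))
    return PermeabilityResult(
        kp=kp, log_kp=float(np.log10(kp)), resistance_profile=stack,
        n_bilayers=n_bilayers, stderr_log_kp=stderr,
    )


def enhancement_ratio(kp_pe: Union[PermeabilityResult, float],
                      kp_ref: Union[PermeabilityResult, float]) -> float:
    """Enhancement ratio ER = K_P(enhancer) / K_P(reference).

    Accepts either :class:`PermeabilityResult` objects or bare log10 K_P
    values (the form permeability tables are printed in):
    ER = 10**(log_kp_pe - log_kp_ref).
    """
    log_pe = kp_pe.log_kp if isinstance(kp_pe, PermeabilityResult) else float(kp_pe)
    log_ref = kp_ref.log_kp if isinstance(kp_ref, PermeabilityResult) else float(kp_ref)
    return float(10.0 ** (log_pe - log_ref))


def flux(kp: Union[PermeabilityResult, float], concentration: float) -> float:
    """Steady-state flux J = C_v * K_P.

    With K_P in cm/h and C_v in ug/cm^3 (= mg/L), J is in ug cm^-2 h^-1.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    kp_val = kp.kp if isinstance(kp, PermeabilityResult) else float(kp)
    return float(concentration * kp_val)
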