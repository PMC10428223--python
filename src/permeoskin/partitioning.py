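"""Partition coefficients from free energies and the skin-vs-octanol relation.

Two partition coefficients appear in transdermal work:

* the octanol-water coefficient, log K_ow, computed from the difference in
  solvation free energies: log K_ow = (dG_water - dG_octanol) / (RT ln 10);
* the water-to-skin-lipid coefficient, log K_w-lip, obtained as the spatial
  Boltzmann average of exp(-beta * dG_rel_water(z)) over a bilayer region,
  where dG_rel_water is the PMF calibrated against the aqueous solvation
  free energy.

Empirically log K_w-lip correlates linearly with log K_ow;
``fit_partition_relation`` fits that line and reports RMSE (log units)
and R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import Constants
from .profiles import Profile, ProfileValidationError


@dataclass
class PermeantRecord:
    """Solvation free energies and ionization descriptors of one permeant.

    Free energies are in kJ/mol with a vacuum reference; pKa is the aqueous
    value. ``acid_or_base`` tags the ionizable character used for pH
    correction ('acid', 'base', or None for non-ionizable molecules).
    """

    name: str
    dg_solv_water: float | None = None
    dg_solv_octanol: float | None = None
    dg_solv_formulation: float | None = None
    pka: float | None = None
    acid_or_base: str | None = None

    def __post_init__(self) -> None:
        for val in (self.dg_solv_water, self.dg_solv_octanol, self.dg_solv_formulation):
            if val is not None and not math.isfinite(val):
                raise ValueError(f"{self.name}: solvation free energies must be finite")
        if self.pka is not None and not (0.0 < self.pka < 14.0):
            raise ValueError(f"{self.name}: pKa must lie in (0, 14)")
        if self.acid_or_base not in (None, "acid", "base"):
            raise ValueError("acid_or_base must be 'acid', 'base' or None")


@dataclass(frozen=True)
class FitReport:
    """Least-squares line log K_skin = slope * log K_ow + intercept."""

    slope: float
    intercept: float
    rmse: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")


def log_kow(record: PermeantRecord, constants: Constants | None = None) -> float:
    """Octanol-water partition coefficient from solvation free energies.

    log K_ow = (dG_solv_water - dG_solv_octanol) / (RT ln 10); positive when
    octanol solvation is more favorable.
    """
    constants = constants or Constants()
    if record.dg_solv_water is None or record.dg_solv_octanol is None:
        raise ValueError(f"{record.name}: both water and octanol solvation "
                         "free energies are required")
    return (record.dg_solv_water - record.dg_solv_octanol) / (
        constants.rt * math.log(10.0))


def log_k_skin(pmf_rel_water: Profile, region: tuple[float, float] | None = None,
               constants: Constants | None = None) -> float:
    """Water-to-skin partition coefficient from a water-calibrated PMF.

    K = (1/|region|) * integral_region exp(-beta * dG_rel_water(z)) dz,
    the spatial Boltzmann average over the region (default: the full
    profile extent). Returns log10 K.
    """
    constants = constants or Constants()
    if pmf_rel_water.kind != "pmf":
        raise ProfileValidationError("expected a pmf profile")
    z0, z1 = region if region is not None else (pmf_rel_water.z[0], pmf_rel_water.z[-1])
    if not z1 > z0:
        raise ValueError("region must have positive width")
    if z0 < pmf_rel_water.z[0] - 1e-12 or z1 > pmf_rel_water.z[-1] + 1e-12:
        raise ProfileValidationError("profile does not cover the requested region")
    # clip the grid to the region, with interpolated endpoint samples so
    # constant profiles integrate exactly regardless of grid alignment
    inner = pmf_rel_water.z[(pmf_rel_water.z > z0) & (pmf_rel_water.z < z1)]
    grid = np.concatenate(([z0], inner, [z1]))
    dg = pmf_rel_water.interp(grid)
    k = np.trapezoid(np.exp(-constants.beta * dg), grid) / (z1 - z0)
    return float(np.log10(k))


def fit_partition_relation(points: Sequence[tuple[float, float]],
                           fix_intercept: float | None = None) -> FitReport:
    """Fit log K_skin = slope * log K_ow (+ intercept) by least squares.

    Parameters
    ----------
    points : sequence of (log_kow, log_k_skin)
        At least 3 paired observations.
    fix_intercept : float, optional
        Hold the intercept fixed (e.g. 0) and fit the slope only.

    Returns
    -------
    FitReport
        Slope, intercept, RMSE of the log K_skin predictions (log units)
        and the coefficient of determination.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be pairs (log_kow, log_k_skin)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no variance in log_kow")
    if fix_intercept is None:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        intercept = float(fix_intercept)
        slope = float(np.dot(x, y - intercept) / np.dot(x, x))
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return FitReport(slope=float(slope), intercept=float(intercept),
                     rmse=rmse, r2=r2, n=int(pts.shape[0]))
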