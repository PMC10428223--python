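"""Permeation-enhancer insertion planning from transfer free-energy profiles.

Rather than simulating partitioning of formulation excipients into the skin
barrier directly, the expected number of enhancer molecules in the bilayer
is computed from the enhancer's transfer free-energy profile:

    N_mol = C * exp(-beta * dG_transfer),

where C is the number of enhancer molecules contained in a formulation
volume equal to the simulated skin system. The bilayer is divided into 20
z-slices; the Boltzmann factor is evaluated within each slice so molecules
are placed where they actually partition. Counts in the headgroup band are
capped so the total inserted mass there (water included) stays below 2.5x
the water mass already present; chain-region slices are never capped.
Placement is random in the lateral xy plane at the slice center, with a
1000 kJ mol^-1 nm^-2 center-of-mass z-restraint recorded for the downstream
interaction-growth stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from .constants import AVOGADRO, Constants, L_PER_NM3
from .profiles import BilayerGeometry, Profile, ProfileValidationError

#: Center-of-mass restraint force constant along z, kJ mol^-1 nm^-2.
RESTRAINT_K = 1000.0

#: Interaction growth / unrestrained equilibration lengths recorded in plans (ns).
GROWTH_NS = 5.0
EQUILIBRATION_NS = 300.0

#: Density of liquid ethanol at ambient conditions, g/cm^3 (for the volume
#: removed by evaporation).
ETHANOL_DENSITY = 0.789


@dataclass(frozen=True)
class Component:
    """One formulation component.

    ``concentration`` is interpreted per ``unit``: 'mg/L' or '%w/v'
    (grams per 100 mL). ``molar_mass`` in g/mol.
    """

    name: str
    concentration: float
    molar_mass: float
    unit: str = "mg/L"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be nonnegative")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.unit not in ("mg/L", "%w/v", "g/L"):
            raise ValueError(f"{self.name}: unknown concentration unit {self.unit!r}")

    @property
    def grams_per_liter(self) -> float:
        if self.unit == "mg/L":
            return self.concentration / 1000.0
        if self.unit == "%w/v":
            return self.concentration * 10.0
        return self.concentration


@dataclass
class FormulationSpec:
    """A topical formulation: components, pH and ethanol-evaporation model.

    ``system_volume`` is the volume (nm^3) of the simulated skin system the
    counts refer to. A fraction ``ethanol_evaporation_fraction`` of any
    component named 'ethanol' is removed before partitioning; the remaining
    concentrations are renormalized to the reduced solution volume.
    """

    components: list[Component]
    system_volume: float
    ph: float | None = None
    ethanol_evaporation_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.system_volume <= 0:
            raise ValueError("system_volume must be positive (nm^3)")
        if not 0.0 <= self.ethanol_evaporation_fraction <= 1.0:
            raise ValueError("evaporation fraction must lie in [0, 1]")

    def component(self, name: str) -> Component:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(f"component {name!r} not in formulation")

    def effective_grams_per_liter(self, name: str) -> float:
        """Concentration after ethanol evaporation and volume renormalization."""
        comp = self.component(name)
        evap = self.ethanol_evaporation_fraction
        ethanol = next((c for c in self.components if c.name.lower() == "ethanol"), None)
        if ethanol is None or evap == 0.0:
            return comp.grams_per_liter
        # grams of ethanol removed per liter of original formulation, and the
        # solution volume that disappears with them
        removed_g = evap * ethanol.grams_per_liter
        removed_volume_fraction = removed_g / (ETHANOL_DENSITY * 1000.0)
        remaining = 1.0 - removed_volume_fraction
        if remaining <= 0:
            raise ValueError("ethanol evaporation removes the entire solution volume")
        mass = comp.grams_per_liter
        if comp.name.lower() == "ethanol":
            mass *= (1.0 - evap)
        return mass / remaining


@dataclass(frozen=True)
class SliceCount:
    """Planned insertion count for one z-slice."""

    index: int
    z_lo: float
    z_hi: float
    count: int

    @property
    def center(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)


@dataclass
class InsertionPlan:
    """Per-slice insertion counts with placement and restraint metadata."""

    component: str
    molar_mass: float
    per_slice: list[SliceCount]
    capped: bool = False
    lateral_positions: list[tuple[float, float, float]] | None = None
    restraint_k: float = RESTRAINT_K
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s.count < 0 for s in self.per_slice):
            raise ValueError("slice counts must be nonnegative")
        self.metadata.setdefault("growth_ns", GROWTH_NS)
        self.metadata.setdefault("equilibration_ns", EQUILIBRATION_NS)

    @property
    def total(self) -> int:
        return sum(s.count for s in self.per_slice)

    def mass(self, region: str | None = None,
             geometry: BilayerGeometry | None = None) -> float:
        """Total planned mass in amu, optionally restricted to one region."""
        if region is None:
            return self.total * self.molar_mass
        geometry = geometry or BilayerGeometry()
        return sum(s.count for s in self.per_slice
                   if geometry.classify(s.center) == region) * self.molar_mass


def number_density_per_nm3(grams_per_liter: float, molar_mass: float) -> float:
    """Molecules per nm^3 from a mass concentration (g/L) and molar mass."""
    return grams_per_liter / molar_mass * AVOGADRO * L_PER_NM3


def formulation_count(spec: FormulationSpec, component: str) -> float:
    """C of the insertion formula: enhancer molecules in a formulation volume
    equal to the simulated skin system.

    Ethanol evaporation (and the accompanying shrinkage of the solution
    volume) is applied before converting concentration to a number density.
    """
    c_gl = spec.effective_grams_per_liter(component)
    molar_mass = spec.component(component).molar_mass
    return number_density_per_nm3(c_gl, molar_mass) * spec.system_volume


def slice_counts(pmf_transfer: Profile, spec: FormulationSpec, component: str,
                 n_slices: int = 20, constants: Constants | None = None,
                 geometry: BilayerGeometry | None = None) -> InsertionPlan:
    """Per-slice insertion counts N_i = (C/n_slices) * <exp(-beta*dG)>_slice.

    ``pmf_transfer`` must be the transfer free energy relative to the
    formulation solvation free energy (not min-shifted). The representative
    Boltzmann factor of a slice is the spatial average of exp(-beta*dG)
    within it; counts are rounded to the nearest integer.
    """
    constants = constants or Constants()
    geometry = geometry or BilayerGeometry()
    if pmf_transfer.kind != "pmf":
        raise ProfileValidationError("expected a pmf profile")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    z0, z1 = geometry.z_min, geometry.z_max
    # cell-centered grids (first/last sample half a spacing inside the
    # domain) count as covering it; values are clamped at the outermost cell
    tol = pmf_transfer.spacing
    if pmf_transfer.z[0] > z0 + tol or pmf_transfer.z[-1] < z1 - tol:
        z0, z1 = float(pmf_transfer.z[0]), float(pmf_transfer.z[-1])
    edges = np.linspace(z0, z1, n_slices + 1)
    c_total = formulation_count(spec, component)
    c_slice = c_total / n_slices
    slices: list[SliceCount] = []
    for i in range(n_slices):
        lo, hi = edges[i], edges[i + 1]
        inner = pmf_transfer.z[(pmf_transfer.z > lo) & (pmf_transfer.z < hi)]
        grid = np.concatenate(([lo], inner, [hi]))
        dg = np.interp(grid, pmf_transfer.z, pmf_transfer.values)
        boltz = np.trapezoid(np.exp(-constants.beta * dg), grid) / (hi - lo)
        count = int(round(c_slice * boltz))
        slices.append(SliceCount(index=i, z_lo=float(lo), z_hi=float(hi), count=count))
    return InsertionPlan(
        component=component,
        molar_mass=spec.component(component).molar_mass,
        per_slice=slices,
        metadata={"C": c_total, "n_slices": n_slices,
                  "temperature": constants.temperature},
    )


def apply_headgroup_cap(plan: InsertionPlan, geometry: BilayerGeometry,
                        water_mass_present: float, cap_ratio: float = 2.5,
                        already_inserted_mass: float = 0.0) -> InsertionPlan:
    """Cap headgroup-region insertion at ``cap_ratio`` x the resident water mass.

    The capped quantity is the total headgroup-region mass after insertion
    (resident water + previously inserted excipients + this plan) relative
    to the resident water mass. If it exceeds ``cap_ratio``, headgroup-slice
    counts are scaled down proportionally (floor-rounded) until the cap
    holds; chain- and tail-region slices are never modified. Idempotent.

    Masses are in amu; ``water_mass_present`` is the water already in the
    skin model (e.g. 90 waters = 90 * 18.015 amu).
    """
    if water_mass_present <= 0:
        raise ValueError("water_mass_present must be positive")
    head_mass = plan.mass("headgroup", geometry)
    allowed = (cap_ratio - 1.0) * water_mass_present - already_inserted_mass
    if head_mass <= allowed or head_mass == 0:
        out = dc_replace(plan, per_slice=list(plan.per_slice), capped=plan.capped)
        out.metadata = dict(plan.metadata)
        out.metadata["headgroup_mass_ratio"] = (
            (water_mass_present + already_inserted_mass + head_mass)
            / water_mass_present)
        return out
    scale = max(allowed, 0.0) / head_mass
    new_slices = [
        dc_replace(s, count=int(math.floor(s.count * scale)))
        if geometry.classify(s.center) == "headgroup" else s
        for s in plan.per_slice
    ]
    out = dc_replace(plan, per_slice=new_slices, capped=True, lateral_positions=None)
    out.metadata = dict(plan.metadata)
    out.metadata["headgroup_cap"] = {"cap_ratio": cap_ratio, "scale": scale}
    out.metadata["headgroup_mass_ratio"] = (
        (water_mass_present + already_inserted_mass + out.mass("headgroup", geometry))
        / water_mass_present)
    return out


def scale_plan(plan: InsertionPlan, factor: float) -> InsertionPlan:
    """Multiply every slice count by ``factor`` (nearest-integer rounding).

    Used for stepwise escalation of under-predicted insertions, e.g. +50%
    per step (16 -> 24 -> 36 ...); lateral positions are cleared and must be
    regenerated.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    new_slices = [dc_replace(s, count=int(round(s.count * factor)))
                  for s in plan.per_slice]
    out = dc_replace(plan, per_slice=new_slices, lateral_positions=None)
    out.metadata = dict(plan.metadata)
    out.metadata.setdefault("scaled_by", []).append(factor)
    out.metadata["scaled_by"] = list(out.metadata["scaled_by"])
    return out


def place_molecules(plan: InsertionPlan, box: tuple[float, float],
                    seed: int) -> InsertionPlan:
    """Draw uniform lateral (x, y) positions for every planned molecule.

    z is the slice center; placement is deterministic for a given seed.
    """
    lx, ly = box
    if lx <= 0 or ly <= 0:
        raise ValueError("box dimensions must be positive")
    rng = np.random.default_rng(seed)
    positions: list[tuple[float, float, float]] = []
    for s in plan.per_slice:
        if s.count == 0:
            continue
        xy = rng.uniform(low=[0.0, 0.0], high=[lx, ly], size=(s.count, 2))
        positions.extend((float(x), float(y), s.center) for x, y in xy)
    out = dc_replace(plan, per_slice=list(plan.per_slice), lateral_positions=positions)
    out.metadata = dict(plan.metadata)
    out.metadata["placement"] = {"box": [lx, ly], "seed": int(seed)}
    return out
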