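"""Synthetic PMF/friction profiles and fixtures with realistic topography.

Real profiles are adaptive-bias MD outputs with no parametric form; for
testing, Gaussian mixtures are used instead because they have closed-form
extrema and smooth integrands. The reference skin profile mimics the
ceramide bilayer topography: the main permeability barrier in the sphingoid
chain region (4-5 nm), the least resistance at the headgroup band
(z ~ 3.2 nm), and a secondary barrier in the fatty-acid chain region
(z ~ 2.1 nm), on the default [0, 5.21] nm domain with 0.01 nm spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import Constants
from .insertion import Component, FormulationSpec
from .profiles import BilayerGeometry, Profile

DEFAULT_DOMAIN = (0.0, 5.21)
DEFAULT_SPACING = 0.01


@dataclass(frozen=True)
class GaussianFeature:
    """One well (height < 0) or barrier (height > 0) of a synthetic profile."""

    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("feature width must be positive")


@dataclass
class BarrierSpec:
    """Sum-of-Gaussians description of a synthetic free-energy landscape."""

    features: list[GaussianFeature] = field(default_factory=list)
    domain: tuple[float, float] = DEFAULT_DOMAIN
    baseline: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.domain
        for f in self.features:
            if not lo <= f.center <= hi:
                raise ValueError(f"feature center {f.center} outside domain {self.domain}")

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(z, float), self.baseline)
        for f in self.features:
            out = out + f.height * np.exp(-((z - f.center) ** 2) / (2.0 * f.width ** 2))
        return out


def _grid(domain: tuple[float, float], spacing: float) -> np.ndarray:
    lo, hi = domain
    n = int(round((hi - lo) / spacing))
    # cell-centered grid, matching the half-spacing offset of binned
    # free-energy outputs (0.005, 0.015, ... for a 0.01 nm spacing)
    return lo + spacing * (np.arange(n) + 0.5)


def make_pmf(spec: BarrierSpec, grid_spacing: float = DEFAULT_SPACING,
             seed: int = 0, noise_sd: float = 0.0) -> Profile:
    """Sample a Gaussian-mixture PMF on a uniform grid, optionally noisy.

    Noise is i.i.d. Gaussian per grid point; deterministic for a given seed.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    z = _grid(spec.domain, grid_spacing)
    values = spec.evaluate(z)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, z.size)
    return Profile(z=z, values=values, kind="pmf",
                   metadata={"source": "synthetic", "seed": int(seed),
                             "noise_sd": noise_sd, "steps": []})


def reference_barrier_spec(permeant_class: str = "hydrophilic") -> BarrierSpec:
    """Barrier topography of the ceramide bilayer for a permeant class.

    hydrophilic: elevated chain-region plateau with a headgroup well, so the
    global minimum sits at z ~ 3.2 nm. lipophilic: minimum inside the
    fatty-acid chain region instead.
    """
    if permeant_class == "hydrophilic":
        return BarrierSpec(
            baseline=8.0,
            features=[
                GaussianFeature(center=4.55, width=0.30, height=18.0),  # sphingoid
                GaussianFeature(center=2.1, width=0.25, height=8.0),    # fatty acid
                GaussianFeature(center=3.2, width=0.25, height=-12.0),  # headgroup
                GaussianFeature(center=0.66, width=0.30, height=6.0),
            ],
        )
    if permeant_class == "lipophilic":
        return BarrierSpec(
            baseline=2.0,
            features=[
                GaussianFeature(center=4.55, width=0.30, height=14.0),
                GaussianFeature(center=3.2, width=0.25, height=4.0),
                GaussianFeature(center=1.9, width=0.40, height=-8.0),
            ],
        )
    raise ValueError("permeant_class must be 'hydrophilic' or 'lipophilic'")


def make_reference_skin_pmf(permeant_class: str = "hydrophilic",
                            grid_spacing: float = DEFAULT_SPACING) -> Profile:
    """Noise-free reference PMF across the skin bilayer for a permeant class."""
    return make_pmf(reference_barrier_spec(permeant_class), grid_spacing)


def make_friction(baseline: float = 2.0e4, chain_excess: float = 4.0e5,
                  grid_spacing: float = DEFAULT_SPACING,
                  domain: tuple[float, float] = DEFAULT_DOMAIN) -> Profile:
    """Synthetic friction profile g(z) (ps nm^-2), higher in ordered chains.

    The reciprocals land around 5e-5 nm^2/ps (5e-7 cm^2/s) in the disordered
    parts and a few 1e-6 nm^2/ps inside the ordered chain regions, the range
    expected for small molecules in dense lipid phases.
    """
    z = _grid(domain, grid_spacing)
    g = baseline + chain_excess * (
        np.exp(-((z - 4.5) ** 2) / (2 * 0.4 ** 2))
        + np.exp(-((z - 2.1) ** 2) / (2 * 0.4 ** 2))
    )
    return Profile(z=z, values=g, kind="friction",
                   metadata={"source": "synthetic", "steps": []})


def make_replicates(pmf: Profile, n: int = 3, sd: float = 1.0,
                    seed: int = 0) -> list[Profile]:
    """n noisy copies of a PMF, emulating independent sampling replicates.

    The replicate mean converges to the input as n grows; sd is the
    per-point Gaussian noise in kJ/mol.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        noise = rng.normal(0.0, sd, pmf.z.size) if sd > 0 else 0.0
        out.append(pmf.replace(values=pmf.values + noise,
                               step=f"replicate({i}, sd={sd})"))
    return out


def make_water_insertion_fixture(
    inserted_target: int = 100,
    waters_present: int = 90,
    system_volume: float = 157.0,
    constants: Constants | None = None,
    geometry: BilayerGeometry | None = None,
) -> tuple[Profile, FormulationSpec, BilayerGeometry, float]:
    """Pure-water formulation fixture calibrated to a target insertion count.

    Synthetic stand-in for the water-insertion bookkeeping of the skin
    model: the transfer PMF is flat and strongly unfavorable except in the
    headgroup slice, whose depth is solved so that the planned insertion is
    exactly ``inserted_target`` molecules. Returns (pmf, formulation,
    geometry, resident water mass in amu).
    """
    from scipy.optimize import brentq

    from .insertion import formulation_count

    constants = constants or Constants()
    geometry = geometry or BilayerGeometry()
    water = Component(name="water", concentration=997.0, molar_mass=18.015,
                      unit="g/L")
    spec = FormulationSpec(components=[water], system_volume=system_volume,
                           ethanol_evaporation_fraction=0.0)
    c_slice = formulation_count(spec, "water") / 20.0
    if c_slice <= inserted_target:
        raise ValueError("system_volume too small to host the target count")
    z = _grid((geometry.z_min, geometry.z_max), DEFAULT_SPACING)
    edges = np.linspace(geometry.z_min, geometry.z_max, 21)
    head_center = 0.5 * sum(geometry.headgroup_region)
    slice_idx = min(int((head_center - geometry.z_min) / (edges[1] - edges[0])), 19)
    in_head = (z >= edges[slice_idx]) & (z <= edges[slice_idx + 1])

    def build(dg_head: float) -> Profile:
        values = np.full(z.size, 60.0)  # effectively forbidden elsewhere
        values[in_head] = dg_head
        return Profile(z=z, values=values, kind="pmf",
                       metadata={"source": "synthetic water fixture", "steps": []})

    def planned_minus_target(dg_head: float) -> float:
        # pre-rounding count in the headgroup slice, for a smooth root
        lo, hi = edges[slice_idx], edges[slice_idx + 1]
        p = build(dg_head)
        inner = p.z[(p.z > lo) & (p.z < hi)]
        grid = np.concatenate(([lo], inner, [hi]))
        raw = c_slice * np.trapezoid(
            np.exp(-constants.beta * p.interp(grid)), grid) / (hi - lo)
        return raw - inserted_target

    # the grid-aware Boltzmann average makes the exact depth slightly off
    # the closed-form guess; solve for it numerically
    guess = -constants.rt * math.log(inserted_target / c_slice)
    dg = brentq(planned_minus_target, guess - 5.0, guess + 5.0, xtol=1e-10)
    return build(dg), spec, geometry, waters_present * 18.015
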