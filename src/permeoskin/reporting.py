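"""Configured pipelines: profiles -> permeability/ER reports, formulation ->
insertion plans, with deterministic JSON output and run manifests.

Reports are plain dicts, serializable with ``json.dumps(..., sort_keys=True)``
and reproducible bit-for-bit from the same config (no timestamps). Every
number in a report can be recomputed from the manifest: the config hash,
file paths, preprocessing steps and seeds are all recorded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import Constants
from .insertion import (FormulationSpec, Component, apply_headgroup_cap,
                        place_molecules, slice_counts)
from .permeability import enhancement_ratio, permeability_coefficient
from .profiles import (BilayerGeometry, Profile, friction_to_diffusion,
                       read_profile, repair_edges, rolling_median, shift_pmf,
                       symmetrize, write_profile)


@dataclass
class SystemFiles:
    """Input files for one permeant/formulation system."""

    pmf: str
    diffusion: str | None = None
    friction: str | None = None
    dialect: str = "xvg"

    def __post_init__(self) -> None:
        if (self.diffusion is None) == (self.friction is None):
            raise ValueError("give exactly one of diffusion or friction per system")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study conditions.

    305.15 K, 30 stacked bilayers, 20 insertion slices, a 2.5x headgroup
    mass cap and 50% ethanol evaporation.
    """

    temperature: float = 305.15
    n_bilayers: int = 30
    n_slices: int = 20
    cap_ratio: float = 2.5
    ethanol_evaporation_fraction: float = 0.5
    seed: int = 0
    median_width: float = 0.2
    repair_points: int = 2
    symmetrize_pmf: bool = False
    symmetrize_friction: bool = False
    systems: dict[str, SystemFiles] = field(default_factory=dict)
    reference: str | None = None
    formulation: dict | None = None
    water_mass_present: float | None = None
    box: tuple[float, float] = (5.5, 5.5)

    def __post_init__(self) -> None:
        for name, val in (("temperature", self.temperature),
                          ("n_bilayers", self.n_bilayers),
                          ("n_slices", self.n_slices),
                          ("cap_ratio", self.cap_ratio),
                          ("median_width", self.median_width)):
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not 0 <= self.ethanol_evaporation_fraction <= 1:
            raise ValueError("ethanol_evaporation_fraction must lie in [0, 1]")
        self.systems = {
            k: v if isinstance(v, SystemFiles) else SystemFiles(**v)
            for k, v in self.systems.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def constants(self) -> Constants:
        return Constants(temperature=self.temperature)

    def manifest_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_system(files: SystemFiles, config: RunConfig) -> tuple[Profile, Profile]:
    """Read and preprocess one system's PMF and diffusion profiles."""
    pmf = read_profile(files.pmf, kind="pmf", dialect=files.dialect)
    if config.symmetrize_pmf:
        pmf = symmetrize(pmf)
    pmf = repair_edges(pmf, config.repair_points)
    pmf = shift_pmf(pmf)
    if files.friction is not None:
        fr = read_profile(files.friction, kind="friction", dialect=files.dialect)
        if config.symmetrize_friction:
            fr = symmetrize(fr)
        diffusion = friction_to_diffusion(fr)
    else:
        diffusion = read_profile(files.diffusion, kind="diffusion",
                                 dialect=files.dialect)
    diffusion = rolling_median(diffusion, config.median_width)
    return pmf, diffusion


def run_permeability_report(config: RunConfig, out_dir=None) -> dict:
    """Compute K_P/log K_P for every configured system, plus ER vs reference.

    When ``out_dir`` is given, the cumulative resistance profile of each
    system is written as a CSV sidecar next to the report.
    """
    if not config.systems:
        raise ValueError("no systems configured")
    if config.reference is not None and config.reference not in config.systems:
        raise ValueError(f"reference system {config.reference!r} not configured")
    constants = config.constants
    results: dict[str, dict] = {}
    objects = {}
    for name, files in sorted(config.systems.items()):
        pmf, diffusion = _load_system(files, config)
        res = permeability_coefficient(pmf, diffusion, constants,
                                       n_bilayers=config.n_bilayers)
        objects[name] = res
        results[name] = {
            "kp_cm_per_h": res.kp,
            "log_kp": res.log_kp,
            "single_bilayer_resistance_h_per_cm":
                float(res.resistance_profile.values[-1]) / config.n_bilayers,
            "preprocessing": list(pmf.metadata.get("steps", [])),
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            sidecar = out_dir / f"resistance_{name}.csv"
            write_profile(res.resistance_profile, sidecar, dialect="csv")
            results[name]["resistance_csv"] = sidecar.name
    if config.reference is not None:
        ref = objects[config.reference]
        for name, res in objects.items():
            results[name]["er_vs_reference"] = enhancement_ratio(res, ref)
    return {
        "manifest": {
            "config_hash": config.manifest_hash(),
            "temperature_K": config.temperature,
            "n_bilayers": config.n_bilayers,
            "reference": config.reference,
        },
        "systems": results,
    }


def formulation_from_config(config: RunConfig) -> FormulationSpec:
    if config.formulation is None:
        raise ValueError("no formulation configured")
    fdata = dict(config.formulation)
    comps = [Component(**c) for c in fdata.pop("components")]
    fdata.setdefault("ethanol_evaporation_fraction",
                     config.ethanol_evaporation_fraction)
    return FormulationSpec(components=comps, **fdata)


def run_insertion_report(config: RunConfig, pmf_by_component: dict[str, Profile],
                         geometry: BilayerGeometry | None = None,
                         out_dir=None) -> dict:
    """Insertion plans for every formulation component with a transfer PMF.

    ``pmf_by_component`` maps component names to formulation-referenced
    transfer free-energy profiles. Returns the plan JSON plus a summary
    table (component, C, total inserted, capped flag); optionally writes a
    flat placement CSV per component.
    """
    geometry = geometry or BilayerGeometry()
    spec = formulation_from_config(config)
    constants = config.constants
    components_out: dict[str, dict] = {}
    summary_rows = []
    inserted_head_mass = 0.0
    for name in sorted(pmf_by_component):
        pmf = pmf_by_component[name]
        plan = slice_counts(pmf, spec, name, config.n_slices, constants, geometry)
        if config.water_mass_present is not None:
            plan = apply_headgroup_cap(plan, geometry, config.water_mass_present,
                                       config.cap_ratio,
                                       already_inserted_mass=inserted_head_mass)
            inserted_head_mass += plan.mass("headgroup", geometry)
        plan = place_molecules(plan, config.box, seed=config.seed)
        components_out[name] = {
            "C": plan.metadata["C"],
            "total_inserted": plan.total,
            "capped": plan.capped,
            "headgroup_mass_ratio": plan.metadata.get("headgroup_mass_ratio"),
            "per_slice": [
                {"slice": s.index, "z_lo": s.z_lo, "z_hi": s.z_hi, "count": s.count}
                for s in plan.per_slice
            ],
            "restraint_k_kj_mol_nm2": plan.restraint_k,
            "schedule_ns": {"growth": plan.metadata["growth_ns"],
                            "equilibration": plan.metadata["equilibration_ns"]},
        }
        summary_rows.append((name, plan.metadata["C"], plan.total, plan.capped))
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            with open(out_dir / f"placement_{name}.csv", "w") as fh:
                fh.write("molecule,x,y,z,restraint_k\n")
                for i, (x, y, zc) in enumerate(plan.lateral_positions or []):
                    fh.write(f"{i},{x!r},{y!r},{zc!r},{plan.restraint_k}\n")
    summary = "\n".join(
        f"{name:30s} C={c:12.1f} inserted={tot:6d} capped={capped}"
        for name, c, tot, capped in summary_rows)
    return {
        "manifest": {"config_hash": config.manifest_hash(),
                     "seed": config.seed,
                     "n_slices": config.n_slices,
                     "cap_ratio": config.cap_ratio},
        "components": components_out,
        "summary": summary,
    }
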