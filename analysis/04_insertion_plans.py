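#!/usr/bin/env python
"""Enhancer-insertion bookkeeping: densities, water cap, escalation series.

Reproduces the insertion accounting of the skin bilayer model: the pure
liquid thymol number density from its bulk density, the pure-water
insertion fixture (100 waters planned, 190 total, ratio 2.1 under the 2.5
headgroup cap), and the stepwise escalation series used when the planned
counts under-predict enhancement (16 -> 24 lauric-acid-like, 18 -> 36 -> 54
oleic-acid-like). Writes results/insertion.json.
"""

import json
from pathlib import Path

from permeoskin import (Constants, apply_headgroup_cap,
                        make_water_insertion_fixture, number_density_per_nm3,
                        place_molecules, scale_plan, slice_counts)
from permeoskin.datasets import THYMOL_DENSITY, THYMOL_MOLAR_MASS

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    constants = Constants()
    report = {}

    density = number_density_per_nm3(THYMOL_DENSITY * 1000.0, THYMOL_MOLAR_MASS)
    report["thymol_pure_liquid_per_nm3"] = round(density, 2)
    print(f"pure liquid thymol: {density:.2f} molecules/nm^3 "
          f"(density {THYMOL_DENSITY} g/cm^3, M {THYMOL_MOLAR_MASS} g/mol)")

    pmf, spec, geometry, water_mass = make_water_insertion_fixture()
    plan = slice_counts(pmf, spec, "water", 20, constants, geometry)
    capped = apply_headgroup_cap(plan, geometry, water_mass, cap_ratio=2.5)
    placed = place_molecules(capped, box=(5.5, 5.5), seed=SEED)
    ratio = capped.metadata["headgroup_mass_ratio"]
    report["water"] = {
        "planned": plan.total, "after_cap": capped.total,
        "resident": 90, "total_after_insertion": 90 + capped.total,
        "mass_ratio": round(ratio, 2), "capped": capped.capped,
        "placed_molecules": len(placed.lateral_positions),
    }
    print(f"pure-water vehicle: plan {plan.total} waters into the headgroup "
          f"slice; {90 + capped.total} total vs 90 resident "
          f"(ratio {ratio:.2f}, cap 2.5, capped={capped.capped})")

    series = {}
    pmf16 = make_water_insertion_fixture(inserted_target=16)[0]
    plan16 = slice_counts(pmf16, spec, "water", 20, constants, geometry)
    series["16_plus_50pct"] = scale_plan(plan16, 1.5).total
    pmf18 = make_water_insertion_fixture(inserted_target=18)[0]
    plan18 = slice_counts(pmf18, spec, "water", 20, constants, geometry)
    series["18_x2"] = scale_plan(plan18, 2.0).total
    series["18_x3"] = scale_plan(plan18, 3.0).total
    report["escalation"] = series
    print(f"escalation: 16 -> {series['16_plus_50pct']} (+50%), "
          f"18 -> {series['18_x2']} (x2) -> {series['18_x3']} (x3)")

    with open(OUT / "insertion.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    print(f"wrote {OUT / 'insertion.json'}")


if __name__ == "__main__":
    main()
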