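#!/usr/bin/env python
"""pH correction for naproxen and flux-design classification.

Applies the neutral-fraction (Henderson-Hasselbalch) correction to a weak
acid (naproxen, pKa 4.19) across the formulation pH range 2.9-4.8, then
classifies two formulation-referenced PMF minima (-5.4 kJ/mol naproxen in
water, -13 kJ/mol caffeine in water) into solubility- vs barrier-limited
regimes with their maximum solubility-driven flux gains. Writes
results/ionization_flux_design.json.
"""

import json
from pathlib import Path

import numpy as np

from permeoskin import (BarrierSpec, Constants, GaussianFeature, classify,
                        ionization_shift, make_pmf)
from permeoskin.datasets import (CAFFEINE_WATER_PMF_MIN, NAPROXEN_PKA,
                                 NAPROXEN_WATER_PMF_MIN)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    constants = Constants()
    report = {"naproxen_pka": NAPROXEN_PKA, "ph_shifts": {}}
    print(f"naproxen (weak acid, pKa {NAPROXEN_PKA}) neutral-fraction "
          "correction to log K_P:")
    for ph in (2.9, 3.5, 4.19, 4.8):
        shift = ionization_shift(NAPROXEN_PKA, ph)
        report["ph_shifts"][str(ph)] = round(shift, 3)
        print(f"  pH {ph:4.2f}: shift {shift:+.3f} log units")

    report["flux_design"] = {}
    for name, vmin in (("naproxen_in_water", NAPROXEN_WATER_PMF_MIN),
                       ("caffeine_in_water", CAFFEINE_WATER_PMF_MIN)):
        spec = BarrierSpec(baseline=0.0,
                           features=[GaussianFeature(3.2, 0.3, vmin)])
        verdict = classify(make_pmf(spec), constants)
        report["flux_design"][name] = {
            "pmf_min_kj_mol": round(verdict.pmf_min, 2),
            "regime": verdict.regime,
            "max_solubility_gain": round(verdict.max_solubility_gain, 1),
        }
        print(f"{name}: PMF minimum {verdict.pmf_min:.1f} kJ/mol -> "
              f"{verdict.regime}; raising the minimum to zero could "
              f"multiply flux by up to {verdict.max_solubility_gain:.1f}")
    print("caveat:", classify(make_pmf(BarrierSpec(
        baseline=0.0, features=[GaussianFeature(3.2, 0.3, -1.0)])),
        constants).caveat)

    with open(OUT / "ionization_flux_design.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    print(f"wrote {OUT / 'ionization_flux_design.json'}")


if __name__ == "__main__":
    main()
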