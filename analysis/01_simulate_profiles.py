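#!/usr/bin/env python
"""Generate the synthetic profile library every later step consumes.

Writes reference PMFs for a hydrophilic and a lipophilic permeant class,
enhancer-modified variants (main sphingoid-chain barrier lowered by 4 and
8 kJ/mol, mimicking what inserted enhancers do to the resistance profile),
a shared friction profile, and noisy three-replicate ensembles — all in the
XVG dialect under results/profiles/.
"""

from pathlib import Path

import numpy as np

from permeoskin import (GaussianFeature, make_friction, make_pmf,
                        make_replicates, reference_barrier_spec, write_profile)

OUT = Path(__file__).resolve().parent.parent / "results" / "profiles"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    written = []
    for cls in ("hydrophilic", "lipophilic"):
        spec = reference_barrier_spec(cls)
        ref = make_pmf(spec)
        write_profile(ref, OUT / f"pmf_{cls}_reference.xvg", "xvg")
        written.append(f"pmf_{cls}_reference.xvg")
        for reduction in (4.0, 8.0):
            enhanced = reference_barrier_spec(cls)
            enhanced.features.append(
                GaussianFeature(center=4.55, width=0.30, height=-reduction))
            p = make_pmf(enhanced)
            name = f"pmf_{cls}_enhancer_minus{int(reduction)}.xvg"
            write_profile(p, OUT / name, "xvg")
            written.append(name)
        for i, rep in enumerate(make_replicates(ref, n=3, sd=1.0, seed=SEED)):
            name = f"pmf_{cls}_replicate{i}.xvg"
            write_profile(rep, OUT / name, "xvg")
            written.append(name)
    write_profile(make_friction(), OUT / "friction.xvg", "xvg")
    written.append("friction.xvg")
    print(f"wrote {len(written)} profiles to {OUT}:")
    for name in written:
        print(f"  {name}")
    print("Barrier topography: main barrier 4-5 nm (sphingoid chains), "
          "minimum ~3.2 nm (headgroups), secondary barrier ~2.1 nm "
          "(fatty-acid chains); domain [0, 5.21] nm, 0.01 nm grid.")


if __name__ == "__main__":
    main()
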