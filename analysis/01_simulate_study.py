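#!/usr/bin/env python
"""Generate the synthetic chamber study.

Writes the full 7-treatment (400–1600 ppm) x 5-pot design to
``results/data/``: per-leaf gas-exchange ladders, adaxial/abaxial stomatal
coordinate fields with counts, per-stoma morphology, mesophyll anatomy and
tissue chemistry, plus ``truth.json`` with the generating parameters.
"""

import argparse
from pathlib import Path

from soyco2 import StudyConfig
from soyco2.io import write_study
from soyco2.simulate import generate_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    study = generate_study(StudyConfig(seed=args.seed))
    write_study(study, args.outdir)

    ge = study.gas_exchange
    print(f"wrote study (seed={args.seed}) to {args.outdir}")
    print(f"  {ge.groupby(['pot_id', 'leaf_id']).ngroups} A-Ci curves "
          f"x {ge.groupby(['pot_id', 'leaf_id']).size().iloc[0]} steps")
    print(f"  {len(study.stomata_fields)} stomatal fields, "
          f"{len(study.stomata_coords)} stomatal coordinates")
    print(f"  {len(study.chemistry)} chemistry samples, "
          f"{len(study.anatomy)} anatomy records")


if __name__ == "__main__":
    main()
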