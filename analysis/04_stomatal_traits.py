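#!/usr/bin/env python
"""Stomatal trait tables, percent changes and treatment ANOVAs.

Summarises density, size, shape index (SSI) and area index (SAI) per leaf
surface and CO2 level, computes percent changes versus the 400 ppm
baseline, and runs one-way (CO2) and two-way (CO2 x surface) ANOVAs on
the pot-level traits.  Writes ``results/stomatal_traits.csv`` and
``results/stomatal_percent_changes.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from soyco2 import one_way_anova, percent_change, summarize_stomata, two_way_anova
from soyco2.io import read_stomata_fields, read_stomata_morphology
from soyco2.stomata import pot_level_stomata


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    morph = read_stomata_morphology(args.datadir / "stomata_morphology.csv")
    fields = read_stomata_fields(args.datadir / "stomata_fields.csv")

    summary = summarize_stomata(morph, fields)
    args.outdir.mkdir(parents=True, exist_ok=True)
    summary.reset_index().to_csv(args.outdir / "stomatal_traits.csv", index=False)

    base = summary.xs(400, level="treatment_co2_ppm")
    changes = []
    for (co2, surface), row in summary.iterrows():
        if co2 == 400:
            continue
        for trait in ("density", "area_um2", "sai"):
            changes.append({
                "surface": surface, "trait": trait, "to_ppm": co2,
                "percent_change": percent_change(
                    base.loc[surface, f"{trait}_mean"], row[f"{trait}_mean"]),
            })
    pd.DataFrame(changes).to_csv(
        args.outdir / "stomatal_percent_changes.csv", index=False)

    pot = pot_level_stomata(morph, fields).reset_index()
    print("one-way ANOVA (CO2 effect) per surface:")
    for trait in ("density", "area_um2", "sai"):
        for surface, g in pot.groupby("surface"):
            groups = [grp[trait].to_numpy()
                      for _, grp in g.groupby("treatment_co2_ppm")]
            t = one_way_anova(groups)["factor"]
            print(f"  {trait:9s} {surface:8s} F={t.f:7.2f}  p={t.p:.2e}")

    print("two-way ANOVA (CO2 x surface):")
    for trait in ("density", "area_um2"):
        cells = {(co2, s): g[trait].to_numpy()
                 for (co2, s), g in pot.groupby(["treatment_co2_ppm", "surface"])}
        res = two_way_anova(cells)
        print(f"  {trait:9s} CO2 p={res['A'].p:.2e}  surface p={res['B'].p:.2e}"
              f"  interaction p={res['A:B'].p:.2e}")

    ad = summary.xs("adaxial", level="surface")["density_mean"]
    print(f"adaxial density change 400 -> 600 ppm: "
          f"{percent_change(ad.loc[400], ad.loc[600]):.0f} %")


if __name__ == "__main__":
    main()
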