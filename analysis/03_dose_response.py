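#!/usr/bin/env python
"""Quadratic dose–response of the fitted photosynthetic parameters.

Regresses per-pot Vcmax, J_max, the Vcmax/J_max ratio and the growth-CO2
A_n / G_s / WUE against treatment CO2, reporting the vertex (optimal CO2)
of each.  Requires ``results/aci_fits.csv`` plus the study gas-exchange
table; writes ``results/dose_response.csv``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from soyco2 import compute_wue, fit_quadratic
from soyco2.io import read_gas_exchange


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=Path("results/aci_fits.csv"))
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/dose_response.csv"))
    args = ap.parse_args()

    fits = pd.read_csv(args.fits)
    fits["vcmax_jmax_ratio"] = fits["vcmax"] / fits["jmax"]

    # measured leaf-level traits at each pot's growth CO2 step
    curves = read_gas_exchange(args.datadir / "gas_exchange.csv")
    leaf_rows = []
    for c in curves:
        idx = int(np.argmin(np.abs(c.ci - c.growth_co2)))
        p = c.points[idx]
        leaf_rows.append({
            "pot_id": c.pot_id,
            "an_growth": p.an,
            "gs_growth": p.gs,
            "wue_growth": compute_wue(p.an, p.tr),
        })
    fits = fits.merge(pd.DataFrame(leaf_rows), on="pot_id")

    rows = []
    for trait in ("vcmax", "jmax", "vcmax_jmax_ratio",
                  "an_growth", "gs_growth", "wue_growth"):
        f = fit_quadratic(fits["growth_co2_ppm"], fits[trait])
        rows.append({
            "trait": trait, "c0": f.c0, "c1": f.c1, "c2": f.c2, "r2": f.r2,
            "x_opt_ppm": f.x_opt, "opt_kind": f.opt_kind,
            "extrapolated": f.extrapolated,
        })
        opt = "extrapolated" if f.extrapolated else f"{f.x_opt:.0f} ppm"
        print(f"  {trait:18s} R^2={f.r2:.2f}  {f.opt_kind} at {opt}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
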