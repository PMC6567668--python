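"""Tissue carbon/nitrogen and non-structural carbohydrate summaries.

Concentrations are on a dry-weight basis (mg g⁻¹ DW).  Derived quantities:

* C/N ratio — a proxy for nitrogen dilution under elevated CO2;
* TNC (total non-structural carbohydrates) = soluble sugar + starch.

Both are computed per sample before averaging across the five pot
replicates per treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "ChemistrySample",
    "cn_ratio",
    "total_nonstructural_carbohydrate",
    "treatment_summary",
]


@dataclass(frozen=True)
class ChemistrySample:
    """One pot's tissue chemistry measurement (mg g⁻¹ DW)."""

    tissue: Literal["leaf", "stem", "root"]
    c: float
    n: float
    soluble_sugar: float
    starch: float
    treatment_co2: float
    pot_id: str = "pot"

    def __post_init__(self) -> None:
        for name in ("c", "n", "soluble_sugar", "starch"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.tissue not in ("leaf", "stem", "root"):
            raise DomainError(f"unknown tissue {self.tissue!r}")

    @property
    def cn(self) -> float:
        return cn_ratio(self.c, self.n)

    @property
    def tnc(self) -> float:
        return total_nonstructural_carbohydrate(self.soluble_sugar, self.starch)


def cn_ratio(c: float, n: float) -> float:
    """Carbon-to-nitrogen mass ratio (dimensionless)."""
    if not n > 0:
        raise DomainError(f"n must be > 0, got {n}")
    if c < 0:
        raise DomainError(f"c must be >= 0, got {c}")
    return c / n


def total_nonstructural_carbohydrate(soluble_sugar: float, starch: float) -> float:
    """TNC = soluble sugar + starch (mg g⁻¹)."""
    if soluble_sugar < 0 or starch < 0:
        raise DomainError("carbohydrate concentrations must be >= 0")
    return soluble_sugar + starch


def treatment_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of C, N, C/N, soluble sugar, starch and TNC per
    (tissue, treatment).

    ``samples`` is a tidy frame with columns ``pot_id, tissue,
    treatment_co2_ppm, c_mg_g, n_mg_g, soluble_sugar_mg_g, starch_mg_g``.
    Derived columns (C/N, TNC) are computed per sample and then averaged.
    Cells with a single sample get ``NaN`` SD; absent cells are simply
    absent rows (missing, not an error).
    """
    df = samples.copy()
    df["cn"] = [cn_ratio(c, n) for c, n in zip(df["c_mg_g"], df["n_mg_g"])]
    df["tnc_mg_g"] = [
        total_nonstructural_carbohydrate(s, st)
        for s, st in zip(df["soluble_sugar_mg_g"], df["starch_mg_g"])
    ]
    traits = ["c_mg_g", "n_mg_g", "cn", "soluble_sugar_mg_g", "starch_mg_g",
              "tnc_mg_g"]
    grouped = df.groupby(["tissue", "treatment_co2_ppm"])[traits]
    out = grouped.mean().add_suffix("_mean").join(
        grouped.std(ddof=1).add_suffix("_sd")
    )
    out["n_samples"] = grouped.size()
    return out
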