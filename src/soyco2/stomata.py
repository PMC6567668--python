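"""Stomatal morphometrics: density, shape index, area index and the
percent-change summaries used to compare CO2 treatments.

Definitions
-----------
* stomatal density SD = n_stomata / field_area (mm⁻²)
* stomatal shape index SSI = 100 * sqrt(SA) / SP (%), with SA the stomatal
  area (μm²) and SP the stomatal perimeter (μm).  The isoperimetric
  inequality caps SSI at 100 / (2*sqrt(pi)) ≈ 28.21 %, attained by a
  circle.
* stomatal area index SAI = SD * mean SA, i.e. total stomatal area per
  unit leaf area, expressed in % (with the μm² → mm² unit conversion the
  literal formula gives fractions of a percent; an optional ``scale``
  factor is provided because published tables are sometimes normalised
  per field rather than per mm² — the discrepancy is surfaced, never
  silently corrected).

Treatment summaries aggregate per pot (the biological replicate) and then
report mean ± SD across pots, with SSI computed per stoma and averaged
(mean of ratios) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "SSI_MAX",
    "StomaMorphology",
    "stomatal_density",
    "shape_index",
    "area_index",
    "percent_change",
    "adaxial_abaxial_ratio",
    "pot_level_stomata",
    "summarize_stomata",
]

#: Upper bound of the shape index, 100/(2*sqrt(pi)): a perfect circle.
SSI_MAX = 100.0 / (2.0 * math.sqrt(math.pi))


@dataclass(frozen=True)
class StomaMorphology:
    """Traced outline measurements of a single stoma (all μm / μm²)."""

    length: float
    width: float
    area: float
    perimeter: float
    surface: Literal["adaxial", "abaxial"]

    def __post_init__(self) -> None:
        for name in ("length", "width", "area", "perimeter"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        # isoperimetric inequality: no closed outline encloses more area
        # than a circle of the same perimeter
        if self.perimeter**2 < 4.0 * math.pi * self.area * (1.0 - 1e-9):
            raise DomainError(
                "perimeter^2 < 4*pi*area violates the isoperimetric inequality"
            )
        if self.surface not in ("adaxial", "abaxial"):
            raise DomainError(f"unknown surface {self.surface!r}")

    @property
    def ssi(self) -> float:
        return shape_index(self.area, self.perimeter)


def stomatal_density(n_stomata: float, field_area: float) -> float:
    """Stomata per mm²: count divided by observed field area (mm²)."""
    if not field_area > 0:
        raise DomainError(f"field_area must be > 0, got {field_area}")
    if n_stomata < 0:
        raise DomainError(f"n_stomata must be >= 0, got {n_stomata}")
    return n_stomata / field_area

def shape_index(area: float, perimeter: float) -> float:
    """SSI = 100 * sqrt(area) / perimeter, in percent."""
    if not area > 0:
        raise DomainError(f"area must be > 0, got {area}")
    if not perimeter > 0:
        raise DomainError(f"perimeter must be > 0, got {perimeter}")
    return 100.0 * math.sqrt(area) / perimeter


def area_index(density: float, mean_stoma_area: float, scale: float = 1.0) -> float:
    """SAI (%) = density (mm⁻²) * mean stoma area (μm²) * 1e-6 * 100 * scale.

    ``scale`` defaults to 1 (the literal total-stomatal-area-per-leaf-area
    definition with explicit unit conversion).
    """
    if density < 0:
        raise DomainError(f"density must be >= 0, got {density}")
    if not mean_stoma_area > 0:
        raise DomainError(f"mean_stoma_area must be > 0, got {mean_stoma_area}")
    if not scale > 0:
        raise DomainError(f"scale must be > 0, got {scale}")
    return density * mean_stoma_area * 1e-6 * 100.0 * scale


def percent_change(baseline: float, treatment: float, ndigits: int = 0) -> float:
    """Signed percent change 100*(treatment - baseline)/baseline, rounded
    half-up (away from zero) to ``ndigits`` decimals, so 36.50 -> 37."""
    if baseline == 0:
        raise DomainError("baseline must be nonzero")
    pct = float(100.0 * (treatment - baseline) / baseline)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(pct)).quantize(quantum, rounding=ROUND_HALF_UP))


def adaxial_abaxial_ratio(adaxial: float, abaxial: float) -> float:
    """Ratio of an upper-surface value to the corresponding lower-surface
    value (typically densities)."""
    if not abaxial > 0:
        raise DomainError(f"abaxial must be > 0, got {abaxial}")
    return adaxial / abaxial


_MORPH_COLS = ("length_um", "width_um", "area_um2", "perimeter_um")


def pot_level_stomata(
    morphology: pd.DataFrame,
    fields: pd.DataFrame,
    ssi_mode: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios",
    sai_scale: float = 1.0,
) -> pd.DataFrame:
    """Pot-level stomatal traits (the biological replicate scale).

    Parameters
    ----------
    morphology : DataFrame
        Per-stoma rows with columns ``pot_id, surface, treatment_co2_ppm,
        length_um, width_um, area_um2, perimeter_um``.
    fields : DataFrame
        Per-field counts with columns ``pot_id, surface, treatment_co2_ppm,
        field_id, n_stomata, field_area_mm2``.
    ssi_mode : str
        ``mean_of_ratios`` (default) averages per-stoma SSI; the
        alternative evaluates SSI at the pot-mean area and perimeter.
    sai_scale : float
        Extra multiplier on the literal SAI formula (see module docstring).

    Returns
    -------
    DataFrame indexed by (treatment_co2_ppm, surface, pot_id) with one
    column per trait (length, width, area, perimeter, ssi, density, sai).
    """
    morph = morphology.copy()
    morph["ssi"] = [
        shape_index(a, p) for a, p in zip(morph["area_um2"], morph["perimeter_um"])
    ]

    # pot-level aggregates (pot = biological replicate)
    pot_morph = morph.groupby(["treatment_co2_ppm", "surface", "pot_id"]).agg(
        length_um=("length_um", "mean"),
        width_um=("width_um", "mean"),
        area_um2=("area_um2", "mean"),
        perimeter_um=("perimeter_um", "mean"),
        ssi_mor=("ssi", "mean"),
    )
    pot_morph["ssi_rom"] = [
        shape_index(a, p)
        for a, p in zip(pot_morph["area_um2"], pot_morph["perimeter_um"])
    ]
    pot_morph["ssi"] = (
        pot_morph["ssi_mor"] if ssi_mode == "mean_of_ratios" else pot_morph["ssi_rom"]
    )

    pot_fields = fields.groupby(["treatment_co2_ppm", "surface", "pot_id"]).agg(
        n_total=("n_stomata", "sum"), area_total=("field_area_mm2", "sum")
    )
    pot_fields["density"] = [
        stomatal_density(n, a)
        for n, a in zip(pot_fields["n_total"], pot_fields["area_total"])
    ]

    pot = pot_morph.join(pot_fields[["density"]], how="inner")
    pot["sai"] = [
        area_index(d, a, scale=sai_scale)
        for d, a in zip(pot["density"], pot["area_um2"])
    ]
    return pot[["length_um", "width_um", "area_um2", "perimeter_um",
                "density", "ssi", "sai"]]


def summarize_stomata(
    morphology: pd.DataFrame,
    fields: pd.DataFrame,
    ssi_mode: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios",
    sai_scale: float = 1.0,
) -> pd.DataFrame:
    """Per (treatment, surface) stomatal trait table: mean ± SD across pots.

    Takes the same inputs as :func:`pot_level_stomata` and reduces the
    pot-level frame to ``<trait>_mean`` / ``<trait>_sd`` columns plus the
    replicate count ``n_pots``.
    """
    pot = pot_level_stomata(morphology, fields, ssi_mode, sai_scale)
    grouped = pot.groupby(["treatment_co2_ppm", "surface"])
    out = grouped.mean().add_suffix("_mean").join(
        grouped.std(ddof=1).add_suffix("_sd")
    )
    out["n_pots"] = grouped.size()
    return out
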