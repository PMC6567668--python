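"""Default trait profiles of the seven-treatment soybean CO2 chamber study.

These are the published per-treatment trait means and standard deviations
(n = 5 pots) that the synthetic-study generator uses as its quantitative
anchors: stomatal density and morphology per leaf surface, mesophyll cell
anatomy, tissue C/N, and soluble sugar / starch concentrations, each at
growth CO2 of 400, 600, 800, 1000, 1200, 1400 and 1600 ppm.

Two published SDs carry obvious transcription slips (orders of magnitude
above every neighbouring cell); they are stored at the plausible magnitude
(3.45 for palisade cell length at 800 ppm, 1.22 for palisade cell width at
800 ppm).

Accessors return tidy pandas DataFrames with columns
``(…grouping…, trait, co2_ppm, mean, sd)``.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

__all__ = [
    "CO2_LEVELS",
    "CI_LADDER",
    "POTS_PER_TREATMENT",
    "FIELD_AREA_MM2",
    "stomatal_profiles",
    "anatomy_profiles",
    "element_profiles",
    "carbohydrate_profiles",
    "stomatal_mean",
    "element_mean",
    "carbohydrate_mean",
    "anatomy_mean",
]

#: Growth-chamber CO2 treatments (ppm).
CO2_LEVELS: Tuple[int, ...] = (400, 600, 800, 1000, 1200, 1400, 1600)

#: Cuvette CO2 ladder of the A_n–C_i measurements (ppm).
CI_LADDER: Tuple[int, ...] = (
    50, 100, 150, 200, 300, 400, 600, 800, 1000, 1200, 1400, 1600
)

#: Pot replicates per chamber.
POTS_PER_TREATMENT: int = 5

#: Microscope field area (mm²); one field is 400 x 400 μm.
FIELD_AREA_MM2: float = 0.16

# (mean tuple over CO2_LEVELS, sd tuple over CO2_LEVELS)
_Profile = Tuple[Tuple[float, ...], Tuple[float, ...]]

# stomatal traits per surface: length/width/area/perimeter (μm, μm²),
# density (mm⁻²), shape index (%), area index (%)
_STOMATA: Dict[str, Dict[str, _Profile]] = {
    "adaxial": {
        "length_um": ((9.4, 9.7, 9.6, 9.6, 9.0, 9.5, 9.8),
                      (1.3, 1.6, 0.6, 0.8, 2.0, 0.5, 1.6)),
        "width_um": ((2.2, 1.8, 2.6, 1.7, 2.7, 2.4, 2.5),
                     (0.9, 0.4, 0.5, 0.2, 0.5, 0.5, 0.7)),
        "area_um2": ((92.6, 88.7, 105.4, 83.3, 126.4, 100.3, 103.9),
                     (16.2, 9.6, 5.2, 9.0, 24.1, 17.2, 11.0)),
        "perimeter_um": ((40.7, 45.0, 41.0, 37.9, 46.2, 40.5, 41.2),
                         (0.5, 1.0, 0.1, 0.2, 0.4, 0.3, 0.27)),
        "density_mm2": ((16.8, 7.3, 6.6, 17.8, 10.4, 11.4, 8.7),
                        (8.9, 4.9, 4.7, 5.3, 6.4, 6.3, 3.5)),
        "ssi_pct": ((24.0, 20.4, 25.0, 24.1, 24.3, 24.6, 24.7),
                    (1.3, 4.7, 0.2, 0.2, 2.4, 0.6, 0.7)),
        "sai_pct": ((9.4, 3.9, 4.2, 9.0, 7.9, 6.9, 5.4),
                    (1.7, 0.4, 0.3, 1.0, 1.5, 1.2, 0.6)),
    },
    "abaxial": {
        "length_um": ((9.6, 9.8, 9.5, 10.2, 8.9, 9.4, 9.2),
                      (1.7, 0.6, 0.8, 0.7, 0.6, 0.2, 0.1)),
        "width_um": ((3.1, 3.1, 3.2, 2.9, 3.0, 3.1, 2.8),
                     (0.9, 0.3, 0.3, 0.4, 0.4, 0.2, 0.1)),
        "area_um2": ((133.1, 123.9, 108.9, 102.3, 109.3, 113.9, 110.1),
                     (0.5, 16.5, 13.8, 6.1, 7.5, 9.2, 17.8)),
        "perimeter_um": ((42.8, 44.6, 41.1, 40.7, 40.7, 42.6, 41.8),
                         (5.5, 2.8, 3.1, 1.4, 2.0, 1.7, 3.3)),
        "density_mm2": ((101.3, 128.3, 95.7, 92.0, 104.8, 84.2, 111.4),
                        (20.1, 18.0, 10.8, 17.0, 9.7, 9.2, 17.8)),
        "ssi_pct": ((25.3, 24.9, 25.2, 24.9, 25.1, 25.0, 25.1),
                    (0.1, 0.1, 0.4, 0.1, 0.5, 0.4, 0.1)),
        "sai_pct": ((81.9, 96.3, 63.2, 57.1, 69.5, 58.2, 74.8),
                    (0.3, 12.8, 8.0, 3.4, 4.8, 4.72, 12.1)),
    },
}

#: Published adaxial/abaxial density ratio row (basis unstated in the
#: source table; kept for reference only, not derivable from the density
#: rows above).
ADAXIAL_ABAXIAL_RATIO: _Profile = (
    (0.23, 0.12, 0.13, 0.26, 0.21, 0.20, 0.09),
    (0.023, 0.022, 0.042, 0.002, 0.018, 0.013, 0.024),
)

# mesophyll anatomy per layer (μm, μm²) plus leaf-level traits
_ANATOMY: Dict[str, Dict[str, _Profile]] = {
    "palisade": {
        "cell_length_um": ((35.69, 39.14, 38.59, 42.03, 33.38, 29.76, 41.15),
                           (3.04, 3.43, 3.45, 5.23, 6.24, 4.47, 7.35)),
        "cell_width_um": ((9.35, 8.93, 7.90, 9.00, 7.25, 10.40, 8.13),
                          (1.76, 1.78, 1.22, 1.50, 1.29, 1.18, 2.00)),
        "cell_area_um2": ((303.3, 348.7, 275.0, 328.0, 213.1, 232.1, 303.5),
                          (39.6, 39.4, 76.2, 80.9, 46.3, 60.5, 88.9)),
        "cell_perimeter_um": ((83.0, 95.1, 80.6, 99.3, 71.4, 67.6, 100.9),
                              (6.4, 12.6, 9.9, 12.7, 9.4, 10.2, 19.3)),
    },
    "spongy": {
        "cell_length_um": ((20.72, 24.85, 22.61, 27.36, 19.87, 20.15, 20.07),
                           (2.43, 4.00, 5.45, 7.75, 3.11, 2.87, 5.11)),
        "cell_width_um": ((11.91, 12.04, 9.39, 10.54, 8.28, 12.68, 8.46),
                          (3.13, 3.75, 5.44, 3.71, 2.14, 2.15, 2.40)),
        "cell_area_um2": ((207.8, 265.3, 192.0, 258.9, 150.0, 215.6, 177.2),
                          (57.6, 88.4, 64.5, 24.5, 43.8, 53.0, 67.7)),
        "cell_perimeter_um": ((86.2, 76.88, 60.6, 71.4, 55.5, 55.6, 63.1),
                              (13.2, 13.8, 13.3, 21.7, 12.0, 13.7, 15.5)),
    },
    "leaf": {
        "palisade_spongy_ratio": ((1.88, 2.52, 2.59, 2.77, 2.13, 1.90, 1.75),
                                  (0.68, 0.23, 0.64, 0.54, 0.60, 0.49, 0.25)),
        "thickness_um": ((103.5, 126.9, 121.5, 125.4, 108.7, 108.0, 106.9),
                         (11.0, 9.9, 9.9, 12.7, 14.1, 12.2, 11.1)),
    },
}

# tissue C and N (mg g⁻¹ DW)
_ELEMENTS: Dict[str, Dict[str, _Profile]] = {
    "leaf": {
        "c_mg_g": ((403.60, 386.14, 390.54, 373.66, 393.30, 392.07, 395.71),
                   (0.33, 0.23, 0.24, 12.73, 0.70, 0.50, 0.37)),
        "n_mg_g": ((32.04, 30.56, 33.56, 31.61, 34.04, 32.61, 30.83),
                   (0.12, 0.22, 0.16, 1.00, 0.12, 0.07, 0.20)),
    },
    "stem": {
        "c_mg_g": ((375.71, 358.33, 348.84, 347.86, 335.51, 339.93, 359.40),
                   (0.66, 0.47, 0.17, 0.20, 0.05, 1.01, 0.30)),
        "n_mg_g": ((26.47, 32.58, 43.24, 45.85, 37.51, 42.24, 36.94),
                   (0.14, 0.19, 0.25, 0.41, 0.10, 0.12, 0.20)),
    },
    "root": {
        "c_mg_g": ((352.38, 347.81, 350.68, 354.78, 376.80, 378.59, 371.19),
                   (0.13, 0.42, 0.18, 0.52, 0.62, 2.97, 8.64)),
        "n_mg_g": ((26.08, 34.40, 38.35, 37.70, 36.79, 37.57, 33.59),
                   (0.29, 0.19, 0.09, 0.10, 0.25, 0.33, 3.33)),
    },
}

# soluble sugar and starch (mg g⁻¹ DW); TNC is their sum
_CARBOHYDRATES: Dict[str, Dict[str, _Profile]] = {
    "root": {
        "soluble_sugar_mg_g": ((58.4, 96.9, 61.2, 40.1, 63.4, 65.2, 52.1),
                               (5.0, 5.7, 5.3, 2.5, 2.0, 3.3, 5.0)),
        "starch_mg_g": ((26.8, 17.2, 25.6, 18.1, 18.4, 20.16, 13.3),
                        (3.3, 9.6, 2.3, 2.3, 1.1, 0.96, 1.5)),
    },
    "stem": {
        "soluble_sugar_mg_g": ((51.1, 59.7, 55.8, 64.5, 54.2, 47.2, 53.3),
                               (6.4, 4.9, 4.3, 7.4, 3.5, 1.2, 5.1)),
        "starch_mg_g": ((16.2, 20.2, 20.2, 11.7, 23.2, 16.2, 10.9),
                        (5.8, 2.7, 4.1, 0.3, 4.1, 0.7, 3.9)),
    },
    "leaf": {
        "soluble_sugar_mg_g": ((65.5, 30.5, 72.6, 59.0, 27.4, 29.7, 22.6),
                               (3.9, 5.0, 13.8, 13.3, 1.7, 7.6, 2.7)),
        "starch_mg_g": ((17.9, 26.0, 14.9, 27.5, 16.9, 15.8, 19.4),
                        (7.8, 5.3, 2.0, 4.4, 5.0, 1.7, 1.9)),
    },
}

#: Whole-plant (leaf+stem+root) carbohydrate rows as published.
TOTAL_CARBOHYDRATES: Dict[str, _Profile] = {
    "soluble_sugar_mg_g": ((182, 196, 212, 164, 145, 142, 128),
                           (3, 27, 41, 11, 30, 10, 9)),
    "starch_mg_g": ((61.0, 63.4, 60.7, 57.3, 58.5, 52.2, 43.5),
                    (11.3, 10.4, 4.4, 6.5, 8.2, 2.4, 6.4)),
    "tnc_mg_g": ((236, 250, 250, 221, 203, 194, 171),
                 (7, 19, 16, 5, 27, 8, 15)),
}


def _tidy(nested: Dict[str, Dict[str, _Profile]], key_name: str) -> pd.DataFrame:
    rows = []
    for group, traits in nested.items():
        for trait, (means, sds) in traits.items():
            for co2, m, s in zip(CO2_LEVELS, means, sds):
                rows.append(
                    {key_name: group, "trait": trait, "co2_ppm": co2,
                     "mean": m, "sd": s}
                )
    return pd.DataFrame(rows)


def stomatal_profiles() -> pd.DataFrame:
    """Stomatal trait means ± SD per surface and CO2 level."""
    return _tidy(_STOMATA, "surface")


def anatomy_profiles() -> pd.DataFrame:
    """Mesophyll cell anatomy means ± SD per layer and CO2 level."""
    return _tidy(_ANATOMY, "layer")


def element_profiles() -> pd.DataFrame:
    """Tissue C and N means ± SD per tissue and CO2 level."""
    return _tidy(_ELEMENTS, "tissue")


def carbohydrate_profiles() -> pd.DataFrame:
    """Soluble sugar and starch means ± SD per tissue and CO2 level."""
    return _tidy(_CARBOHYDRATES, "tissue")


def _lookup(nested, group, trait, co2, which):
    means, sds = nested[group][trait]
    idx = CO2_LEVELS.index(int(co2))
    return (means if which == "mean" else sds)[idx]


def stomatal_mean(surface: str, trait: str, co2: int, which: str = "mean") -> float:
    return _lookup(_STOMATA, surface, trait, co2, which)


def anatomy_mean(layer: str, trait: str, co2: int, which: str = "mean") -> float:
    return _lookup(_ANATOMY, layer, trait, co2, which)


def element_mean(tissue: str, trait: str, co2: int, which: str = "mean") -> float:
    return _lookup(_ELEMENTS, tissue, trait, co2, which)


def carbohydrate_mean(tissue: str, trait: str, co2: int, which: str = "mean") -> float:
    return _lookup(_CARBOHYDRATES, tissue, trait, co2, which)
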