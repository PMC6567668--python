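"""Seeded generator of a complete synthetic chamber study.

The generator reproduces the statistical structure the analysis chain
assumes: 7 CO2 treatments (400–1600 ppm) × 5 pots, a 12-step cuvette CO2
ladder per pot for the A_n–C_i curves, adaxial/abaxial stomatal coordinate
fields of 0.16 mm² with treatment-dependent density and hard-core
regularity, per-stoma morphology, mesophyll anatomy and tissue chemistry
drawn around the published treatment means/SDs.

FvCB truth follows smooth quadratic dose–response profiles by default
(Vcmax peaking near 600 ppm, J peaking near 390 ppm, R_d near 900 ppm),
so that downstream vertex estimation has a recoverable interior optimum;
all other traits are lookups at the published table means with Gaussian
(morphology: lognormal) noise at the published SDs.

Everything is deterministic given the study seed: each stage draws from a
named substream spawned from a single ``SeedSequence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import profiles
from .errors import PackingError
from .fvcb import ACiCurve, FvCBParams, GasExchangePoint, fvcb_curve
from .spatial import PointPattern, Window, simulate_csr, simulate_hardcore
from .stomata import SSI_MAX

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "default_fvcb_profile",
    "generate_aci_curve",
    "generate_study",
]

_STAGES = ("fvcb", "aci", "coords", "morphology", "anatomy", "chemistry")


def default_fvcb_profile(co2: float) -> Dict[str, float]:
    """Quadratic dose–response truth for the FvCB parameters.

    Vcmax peaks at 600 ppm, J at 390 ppm and R_d at 900 ppm growth CO2,
    echoing the bell-shaped responses the analysis is designed to detect.
    Units: μmol m⁻² s⁻¹.
    """
    return {
        "vcmax": 120.0 - 8.0e-5 * (co2 - 600.0) ** 2,
        "j": 190.0 - 9.0e-5 * (co2 - 390.0) ** 2,
        "rd": 2.2 - 2.0e-6 * (co2 - 900.0) ** 2,
    }


@dataclass(frozen=True)
class StudyConfig:
    """Design and noise parameters of the synthetic study.

    Defaults are the chamber study's own conditions: 7 treatments × 5
    pots, the 12-step cuvette ladder, 30 microscope fields of 0.16 mm²
    per surface, 6 measured stomata per surface and pot, gas-exchange
    noise of 0.5 μmol m⁻² s⁻¹, 5 % between-pot variation on the FvCB
    truth, hard-core inhibition radii of 30 μm (adaxial) / 20 μm
    (abaxial).
    """

    treatments: Tuple[int, ...] = profiles.CO2_LEVELS
    pots_per_treatment: int = profiles.POTS_PER_TREATMENT
    ci_steps: Tuple[float, ...] = profiles.CI_LADDER
    aci_noise_sd: float = 0.5
    pot_cv: float = 0.05
    fields_per_surface: int = 30
    stomata_measured_per_surface: int = 6
    window: Window = field(default_factory=Window)
    hardcore_radius_um: Tuple[float, float] = (30.0, 20.0)  # adaxial, abaxial
    fvcb_profile: Callable[[float], Dict[str, float]] = default_fvcb_profile
    ppfd: float = 1500.0
    tleaf: float = 25.0
    vpd_kpa: float = 1.2
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.treatments) < 2:
            raise ValueError("need >= 2 treatments")
        if self.aci_noise_sd < 0 or self.pot_cv < 0:
            raise ValueError("noise levels must be >= 0")


@dataclass
class SyntheticStudy:
    """All generated tables plus the generating truth.

    DataFrames follow the package's CSV schemas exactly, so every table
    round-trips through :mod:`soyco2.io`.
    """

    gas_exchange: pd.DataFrame
    stomata_morphology: pd.DataFrame
    stomata_fields: pd.DataFrame
    stomata_coords: pd.DataFrame
    windows: pd.DataFrame
    anatomy: pd.DataFrame
    chemistry: pd.DataFrame
    truth: Dict

    @property
    def aci_curves(self) -> list:
        """Parse the gas-exchange table into ACiCurve objects."""
        from .io import curves_from_frame

        return curves_from_frame(self.gas_exchange)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, named random substream for one generation stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES.index(stage),))
    )


def _lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws parameterised by their arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_aci_curve(
    truth: FvCBParams,
    ci_steps: Sequence[float],
    noise_sd: float,
    seed,
    growth_co2: float = 400.0,
    pot_id: str = "pot",
    leaf_id: str = "leaf",
    ppfd: float = 1500.0,
    tleaf: float = 25.0,
    vpd_kpa: float = 1.2,
) -> ACiCurve:
    """Forward FvCB model at the cuvette ladder plus i.i.d. Gaussian noise.

    ``noise_sd = 0`` reproduces the forward model exactly.  Stomatal
    conductance and transpiration are filled in with a simple empirical
    coupling (gs increasing with A_n, T_r = gs * VPD / P) so that the
    gas-exchange schema is complete.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ci = np.asarray(ci_steps, dtype=float)
    an_true, _ = fvcb_curve(truth, ci)
    an = an_true + rng.normal(0.0, noise_sd, len(ci)) if noise_sd > 0 else an_true
    gs = np.clip(0.01 + 0.012 * np.maximum(an, 0.0), 0.02, 2.0)
    tr = gs * vpd_kpa / 101.325 * 1000.0  # mmol m-2 s-1
    points = tuple(
        GasExchangePoint(
            ci=float(c), an=float(a), ppfd=ppfd, tleaf=tleaf,
            gs=float(g), tr=float(t), vpd=vpd_kpa,
        )
        for c, a, g, t in zip(ci, an, gs, tr)
    )
    return ACiCurve(
        points=points,
        growth_co2=growth_co2,
        leaf_id=leaf_id,
        pot_id=pot_id,
        rd_measured=truth.rd,
    )


def _generate_gas_exchange(cfg: StudyConfig):
    rng_truth = _stage_rng(cfg.seed, "fvcb")
    rng_noise = _stage_rng(cfg.seed, "aci")
    rows = []
    truth: Dict[str, Dict] = {}
    for co2 in cfg.treatments:
        base = cfg.fvcb_profile(co2)
        for pot in range(1, cfg.pots_per_treatment + 1):
            pot_id = f"T{co2}_P{pot}"
            factors = 1.0 + rng_truth.normal(0.0, cfg.pot_cv, 3)
            factors = np.clip(factors, 0.5, 1.5)
            params = FvCBParams(
                vcmax=base["vcmax"] * factors[0],
                j=base["j"] * factors[1],
                rd=max(base["rd"] * factors[2], 0.05),
            )
            curve = generate_aci_curve(
                params, cfg.ci_steps, cfg.aci_noise_sd, rng_noise,
                growth_co2=co2, pot_id=pot_id, leaf_id="L1",
                ppfd=cfg.ppfd, tleaf=cfg.tleaf, vpd_kpa=cfg.vpd_kpa,
            )
            truth[pot_id] = {
                "growth_co2": co2,
                "vcmax": params.vcmax,
                "j": params.j,
                "rd": params.rd,
            }
            for p in curve.points:
                rows.append(
                    {
                        "pot_id": pot_id,
                        "leaf_id": "L1",
                        "growth_co2_ppm": co2,
                        "ci_umol_mol": p.ci,
                        "an_umol_m2_s": p.an,
                        "gs_mol_m2_s": p.gs,
                        "tr_mmol_m2_s": p.tr,
                        "ppfd_umol_m2_s": p.ppfd,
                        "tleaf_c": p.tleaf,
                        "vpd_kpa": p.vpd,
                    }
                )
    return pd.DataFrame(rows), truth


def _generate_coords(cfg: StudyConfig):
    rng = _stage_rng(cfg.seed, "coords")
    surfaces = ("adaxial", "abaxial")
    win = cfg.window
    area_mm2 = win.area * 1e-6
    coord_rows, field_rows, window_rows = [], [], []
    for co2 in cfg.treatments:
        for pot in range(1, cfg.pots_per_treatment + 1):
            pot_id = f"T{co2}_P{pot}"
            for surface, r_min in zip(surfaces, cfg.hardcore_radius_um):
                density = profiles.stomatal_mean(surface, "density_mm2", co2)
                for fld in range(1, cfg.fields_per_surface + 1):
                    field_id = f"{pot_id}_{surface}_F{fld}"
                    n = int(rng.poisson(density * area_mm2))
                    if n > 0:
                        try:
                            pat = simulate_hardcore(n, win, r_min, rng)
                        except PackingError:
                            warnings.warn(
                                f"hard-core packing infeasible for {field_id}; "
                                "falling back to CSR"
                            )
                            pat = simulate_csr(n, win, rng)
                    else:
                        pat = PointPattern(np.empty((0, 2)), win)
                    field_rows.append(
                        {
                            "field_id": field_id,
                            "pot_id": pot_id,
                            "surface": surface,
                            "treatment_co2_ppm": co2,
                            "n_stomata": n,
                            "field_area_mm2": area_mm2,
                        }
                    )
                    window_rows.append(
                        {
                            "field_id": field_id,
                            "width_um": win.width,
                            "height_um": win.height,
                        }
                    )
                    for x, y in pat.coords:
                        coord_rows.append(
                            {
                                "field_id": field_id,
                                "surface": surface,
                                "treatment_co2_ppm": co2,
                                "x_um": round(float(x), 3),
                                "y_um": round(float(y), 3),
                            }
                        )
    return (
        pd.DataFrame(coord_rows),
        pd.DataFrame(field_rows),
        pd.DataFrame(window_rows),
    )


def _generate_morphology(cfg: StudyConfig) -> pd.DataFrame:
    """Per-stoma outlines: area and length/width lognormal around the
    treatment means; perimeter derived from a truncated-normal shape index
    so the isoperimetric constraint holds by construction."""
    rng = _stage_rng(cfg.seed, "morphology")
    rows = []
    k = cfg.stomata_measured_per_surface
    for co2 in cfg.treatments:
        for pot in range(1, cfg.pots_per_treatment + 1):
            pot_id = f"T{co2}_P{pot}"
            for surface in ("adaxial", "abaxial"):
                m = lambda t: profiles.stomatal_mean(surface, t, co2, "mean")
                s = lambda t: profiles.stomatal_mean(surface, t, co2, "sd")
                length = _lognormal(rng, m("length_um"), s("length_um"), k)
                width = _lognormal(rng, m("width_um"), s("width_um"), k)
                area = _lognormal(rng, m("area_um2"), s("area_um2"), k)
                ssi = np.clip(
                    rng.normal(m("ssi_pct"), s("ssi_pct"), k), 5.0, SSI_MAX - 1e-6
                )
                perimeter = 100.0 * np.sqrt(area) / ssi
                for i in range(k):
                    rows.append(
                        {
                            "pot_id": pot_id,
                            "surface": surface,
                            "treatment_co2_ppm": co2,
                            "field_id": f"{pot_id}_{surface}_F{(i % cfg.fields_per_surface) + 1}",
                            "length_um": round(float(length[i]), 3),
                            "width_um": round(float(width[i]), 3),
                            "area_um2": round(float(area[i]), 3),
                            "perimeter_um": round(float(perimeter[i]), 3),
                        }
                    )
    return pd.DataFrame(rows)


def _generate_anatomy(cfg: StudyConfig) -> pd.DataFrame:
    rng = _stage_rng(cfg.seed, "anatomy")
    prof = profiles.anatomy_profiles()
    rows = []
    for co2 in cfg.treatments:
        sub = prof[prof["co2_ppm"] == co2]
        for pot in range(1, cfg.pots_per_treatment + 1):
            pot_id = f"T{co2}_P{pot}"
            for _, r in sub.iterrows():
                value = max(rng.normal(r["mean"], r["sd"]), 0.01)
                rows.append(
                    {
                        "pot_id": pot_id,
                        "treatment_co2_ppm": co2,
                        "layer": r["layer"],
                        "trait": r["trait"],
                        "value": round(float(value), 4),
                    }
                )
    return pd.DataFrame(rows)


def _generate_chemistry(cfg: StudyConfig) -> pd.DataFrame:
    rng = _stage_rng(cfg.seed, "chemistry")
    rows = []
    for co2 in cfg.treatments:
        for pot in range(1, cfg.pots_per_treatment + 1):
            pot_id = f"T{co2}_P{pot}"
            for tissue in ("leaf", "stem", "root"):
                draw = lambda kind, trait: max(
                    rng.normal(
                        kind(tissue, trait, co2, "mean"),
                        kind(tissue, trait, co2, "sd"),
                    ),
                    0.1,
                )
                rows.append(
                    {
                        "pot_id": pot_id,
                        "tissue": tissue,
                        "treatment_co2_ppm": co2,
                        "c_mg_g": round(draw(profiles.element_mean, "c_mg_g"), 3),
                        "n_mg_g": round(draw(profiles.element_mean, "n_mg_g"), 3),
                        "soluble_sugar_mg_g": round(
                            draw(profiles.carbohydrate_mean, "soluble_sugar_mg_g"), 3
                        ),
                        "starch_mg_g": round(
                            draw(profiles.carbohydrate_mean, "starch_mg_g"), 3
                        ),
                    }
                )
    return pd.DataFrame(rows)


def generate_study(config: Optional[StudyConfig] = None) -> SyntheticStudy:
    """Generate the full synthetic study, deterministic under the seed."""
    cfg = config or StudyConfig()
    gas_exchange, fvcb_truth = _generate_gas_exchange(cfg)
    coords, fields, windows = _generate_coords(cfg)
    morphology = _generate_morphology(cfg)
    anatomy = _generate_anatomy(cfg)
    chemistry = _generate_chemistry(cfg)
    truth = {
        "seed": cfg.seed,
        "treatments": list(cfg.treatments),
        "pots_per_treatment": cfg.pots_per_treatment,
        "fvcb": fvcb_truth,
        "fvcb_profile_at_treatments": {
            str(c): cfg.fvcb_profile(c) for c in cfg.treatments
        },
        "hardcore_radius_um": {
            "adaxial": cfg.hardcore_radius_um[0],
            "abaxial": cfg.hardcore_radius_um[1],
        },
        "aci_noise_sd": cfg.aci_noise_sd,
        "pot_cv": cfg.pot_cv,
    }
    return SyntheticStudy(
        gas_exchange=gas_exchange,
        stomata_morphology=morphology,
        stomata_fields=fields,
        stomata_coords=coords,
        windows=windows,
        anatomy=anatomy,
        chemistry=chemistry,
        truth=truth,
    )
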