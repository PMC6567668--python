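"""End-to-end analysis pipeline over a study directory.

Stages (each logs its seed and aborts with its name on failure):

1. **simulate/load** — generate the synthetic study (or read an existing
   one) from ``data_dir``;
2. **fit-aci** — FvCB fit per leaf (Vcmax, J_max, R_d);
3. **dose-response** — quadratic fits of the recovered Vcmax, J_max,
   Vcmax/J_max ratio and of growth-CO2 A_n, G_s and WUE against treatment
   CO2, with vertex optima;
4. **stomata** — per-surface trait table, percent-change matrix, one-way
   ANOVA per trait and the two-way CO2 × surface ANOVA;
5. **ripley** — K/L analysis with Monte Carlo CSR envelopes on a fixed
   number of fields per treatment × surface;
6. **chemistry** — C/N and TNC treatment summaries.

Outputs a machine-readable ``report.json`` (byte-identical across reruns
of the same config) and human-readable CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io
from .chemistry import treatment_summary
from .dose_response import fit_quadratic, one_way_anova, two_way_anova
from .errors import SoyCO2Error
from .fvcb import FitConfig, compute_wue, fit_aci
from .simulate import StudyConfig, generate_study
from .spatial import PointPattern, Window, analyze_pattern
from .stomata import percent_change, pot_level_stomata, summarize_stomata

__all__ = ["run_pipeline"]

log = logging.getLogger("soyco2.pipeline")


class StageError(SoyCO2Error):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SoyCO2Error as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("simulate/load")
def _load_data(cfg: io.RunConfig) -> Dict[str, pd.DataFrame]:
    data_dir = Path(cfg.data_dir)
    marker = data_dir / "gas_exchange.csv"
    if cfg.simulate and not marker.exists():
        log.info("simulating study into %s (seed=%d)", data_dir, cfg.seed)
        study = generate_study(StudyConfig(seed=cfg.seed))
        io.write_study(study, data_dir)
    return io.read_study(data_dir)


@_stage("fit-aci")
def _fit_curves(cfg: io.RunConfig, data) -> pd.DataFrame:
    curves = io.curves_from_frame(data["gas_exchange"])
    fit_cfg = FitConfig(rd_policy=cfg.rd_policy)
    rows = []
    for curve in curves:
        fit = fit_aci(curve, fit_cfg)
        growth = curve.growth_co2
        # measured point at the growth CO2 step of the ladder
        idx = int(np.argmin(np.abs(curve.ci - growth)))
        p = curve.points[idx]
        wue = compute_wue(p.an, p.tr) if p.tr else np.nan
        rows.append(
            {
                "pot_id": curve.pot_id,
                "leaf_id": curve.leaf_id,
                "growth_co2_ppm": growth,
                "vcmax": fit.params.vcmax,
                "jmax": fit.params.j,
                "rd": fit.params.rd,
                "vcmax_jmax_ratio": fit.params.vcmax / fit.params.j,
                "transition_ci": fit.transition_ci,
                "sse": fit.sse,
                "r2": fit.r2,
                "an_growth": p.an,
                "gs_growth": p.gs if p.gs is not None else np.nan,
                "wue_growth": wue,
            }
        )
    return pd.DataFrame(rows)


@_stage("dose-response")
def _dose_response(fits: pd.DataFrame) -> Dict:
    out: Dict = {}
    for trait in ("vcmax", "jmax", "vcmax_jmax_ratio",
                  "an_growth", "gs_growth", "wue_growth"):
        sub = fits[["growth_co2_ppm", trait]].dropna()
        fit = fit_quadratic(sub["growth_co2_ppm"], sub[trait])
        out[trait] = {
            "c0": fit.c0,
            "c1": fit.c1,
            "c2": fit.c2,
            "r2": fit.r2,
            "x_opt_ppm": fit.x_opt,
            "opt_kind": fit.opt_kind,
            "extrapolated": fit.extrapolated,
            "n": fit.n,
        }
    return out


@_stage("stomata")
def _stomata(cfg: io.RunConfig, data) -> Dict:
    morph = data["stomata_morphology"]
    fields = data["stomata_fields"]
    pot = pot_level_stomata(morph, fields, cfg.ssi_mode, cfg.sai_scale)
    summary = summarize_stomata(morph, fields, cfg.ssi_mode, cfg.sai_scale)

    baseline_co2 = summary.index.get_level_values(0).min()
    changes = []
    for (co2, surface), row in summary.iterrows():
        if co2 == baseline_co2:
            continue
        for trait in ("density", "area_um2", "sai"):
            base = summary.loc[(baseline_co2, surface)][f"{trait}_mean"]
            changes.append(
                {
                    "surface": surface,
                    "trait": trait,
                    "from_ppm": baseline_co2,
                    "to_ppm": co2,
                    "percent_change": percent_change(base, row[f"{trait}_mean"]),
                }
            )

    anova_one_way = {}
    for trait in ("density", "area_um2", "ssi", "sai"):
        per_surface = {}
        for surface, g in pot.reset_index().groupby("surface"):
            groups = [
                grp[trait].to_numpy()
                for _, grp in g.groupby("treatment_co2_ppm")
            ]
            res = one_way_anova(groups)["factor"]
            per_surface[surface] = {"F": res.f, "p": res.p,
                                    "df": [res.df_num, res.df_den]}
        anova_one_way[trait] = per_surface

    anova_two_way = {}
    flat = pot.reset_index()
    for trait in ("density", "area_um2"):
        cells = {
            (co2, surf): g[trait].to_numpy()
            for (co2, surf), g in flat.groupby(["treatment_co2_ppm", "surface"])
        }
        res = two_way_anova(cells)
        anova_two_way[trait] = {
            "co2": {"F": res["A"].f, "p": res["A"].p},
            "surface": {"F": res["B"].f, "p": res["B"].p},
            "co2_x_surface": {"F": res["A:B"].f, "p": res["A:B"].p},
        }

    return {
        "summary": summary.reset_index(),
        "percent_changes": changes,
        "anova_one_way": anova_one_way,
        "anova_two_way": anova_two_way,
    }


@_stage("ripley")
def _ripley(cfg: io.RunConfig, data) -> pd.DataFrame:
    coords = data["stomata_coords"]
    windows = data["windows"].set_index("field_id")
    fields = data["stomata_fields"]
    seeds = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(101,))
    rows = []
    eligible = fields[fields["n_stomata"] >= cfg.ripley_min_points]
    for (co2, surface), g in eligible.groupby(["treatment_co2_ppm", "surface"]):
        chosen = g.sort_values("field_id").head(cfg.ripley_fields_per_group)
        for field_id in chosen["field_id"]:
            sub = coords[coords["field_id"] == field_id]
            win = Window(
                width=float(windows.loc[field_id, "width_um"]),
                height=float(windows.loc[field_id, "height_um"]),
            )
            pattern = PointPattern(
                sub[["x_um", "y_um"]].to_numpy(), win,
                surface=surface, treatment_co2=co2,
            )
            child = seeds.spawn(1)[0]
            res = analyze_pattern(
                pattern, n_sims=cfg.n_sims, alpha=cfg.alpha,
                seed=np.random.default_rng(child),
            )
            labels, counts = np.unique(res.labels, return_counts=True)
            tally = dict(zip(labels.tolist(), counts.tolist()))
            rows.append(
                {
                    "field_id": field_id,
                    "surface": surface,
                    "treatment_co2_ppm": co2,
                    "n_points": pattern.n,
                    "regular_d_min_um": res.regular_range[0]
                    if res.regular_range else np.nan,
                    "regular_d_max_um": res.regular_range[1]
                    if res.regular_range else np.nan,
                    "n_regular_scales": tally.get("regular", 0),
                    "n_random_scales": tally.get("random", 0),
                    "n_clustered_scales": tally.get("clustered", 0),
                    "min_lhat_um": float(np.nanmin(res.lhat[1:])),
                }
            )
    return pd.DataFrame(rows)


@_stage("chemistry")
def _chemistry(data) -> pd.DataFrame:
    return treatment_summary(data["chemistry"]).reset_index()


def run_pipeline(config: Optional[io.RunConfig] = None) -> Dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report dictionary; rerunning with an identical config
    produces a byte-identical ``report.json``.
    """
    cfg = config or io.RunConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    data = _load_data(cfg)
    fits = _fit_curves(cfg, data)
    dose = _dose_response(fits)
    stomata = _stomata(cfg, data)
    ripley = _ripley(cfg, data)
    chem = _chemistry(data)

    fits.to_csv(out_dir / "aci_fits.csv", index=False)
    stomata["summary"].to_csv(out_dir / "stomatal_traits.csv", index=False)
    pd.DataFrame(stomata["percent_changes"]).to_csv(
        out_dir / "stomatal_percent_changes.csv", index=False
    )
    ripley.to_csv(out_dir / "ripley_fields.csv", index=False)
    chem.to_csv(out_dir / "chemistry_summary.csv", index=False)

    report = {
        "config": asdict(cfg),
        "n_treatments": int(fits["growth_co2_ppm"].nunique()),
        "n_curves": int(len(fits)),
        "aci_fits": fits.to_dict(orient="records"),
        "dose_response": dose,
        "stomata": {
            "percent_changes": stomata["percent_changes"],
            "anova_one_way": stomata["anova_one_way"],
            "anova_two_way": stomata["anova_two_way"],
        },
        "ripley": ripley.to_dict(orient="records"),
        "chemistry": chem.to_dict(orient="records"),
    }
    io.write_json(report, out_dir / "report.json")
    return report
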