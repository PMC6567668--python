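"""CSV/JSON readers and writers for every table in the analysis chain.

All tables are plain UTF-8 CSV with a mandatory header, comma separator
and '.' decimal; nested fit results go to JSON with sorted keys so that
reruns are byte-identical.  Readers validate the schema up front
(:class:`~soyco2.errors.SchemaError` names the missing columns) and report
non-numeric cells with their line numbers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .fvcb import ACiCurve, GasExchangePoint

__all__ = [
    "GAS_EXCHANGE_COLUMNS",
    "RunConfig",
    "read_gas_exchange",
    "curves_from_frame",
    "read_stomata_morphology",
    "read_stomata_fields",
    "read_stomata_coords",
    "read_windows",
    "read_chemistry",
    "read_anatomy",
    "write_study",
    "read_study",
    "write_json",
]

PathLike = Union[str, Path]

GAS_EXCHANGE_COLUMNS = (
    "pot_id", "leaf_id", "growth_co2_ppm", "ci_umol_mol", "an_umol_m2_s",
    "gs_mol_m2_s", "tr_mmol_m2_s", "ppfd_umol_m2_s", "tleaf_c", "vpd_kpa",
)
_MORPH_COLUMNS = (
    "pot_id", "surface", "treatment_co2_ppm", "field_id",
    "length_um", "width_um", "area_um2", "perimeter_um",
)
_FIELD_COLUMNS = (
    "field_id", "pot_id", "surface", "treatment_co2_ppm",
    "n_stomata", "field_area_mm2",
)
_COORD_COLUMNS = ("field_id", "surface", "treatment_co2_ppm", "x_um", "y_um")
_WINDOW_COLUMNS = ("field_id", "width_um", "height_um")
_CHEM_COLUMNS = (
    "pot_id", "tissue", "treatment_co2_ppm", "c_mg_g", "n_mg_g",
    "soluble_sugar_mg_g", "starch_mg_g",
)
_ANATOMY_COLUMNS = ("pot_id", "treatment_co2_ppm", "layer", "trait", "value")

_NON_NUMERIC = {"pot_id", "leaf_id", "field_id", "surface", "tissue",
                "layer", "trait"}


def _read_csv(path: PathLike, required) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # malformed file / not CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in required:
        if col in _NON_NUMERIC:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = converted
    return df


def curves_from_frame(df: pd.DataFrame) -> List[ACiCurve]:
    """Group a gas-exchange table into per-leaf A_n–C_i curves, sorted by
    C_i (row order in the file is irrelevant)."""
    curves = []
    for (pot_id, leaf_id), g in df.groupby(["pot_id", "leaf_id"], sort=True):
        g = g.sort_values("ci_umol_mol")
        points = tuple(
            GasExchangePoint(
                ci=row.ci_umol_mol,
                an=row.an_umol_m2_s,
                ppfd=row.ppfd_umol_m2_s,
                tleaf=row.tleaf_c,
                gs=None if pd.isna(row.gs_mol_m2_s) else row.gs_mol_m2_s,
                tr=None if pd.isna(row.tr_mmol_m2_s) else row.tr_mmol_m2_s,
                vpd=None if pd.isna(row.vpd_kpa) else row.vpd_kpa,
            )
            for row in g.itertuples()
        )
        curves.append(
            ACiCurve(
                points=points,
                growth_co2=float(g["growth_co2_ppm"].iloc[0]),
                leaf_id=str(leaf_id),
                pot_id=str(pot_id),
            )
        )
    return curves


def read_gas_exchange(path: PathLike) -> List[ACiCurve]:
    """Read a gas-exchange CSV into a list of :class:`ACiCurve`."""
    return curves_from_frame(_read_csv(path, GAS_EXCHANGE_COLUMNS))


def read_stomata_morphology(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, _MORPH_COLUMNS)


def read_stomata_fields(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, _FIELD_COLUMNS)


def read_stomata_coords(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, _COORD_COLUMNS)


def read_windows(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, _WINDOW_COLUMNS)


def read_chemistry(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, _CHEM_COLUMNS)


def read_anatomy(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, _ANATOMY_COLUMNS)


_STUDY_FILES = {
    "gas_exchange": "gas_exchange.csv",
    "stomata_morphology": "stomata_morphology.csv",
    "stomata_fields": "stomata_fields.csv",
    "stomata_coords": "stomata_coords.csv",
    "windows": "windows.csv",
    "anatomy": "anatomy.csv",
    "chemistry": "chemistry.csv",
}


def write_study(study, outdir: PathLike) -> Path:
    """Write every table of a :class:`~soyco2.simulate.SyntheticStudy` as
    CSV plus the generating truth as ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _STUDY_FILES.items():
        getattr(study, attr).to_csv(outdir / fname, index=False)
    write_json(study.truth, outdir / "truth.json")
    return outdir


def read_study(datadir: PathLike) -> Dict[str, pd.DataFrame]:
    """Read a study directory back into validated DataFrames (plus truth,
    when present)."""
    datadir = Path(datadir)
    readers = {
        "gas_exchange": GAS_EXCHANGE_COLUMNS,
        "stomata_morphology": _MORPH_COLUMNS,
        "stomata_fields": _FIELD_COLUMNS,
        "stomata_coords": _COORD_COLUMNS,
        "windows": _WINDOW_COLUMNS,
        "anatomy": _ANATOMY_COLUMNS,
        "chemistry": _CHEM_COLUMNS,
    }
    out: Dict = {}
    for key, cols in readers.items():
        out[key] = _read_csv(datadir / _STUDY_FILES[key], cols)
    truth_path = datadir / "truth.json"
    if truth_path.exists():
        out["truth"] = json.loads(truth_path.read_text())
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload, path: PathLike) -> Path:
    """Deterministic JSON dump (sorted keys, stable float repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
        + "\n"
    )
    return path


@dataclasses.dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline.

    Unknown keys in a YAML config are rejected (typos should fail loudly,
    not silently fall back to defaults).
    """

    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 1
    simulate: bool = True  # generate the study if data_dir has no CSVs
    rd_policy: str = "fit"
    n_sims: int = 100
    alpha: float = 0.05
    ripley_fields_per_group: int = 2
    ripley_min_points: int = 8
    sai_scale: float = 1.0
    ssi_mode: str = "mean_of_ratios"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_sims < 20:
            raise SchemaError("n_sims must be >= 20")
        if not 0 < self.alpha < 1:
            raise SchemaError("alpha must be in (0, 1)")
        if self.rd_policy not in ("fit", "measured"):
            raise SchemaError("rd_policy must be 'fit' or 'measured'")
        if self.ssi_mode not in ("mean_of_ratios", "ratio_of_means"):
            raise SchemaError("unknown ssi_mode")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)
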