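"""Farquhar–von Caemmerer–Berry (FvCB) model of C3 photosynthesis and
estimation of its parameters from A_n–C_i curves.

The FvCB model describes net CO2 assimilation A_n as the minimum of two
potential rates:

* the Rubisco-limited (carboxylation-limited) rate, which dominates at low
  intercellular CO2 (C_i)::

      A_c = Vcmax * (C_i - Γ*) / (C_i + Kc * (1 + O / Ko)) - R_d

* the RuBP-regeneration-limited (electron-transport-limited) rate, which
  dominates at high C_i::

      A_j = J * (C_i - Γ*) / (4 * C_i + 8 * Γ*) - R_d

with Vcmax the maximum carboxylation rate, J the potential electron
transport rate at the measurement irradiance, R_d day respiration, Γ* the
CO2 compensation point in the absence of R_d, and Kc/Ko the Michaelis
constants of Rubisco for CO2/O2.  Mesophyll conductance is taken as
infinite (C_c = C_i); kinetic constants default to standard 25 °C values.

Under saturating light the fitted J is conventionally reported as J_max;
:func:`jmax_from_j` provides the optional non-rectangular-hyperbola
inversion when the measurement light was not saturating.

Units throughout: C_i in μmol mol⁻¹ (≈ μbar at ambient pressure), rates in
μmol m⁻² s⁻¹, Ko and O in mbar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import lsq_linear

from .errors import DomainError, FitError

__all__ = [
    "GasExchangePoint",
    "ACiCurve",
    "FvCBParams",
    "FvCBFit",
    "DEFAULT_KINETICS_25C",
    "fvcb_assimilation",
    "fvcb_curve",
    "fit_aci",
    "compute_wue",
    "jmax_from_j",
]

#: Standard Rubisco kinetic constants at 25 °C (Kc μbar, Ko mbar, Γ* μbar,
#: O mbar).  Used whenever a fit or forward run does not override them.
DEFAULT_KINETICS_25C = {
    "kc": 404.9,
    "ko": 278.4,
    "gamma_star": 42.75,
    "o": 210.0,
}

Limb = Literal["rubisco", "rubp"]


@dataclass(frozen=True)
class GasExchangePoint:
    """One cuvette step of a gas-exchange measurement.

    Parameters
    ----------
    ci : float
        Intercellular CO2, μmol mol⁻¹ (> 0).
    an : float
        Net assimilation, μmol CO2 m⁻² s⁻¹.
    ppfd : float
        Photon flux density, μmol m⁻² s⁻¹ (>= 0).
    tleaf : float
        Leaf temperature, °C.
    gs, tr, vpd : float, optional
        Stomatal conductance (mol H2O m⁻² s⁻¹), transpiration
        (mmol H2O m⁻² s⁻¹) and vapour pressure deficit (kPa).
    """

    ci: float
    an: float
    ppfd: float = 1500.0
    tleaf: float = 25.0
    gs: Optional[float] = None
    tr: Optional[float] = None
    vpd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ci > 0:
            raise DomainError(f"ci must be > 0, got {self.ci}")
        if self.ppfd < 0:
            raise DomainError(f"ppfd must be >= 0, got {self.ppfd}")
        if self.gs is not None and not self.gs > 0:
            raise DomainError(f"gs must be > 0 when given, got {self.gs}")
        if self.tr is not None and not self.tr > 0:
            raise DomainError(f"tr must be > 0 when given, got {self.tr}")


@dataclass(frozen=True)
class ACiCurve:
    """An ordered A_n–C_i response curve for one leaf.

    Points are sorted by C_i on construction; at least six points and
    strictly increasing C_i (no duplicated cuvette steps) are required.
    """

    points: Tuple[GasExchangePoint, ...]
    growth_co2: float
    leaf_id: str = "leaf"
    pot_id: str = "pot"
    rd_measured: Optional[float] = None

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.ci))
        object.__setattr__(self, "points", pts)
        if len(pts) < 6:
            raise FitError(
                f"insufficient points: A-Ci curve needs >= 6, got {len(pts)}"
            )
        ci = [p.ci for p in pts]
        if any(b <= a for a, b in zip(ci, ci[1:])):
            raise DomainError("ci values must be strictly increasing after sorting")

    @property
    def ci(self) -> np.ndarray:
        return np.array([p.ci for p in self.points])

    @property
    def an(self) -> np.ndarray:
        return np.array([p.an for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FvCBParams:
    """FvCB model parameters (all strictly positive)."""

    vcmax: float
    j: float
    rd: float
    gamma_star: float = DEFAULT_KINETICS_25C["gamma_star"]
    kc: float = DEFAULT_KINETICS_25C["kc"]
    ko: float = DEFAULT_KINETICS_25C["ko"]
    o: float = DEFAULT_KINETICS_25C["o"]

    def __post_init__(self) -> None:
        for name in ("vcmax", "j", "rd", "gamma_star", "kc", "ko", "o"):
            v = getattr(self, name)
            if not v > 0:
                raise DomainError(f"{name} must be strictly positive, got {v}")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc * (1 + O/Ko), μbar."""
        return self.kc * (1.0 + self.o / self.ko)


@dataclass(frozen=True)
class FvCBFit:
    """Result of fitting the FvCB model to one A_n–C_i curve."""

    params: FvCBParams
    transition_ci: float
    limb_labels: Tuple[Limb, ...]
    sse: float
    r2: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "vcmax": self.params.vcmax,
            "j": self.params.j,
            "jmax": self.params.j,
            "rd": self.params.rd,
            "gamma_star": self.params.gamma_star,
            "kc": self.params.kc,
            "ko": self.params.ko,
            "o": self.params.o,
            "transition_ci": self.transition_ci,
            "limb_labels": list(self.limb_labels),
            "sse": self.sse,
            "r2": self.r2,
            "n_points": self.n_points,
        }


def _rubisco_rate(params: FvCBParams, ci):
    return params.vcmax * (ci - params.gamma_star) / (ci + params.km) - params.rd


def _rubp_rate(params: FvCBParams, ci):
    return params.j * (ci - params.gamma_star) / (
        4.0 * ci + 8.0 * params.gamma_star
    ) - params.rd


def fvcb_assimilation(params: FvCBParams, ci: float) -> Tuple[float, Limb]:
    """Net assimilation at a single C_i: the minimum of the two limbs.

    Returns ``(an, limb)`` where ``limb`` names the limiting process
    (ties resolve to ``"rubisco"``).
    """
    if not ci > 0:
        raise DomainError(f"ci must be > 0, got {ci}")
    ac = _rubisco_rate(params, ci)
    aj = _rubp_rate(params, ci)
    if ac <= aj:
        return ac, "rubisco"
    return aj, "rubp"


def fvcb_curve(params: FvCBParams, ci: Sequence[float]) -> Tuple[np.ndarray, list]:
    """Vectorised forward model: min-limb A_n and per-point limb labels."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise DomainError("all ci must be > 0")
    ac = _rubisco_rate(params, ci)
    aj = _rubp_rate(params, ci)
    an = np.minimum(ac, aj)
    labels = ["rubisco" if a <= b else "rubp" for a, b in zip(ac, aj)]
    return an, labels


def compute_wue(an: float, tr: float) -> float:
    """Leaf water-use efficiency WUE = A_n / T_r (μmol CO2 / mmol H2O)."""
    if not tr > 0:
        raise DomainError(f"tr must be > 0, got {tr}")
    return an / tr


def jmax_from_j(j: float, ppfd: float, theta: float = 0.9, alpha: float = 0.3) -> float:
    """Invert the non-rectangular hyperbola to recover J_max from J.

    The light response J(I) solves theta*J² − (alpha*I + Jmax)*J +
    alpha*I*Jmax = 0; solving for Jmax given J at irradiance I = ppfd gives
    ``Jmax = J * (alpha*I − theta*J) / (alpha*I − J)``.  Only needed when
    the measurement light was not saturating.
    """
    if not 0 < theta < 1:
        raise DomainError(f"theta must be in (0, 1), got {theta}")
    i_abs = alpha * ppfd
    if i_abs <= j:
        raise DomainError(
            f"alpha*ppfd = {i_abs} must exceed j = {j}: light insufficient"
        )
    return j * (i_abs - theta * j) / (i_abs - j)


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitConfig:
    """Options for :func:`fit_aci`.

    rd_policy:
        ``"fit"`` estimates R_d jointly (bounded to ``rd_bounds``);
        ``"measured"`` fixes R_d to the curve's measured dark respiration.
    """

    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS_25C))
    rd_policy: Literal["fit", "measured"] = "fit"
    rd_bounds: Tuple[float, float] = (0.0, 10.0)
    vj_upper: float = 2000.0


def _fit_partition(ci, an, split, cfg: FitConfig, rd_fixed: Optional[float]):
    """Exact bounded linear least squares for one limb partition.

    With fixed kinetic constants the partitioned model is linear in
    (Vcmax, J, R_d):  A_i = Vcmax*f1_i  (i < split),  J*f2_i  (i >= split),
    minus R_d everywhere.
    """
    gs = cfg.kinetics["gamma_star"]
    km = cfg.kinetics["kc"] * (1.0 + cfg.kinetics["o"] / cfg.kinetics["ko"])
    n = len(ci)
    f1 = (ci - gs) / (ci + km)
    f2 = (ci - gs) / (4.0 * ci + 8.0 * gs)
    mask_c = np.arange(n) < split
    a1 = np.where(mask_c, f1, 0.0)
    a2 = np.where(mask_c, 0.0, f2)
    if rd_fixed is None:
        design = np.column_stack([a1, a2, -np.ones(n)])
        lo = np.array([1e-9, 1e-9, cfg.rd_bounds[0]])
        hi = np.array([cfg.vj_upper, cfg.vj_upper, cfg.rd_bounds[1]])
        res = lsq_linear(design, an, bounds=(lo, hi), method="bvls", tol=1e-14)
        vcmax, j, rd = res.x
    else:
        design = np.column_stack([a1, a2])
        lo = np.array([1e-9, 1e-9])
        hi = np.array([cfg.vj_upper, cfg.vj_upper])
        res = lsq_linear(design, an + rd_fixed, bounds=(lo, hi), method="bvls",
                         tol=1e-14)
        vcmax, j = res.x
        rd = rd_fixed
    pred = design @ res.x - (0.0 if rd_fixed is None else rd_fixed)
    sse = float(np.sum((pred - an) ** 2))
    return (vcmax, j, rd), sse, res.success


def fit_aci(curve: ACiCurve, config: Optional[FitConfig] = None) -> FvCBFit:
    """Estimate (Vcmax, J, R_d) from an A_n–C_i curve.

    Every admissible transition between consecutive observed C_i values
    with at least three points on each limb is tried; for each, the limb
    assignment is fixed by the transition and the parameters solved by
    bounded linear least squares (exact for this model).  The partition
    with minimal SSE wins; ties break toward the lower transition C_i.
    Under the saturating-light convention the fitted J is reported as
    J_max.
    """
    cfg = config or FitConfig()
    ci = curve.ci
    an = curve.an
    n = len(ci)
    if cfg.rd_policy == "measured":
        if curve.rd_measured is None:
            raise FitError("rd_policy='measured' but curve has no rd_measured")
        rd_fixed = float(curve.rd_measured)
    else:
        rd_fixed = None

    best = None  # (sse, split, params)
    any_success = False
    for split in range(3, n - 2):  # >= 3 points on each limb
        params, sse, ok = _fit_partition(ci, an, split, cfg, rd_fixed)
        if not ok:
            continue
        any_success = True
        if best is None or sse < best[0] - 1e-12:
            best = (sse, split, params)
    if best is None:
        if not any_success:
            raise FitError("optimizer failed to converge on every partition")
        raise FitError("no admissible limb partition (need >= 3 points per limb)")

    sse, split, (vcmax, j, rd) = best
    rd = max(rd, 1e-9)  # FvCBParams requires strict positivity
    params = FvCBParams(vcmax=vcmax, j=j, rd=rd, **{
        "gamma_star": cfg.kinetics["gamma_star"],
        "kc": cfg.kinetics["kc"],
        "ko": cfg.kinetics["ko"],
        "o": cfg.kinetics["o"],
    })
    labels: Tuple[Limb, ...] = tuple(
        "rubisco" if i < split else "rubp" for i in range(n)
    )
    transition_ci = 0.5 * (ci[split - 1] + ci[split])
    sst = float(np.sum((an - an.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2 = min(1.0, max(0.0, r2))
    return FvCBFit(
        params=params,
        transition_ci=float(transition_ci),
        limb_labels=labels,
        sse=sse,
        r2=r2,
        n_points=n,
    )
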