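"""Dose–response regression across CO2 treatments and fixed-effects ANOVA.

The CO2 optimum of a trait is estimated as the vertex of an ordinary
least-squares quadratic y = c0 + c1*x + c2*x², x_opt = -c1 / (2*c2) — a
maximum when c2 < 0.  Vertices far outside the dosed range are flagged as
extrapolated rather than suppressed.

ANOVA is the classical balanced decomposition: one-way F = MSB/MSW and the
two-factor model with interaction (balanced complete designs only, which
sidesteps sum-of-squares type ambiguity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError, FitError

__all__ = [
    "QuadraticFit",
    "LinearFit",
    "AnovaTerm",
    "AnovaResult",
    "fit_quadratic",
    "fit_linear",
    "one_way_anova",
    "two_way_anova",
]


@dataclass(frozen=True)
class QuadraticFit:
    c0: float
    c1: float
    c2: float
    r2: float
    x_opt: Optional[float]
    opt_kind: Optional[str]  # "maximum" | "minimum"
    extrapolated: bool
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.c0 + self.c1 * x + self.c2 * x**2


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AnovaTerm:
    name: str
    f: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    terms: Dict[str, AnovaTerm]

    def __getitem__(self, name: str) -> AnovaTerm:
        return self.terms[name]


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """OLS quadratic with vertex-based optimum.

    Requires at least four observations over at least three distinct x (the
    design must have full rank).  The vertex is reported as extrapolated
    when it lies outside the dosed range widened by half its span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("x and y must have equal length")
    if len(x) < 4 or len(np.unique(x)) < 4:
        raise FitError("quadratic fit needs >= 4 observations at >= 4 distinct x")
    design = np.column_stack([np.ones_like(x), x, x**2])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient (collinear) quadratic design")
    c0, c1, c2 = coef
    resid = y - design @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    r2 = min(1.0, max(0.0, r2))
    if c2 == 0.0:
        x_opt, opt_kind, extrapolated = None, None, False
    else:
        x_opt = -c1 / (2.0 * c2)
        opt_kind = "maximum" if c2 < 0 else "minimum"
        span = x.max() - x.min()
        extrapolated = not (
            x.min() - 0.5 * span <= x_opt <= x.max() + 0.5 * span
        )
    return QuadraticFit(float(c0), float(c1), float(c2), r2,
                        None if x_opt is None else float(x_opt),
                        opt_kind, extrapolated, len(x))


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS line with r² and the two-sided p-value of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("x and y must have equal length")
    if len(x) < 3:
        raise FitError("linear fit needs >= 3 observations")
    if np.ptp(x) == 0:
        raise FitError("zero variance in x")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MSB/MSW on (k-1, N-k) df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DomainError("one-way ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise DomainError("every group needs >= 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n_total = len(all_vals)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    df1, df2 = k - 1, n_total - k
    msw = ssw / df2
    f = (ssb / df1) / msw if msw > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return AnovaResult({"factor": AnovaTerm("factor", float(f), df1, df2, p)})


def two_way_anova(
    cells: Mapping[Tuple[object, object], Sequence[float]]
) -> AnovaResult:
    """Balanced two-factor fixed-effects ANOVA with interaction.

    ``cells`` maps (level_A, level_B) to the replicate values of that cell;
    the design must be complete and balanced with >= 2 replicates per cell.
    Returns F and p for factor A, factor B and the A × B interaction.
    """
    a_levels = sorted({k[0] for k in cells}, key=repr)
    b_levels = sorted({k[1] for k in cells}, key=repr)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise DomainError("both factors need >= 2 levels")
    missing = [
        (a, b) for a in a_levels for b in b_levels if (a, b) not in cells
    ]
    if missing:
        raise DomainError(f"incomplete design: missing cells {missing}")
    sizes = {len(cells[(a, b)]) for a in a_levels for b in b_levels}
    if len(sizes) != 1:
        raise DomainError(
            "unbalanced design: aggregate to equal replication per cell "
            "(unequal-n sum-of-squares types are out of scope)"
        )
    r = sizes.pop()
    if r < 2:
        raise DomainError("need >= 2 replicates per cell")

    a_n, b_n = len(a_levels), len(b_levels)
    data = np.array(
        [[np.asarray(cells[(a, b)], dtype=float) for b in b_levels]
         for a in a_levels]
    )  # shape (a, b, r)
    grand = data.mean()
    mean_ab = data.mean(axis=2)
    mean_a = data.mean(axis=(1, 2))
    mean_b = data.mean(axis=(0, 2))

    ss_a = r * b_n * float(np.sum((mean_a - grand) ** 2))
    ss_b = r * a_n * float(np.sum((mean_b - grand) ** 2))
    ss_ab = r * float(
        np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    )
    ss_e = float(np.sum((data - mean_ab[:, :, None]) ** 2))

    df_a, df_b = a_n - 1, b_n - 1
    df_ab = df_a * df_b
    df_e = a_n * b_n * (r - 1)
    mse = ss_e / df_e

    def term(name: str, ss: float, df: int) -> AnovaTerm:
        if ss <= 1e-300:  # no effect at all, regardless of MSE
            return AnovaTerm(name, 0.0, df, df_e, 1.0)
        f = (ss / df) / mse if mse > 0 else np.inf
        p = float(stats.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
        return AnovaTerm(name, float(f), df, df_e, p)

    return AnovaResult(
        {
            "A": term("A", ss_a, df_a),
            "B": term("B", ss_b, df_b),
            "A:B": term("A:B", ss_ab, df_ab),
        }
    )
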