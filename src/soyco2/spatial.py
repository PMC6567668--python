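"""Spatial point-pattern analysis of stomatal coordinates.

Implements Ripley's K-function with translation edge correction, the
variance-stabilised L-transform ``Lhat(d) = sqrt(K(d)/pi) - d`` (zero in
expectation under complete spatial randomness, negative for regular /
inhibited patterns, positive for clustered ones), pointwise Monte Carlo
CSR envelopes, per-scale pattern classification, and the point-process
simulators (binomial CSR, simple sequential inhibition hard-core, Thomas
cluster) used as null and control models.

Coordinates are in μm inside a rectangular observation window with the
origin at the lower-left corner; the default window is 400 × 400 μm
(0.16 mm², one microscope field).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import pdist

from .errors import AnalysisError, DomainError, PackingError

__all__ = [
    "Window",
    "PointPattern",
    "KFunctionResult",
    "default_distance_grid",
    "ripley_k",
    "l_transform",
    "csr_envelope",
    "classify_scales",
    "analyze_pattern",
    "simulate_csr",
    "simulate_hardcore",
    "simulate_cluster",
]

Correction = Literal["none", "translation"]
RngLike = Union[int, np.random.Generator, None]

#: jitter applied to exactly coincident digitised points (μm)
_JITTER = 0.01


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, lower-left origin, μm."""

    width: float = 400.0
    height: float = 400.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise DomainError("window sides must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def max_valid_distance(self) -> float:
        """Half the shorter side: validity bound of the translation
        correction."""
        return 0.5 * min(self.width, self.height)


@dataclass
class PointPattern:
    """Point coordinates (μm) inside a window.

    Exactly coincident points (digitisation artefacts) are deterministically
    nudged apart by at most 0.01 μm with a warning, since inter-point
    distances of zero are not handled by the K estimator.
    """

    coords: np.ndarray
    window: Window = field(default_factory=Window)
    surface: Optional[str] = None
    treatment_co2: Optional[float] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if c.size and (
            c[:, 0].min() < 0
            or c[:, 1].min() < 0
            or c[:, 0].max() > self.window.width
            or c[:, 1].max() > self.window.height
        ):
            raise DomainError("all points must lie inside the window")
        c = self._dejitter(c)
        self.coords = c

    def _dejitter(self, c: np.ndarray) -> np.ndarray:
        if len(c) < 2:
            return c
        _, inverse, counts = np.unique(
            c, axis=0, return_inverse=True, return_counts=True
        )
        if counts.max() <= 1:
            return c
        warnings.warn(
            "duplicate coordinates jittered by <= 0.01 um", stacklevel=2
        )
        c = c.copy()
        seen: dict = {}
        for i, key in enumerate(inverse):
            k = int(key)
            rank = seen.get(k, 0)
            seen[k] = rank + 1
            if rank:
                # deterministic sub-jitter nudge, kept inside the window
                dx = _JITTER * rank / counts[k]
                c[i, 0] = min(c[i, 0] + dx, self.window.width)
                c[i, 1] = min(c[i, 1] + dx / 2.0, self.window.height)
        return c

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def intensity(self) -> float:
        return self.n / self.window.area


def default_distance_grid(
    window: Optional[Window] = None, step: float = 2.0, d_max: float = 200.0
) -> np.ndarray:
    """Distance grid 0..d_max in ``step`` μm increments, capped at the
    window's validity bound."""
    if window is not None:
        d_max = min(d_max, window.max_valid_distance)
    return np.arange(0.0, d_max + 0.5 * step, step)


def _pair_weights(
    coords: np.ndarray, window: Window, correction: Correction
) -> Tuple[np.ndarray, np.ndarray]:
    """Distances and edge-correction weights for all unordered pairs."""
    d = pdist(coords)
    if correction == "none":
        w = np.ones_like(d)
    elif correction == "translation":
        dx = pdist(coords[:, :1])
        dy = pdist(coords[:, 1:])
        overlap = (window.width - dx) * (window.height - dy)
        w = window.area / overlap
    else:
        raise DomainError(f"unknown correction {correction!r}")
    return d, w


def ripley_k(
    pattern: PointPattern,
    distances: Sequence[float],
    correction: Correction = "translation",
) -> np.ndarray:
    """Ripley's K estimate on a distance grid.

    ``Khat(d) = |W| / (n (n-1)) * sum_{i != j} w_ij 1(d_ij <= d)`` with
    w_ij = 1 (``correction="none"``) or the translation weight
    |W| / area(W ∩ W shifted by x_j − x_i).

    Distances beyond half the shorter window side (where the translation
    correction loses validity) are returned as NaN with a warning.
    """
    if pattern.n < 2:
        raise AnalysisError(f"Ripley's K needs n >= 2 points, got {pattern.n}")
    distances = np.asarray(distances, dtype=float)
    bound = pattern.window.max_valid_distance
    valid = distances <= bound + 1e-9
    if not valid.all():
        warnings.warn(
            f"distances beyond the validity bound {bound:g} um truncated",
            stacklevel=2,
        )
    d, w = _pair_weights(pattern.coords, pattern.window, correction)
    order = np.argsort(d)
    d_sorted = d[order]
    w_cum = np.concatenate([[0.0], np.cumsum(w[order])])
    idx = np.searchsorted(d_sorted, distances, side="right")
    # each unordered pair contributes twice to the i != j double sum
    khat = 2.0 * w_cum[idx] * pattern.window.area / (pattern.n * (pattern.n - 1))
    khat[~valid] = np.nan
    return khat


def l_transform(khat: Sequence[float], distances: Sequence[float]) -> np.ndarray:
    """Variance-stabilised transform Lhat(d) - d = sqrt(Khat/pi) - d."""
    khat = np.asarray(khat, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if np.any(khat[~np.isnan(khat)] < 0):
        raise AnalysisError("khat must be nonnegative")
    return np.sqrt(khat / math.pi) - distances


def simulate_csr(n: int, window: Window, seed: RngLike = None) -> PointPattern:
    """Binomial process: exactly n i.i.d. uniform points in the window."""
    if n < 0:
        raise DomainError("n must be >= 0")
    rng = _as_rng(seed)
    coords = rng.random((n, 2)) * np.array([window.width, window.height])
    return PointPattern(coords, window)


def simulate_hardcore(
    n: int,
    window: Window,
    r_min: float,
    seed: RngLike = None,
    max_attempts: int = 100_000,
) -> PointPattern:
    """Simple sequential inhibition: n points with all pairwise distances
    >= r_min, by rejection.  Raises :class:`PackingError` when infeasible
    (disk packing bound) or when ``max_attempts`` proposals are exhausted.
    """
    if n < 0:
        raise DomainError("n must be >= 0")
    if r_min < 0:
        raise DomainError("r_min must be >= 0")
    # random sequential adsorption jams near 0.547 coverage for disks
    if n * math.pi * (r_min / 2.0) ** 2 > 0.547 * window.area:
        raise PackingError(
            f"cannot pack {n} points with r_min={r_min} into the window"
        )
    rng = _as_rng(seed)
    pts: list = []
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(pts)}/{n} points after {max_attempts} attempts"
            )
        attempts += 1
        p = rng.random(2) * np.array([window.width, window.height])
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= r_min**2 for q in pts):
            pts.append(p)
    coords = np.array(pts).reshape(-1, 2)
    return PointPattern(coords, window)


def simulate_cluster(
    parent_intensity: float,
    mean_offspring: float,
    sigma: float,
    window: Window,
    seed: RngLike = None,
) -> PointPattern:
    """Thomas cluster process: Poisson parents, Poisson(mean_offspring)
    Gaussian-displaced children; children outside the window are dropped."""
    if parent_intensity <= 0 or mean_offspring <= 0 or sigma <= 0:
        raise DomainError("all Thomas-process parameters must be positive")
    rng = _as_rng(seed)
    n_parents = rng.poisson(parent_intensity * window.area)
    parents = rng.random((n_parents, 2)) * np.array([window.width, window.height])
    children = []
    for p in parents:
        k = rng.poisson(mean_offspring)
        offs = p + rng.normal(scale=sigma, size=(k, 2))
        inside = (
            (offs[:, 0] >= 0)
            & (offs[:, 0] <= window.width)
            & (offs[:, 1] >= 0)
            & (offs[:, 1] <= window.height)
        )
        children.append(offs[inside])
    coords = np.concatenate(children) if children else np.empty((0, 2))
    return PointPattern(coords, window)


def csr_envelope(
    n: int,
    window: Window,
    distances: Sequence[float],
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: RngLike = None,
    correction: Correction = "translation",
) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise Monte Carlo CSR envelope for Lhat(d) - d.

    Simulates ``n_sims`` binomial (fixed-n) CSR patterns and returns the
    empirical alpha/2 and 1 - alpha/2 quantiles of Lhat(d) - d at each
    grid distance.  Deterministic given ``seed``.
    """
    if n < 2:
        raise AnalysisError("envelope needs n >= 2 points")
    if n_sims < 20:
        raise AnalysisError(f"insufficient simulations: n_sims={n_sims} < 20")
    rng = _as_rng(seed)
    distances = np.asarray(distances, dtype=float)
    sims = np.empty((n_sims, len(distances)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sims):
            pat = simulate_csr(n, window, rng)
            sims[i] = l_transform(ripley_k(pat, distances, correction), distances)
    # Weibull plotting position: a fresh CSR draw falls outside each bound
    # with probability alpha/2 in expectation (rank k = p*(m+1))
    low = np.quantile(sims, alpha / 2.0, axis=0, method="weibull")
    high = np.quantile(sims, 1.0 - alpha / 2.0, axis=0, method="weibull")
    return low, high


def classify_scales(
    lhat: Sequence[float],
    envelope_low: Sequence[float],
    envelope_high: Sequence[float],
    distances: Sequence[float],
) -> Tuple[np.ndarray, Optional[Tuple[float, float]]]:
    """Label each scale regular / random / clustered against the envelope.

    ``regular`` where Lhat - d falls below the lower envelope, ``clustered``
    above the upper, ``random`` between.  Also returns the longest
    contiguous run of regular scales as (d_min, d_max), or None.
    """
    lhat = np.asarray(lhat, dtype=float)
    low = np.asarray(envelope_low, dtype=float)
    high = np.asarray(envelope_high, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if not (len(lhat) == len(low) == len(high) == len(distances)):
        raise AnalysisError("lhat, envelopes and distances must share one grid")
    labels = np.full(len(lhat), "random", dtype=object)
    labels[lhat < low] = "regular"
    labels[lhat > high] = "clustered"

    best: Optional[Tuple[int, int]] = None
    start = None
    for i, lab in enumerate(list(labels) + ["random"]):  # sentinel flush
        if lab == "regular" and start is None:
            start = i
        elif lab != "regular" and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i - 1)
            start = None
    regular_range = (
        (float(distances[best[0]]), float(distances[best[1]]))
        if best is not None
        else None
    )
    return labels, regular_range


@dataclass
class KFunctionResult:
    """Full K/L analysis of one pattern: grid, estimates, envelope,
    per-scale labels and the dominant regular range."""

    distances: np.ndarray
    khat: np.ndarray
    lhat: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    labels: np.ndarray
    regular_range: Optional[Tuple[float, float]]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "distances": self.distances.tolist(),
            "khat": self.khat.tolist(),
            "lhat": self.lhat.tolist(),
            "envelope_low": self.envelope_low.tolist(),
            "envelope_high": self.envelope_high.tolist(),
            "labels": self.labels.tolist(),
            "regular_range": list(self.regular_range)
            if self.regular_range
            else None,
            "n_points": self.n_points,
        }


def analyze_pattern(
    pattern: PointPattern,
    distances: Optional[Sequence[float]] = None,
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: RngLike = None,
    correction: Correction = "translation",
) -> KFunctionResult:
    """K, Lhat - d, CSR envelope and classification for one pattern."""
    if distances is None:
        distances = default_distance_grid(pattern.window)
    distances = np.asarray(distances, dtype=float)
    khat = ripley_k(pattern, distances, correction)
    lhat = l_transform(khat, distances)
    low, high = csr_envelope(
        pattern.n, pattern.window, distances, n_sims, alpha, seed, correction
    )
    labels, regular_range = classify_scales(lhat, low, high, distances)
    return KFunctionResult(
        distances=distances,
        khat=khat,
        lhat=lhat,
        envelope_low=low,
        envelope_high=high,
        labels=labels,
        regular_range=regular_range,
        n_points=pattern.n,
    )
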