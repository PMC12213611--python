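"""Exponential depth-distribution (beta) estimation.

The depth profile of a stock is summarized by the one-parameter model

    Y(d) = 1 - beta**d

where Y is the cumulative fraction of the whole-profile stock at or above
depth d (cm, measured at layer bottoms) and beta in (0, 1) controls how
deep the stock is distributed: higher beta = deeper profile. The fit
minimizes the sum of squared residuals of the model over the cumulative
points. A brute-force grid-search oracle is provided alongside the
production optimizer so the two routes can be compared on any profile.

Profiles truncated at a maximum depth D have final cumulative fraction
exactly 1 while the model reaches 1 only asymptotically; the resulting
fit is the SSE-optimal compromise on the profile's own depth support
(no extrapolation below D is attempted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .records import (
    EXCL_TOO_FEW_POINTS,
    EXCL_ZERO_STOCK,
    LayerStock,
    ValidationError,
)

QUANTITIES = ("FRC", "SOC")

DEFAULT_BETA_BOUNDS = (0.5, 0.99999)


class ZeroTotalStockError(ValidationError):
    """Profile total stock is zero; no cumulative fractions exist."""


@dataclass(frozen=True)
class CumulativeProfile:
    """Cumulative stock fractions at layer bottoms for one site/quantity."""

    site_id: str
    quantity: str                       # FRC | SOC
    points: tuple[tuple[float, float], ...]  # (depth cm, cumulative fraction)

    def __post_init__(self) -> None:
        ys = [y for _, y in self.points]
        ds = [d for d, _ in self.points]
        if any(y < -1e-12 or y > 1 + 1e-12 for y in ys):
            raise ValidationError(f"{self.site_id}/{self.quantity}: Y outside [0, 1]")
        if any(ys[i] > ys[i + 1] + 1e-12 for i in range(len(ys) - 1)):
            raise ValidationError(f"{self.site_id}/{self.quantity}: Y not non-decreasing")
        if any(ds[i] >= ds[i + 1] for i in range(len(ds) - 1)):
            raise ValidationError(f"{self.site_id}/{self.quantity}: depths not increasing")

    @property
    def depths(self) -> np.ndarray:
        return np.array([d for d, _ in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([y for _, y in self.points])


@dataclass(frozen=True)
class BetaEstimate:
    site_id: str
    quantity: str
    beta: float        # NaN when excluded
    sse: float
    n_points: int
    excluded: bool = False
    reason: str | None = None


def cumulative_profile(layers: list[LayerStock], quantity: str) -> CumulativeProfile:
    """Cumulative fraction of the whole-profile stock at every layer bottom.

    Layers are taken in depth order; the final point is (deepest bottom, 1)
    by construction. Raises ZeroTotalStockError when the profile holds no
    stock of the requested quantity.
    """
    if quantity not in QUANTITIES:
        raise ValidationError(f"unknown quantity {quantity!r}")
    if not layers:
        raise ZeroTotalStockError("empty layer list")
    ordered = sorted(layers, key=lambda l: l.top)
    vals = [l.frc if quantity == "FRC" else l.soc for l in ordered]
    total = sum(vals)
    if total <= 0:
        raise ZeroTotalStockError(
            f"{ordered[0].site_id}/{quantity}: total stock is zero")
    pts = []
    run = 0.0
    for l, v in zip(ordered, vals):
        run += v
        pts.append((l.bottom, run / total))
    return CumulativeProfile(site_id=ordered[0].site_id, quantity=quantity,
                             points=tuple(pts))


def solve_beta_point(y: float, d: float) -> float:
    """Closed-form per-layer solution beta = (1 - Y)^(1/d).

    Returns NaN for the degenerate fractions Y in {0, 1} where the model
    cannot be inverted.
    """
    if d <= 0:
        raise ValidationError(f"depth must be > 0, got {d}")
    if not 0 <= y <= 1:
        raise ValidationError(f"cumulative fraction must be in [0, 1], got {y}")
    if y == 0.0 or y == 1.0:
        return math.nan
    return (1.0 - y) ** (1.0 / d)


def _sse(beta: float, d: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((y - (1.0 - beta ** d)) ** 2))


def grid_search_beta(profile: CumulativeProfile, step: float = 1e-4,
                     bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS,
                     ) -> tuple[float, float]:
    """Exhaustive grid-search oracle: (argmin beta, SSE) at resolution `step`."""
    d, y = profile.depths, profile.fractions
    grid = np.arange(bounds[0], bounds[1] + step / 2, step)
    sses = np.sum((y[None, :] - (1.0 - grid[:, None] ** d[None, :])) ** 2, axis=1)
    i = int(np.argmin(sses))
    return float(grid[i]), float(sses[i])


def fit_beta(profile: CumulativeProfile, min_points: int = 3,
             bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS) -> BetaEstimate:
    """Fit beta by bounded scalar minimization of the cumulative-point SSE.

    Profiles with fewer than `min_points` cumulative points are excluded
    (reason "too_few_measurements") rather than fit. The optimizer starts
    from the median of the per-point closed-form solutions and is safeguarded
    by a coarse scan so a poor start cannot trap it in a shoulder of the
    SSE surface; the two candidates are reconciled by SSE.
    """
    d, y = profile.depths, profile.fractions
    n = len(d)
    if n < min_points:
        return BetaEstimate(profile.site_id, profile.quantity, math.nan, math.nan,
                            n, excluded=True, reason=EXCL_TOO_FEW_POINTS)

    lo, hi = bounds
    # start: median of invertible per-point solutions, clipped into bounds
    pt = [solve_beta_point(yi, di) for di, yi in zip(d, y)]
    pt = [b for b in pt if not math.isnan(b)]
    start = float(np.clip(np.median(pt), lo, hi)) if pt else 0.5 * (lo + hi)

    # local polish in a window around the start
    w = 0.05
    res_local = minimize_scalar(
        _sse, args=(d, y), method="bounded",
        bounds=(max(lo, start - w), min(hi, start + w)),
        options={"xatol": 1e-10})

    # safeguard: coarse scan of the full interval, refined in the bracketing cell
    grid = np.linspace(lo, hi, 512)
    sses = np.sum((y[None, :] - (1.0 - grid[:, None] ** d[None, :])) ** 2, axis=1)
    i = int(np.argmin(sses))
    cell = (grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)])
    res_global = minimize_scalar(_sse, args=(d, y), method="bounded",
                                 bounds=cell, options={"xatol": 1e-10})

    best = min((res_local, res_global), key=lambda r: r.fun)
    if not best.success:
        raise RuntimeError(
            f"beta optimizer failed for {profile.site_id}/{profile.quantity}: "
            f"last iterate beta={best.x:.8f}, sse={best.fun:.3e}")
    return BetaEstimate(profile.site_id, profile.quantity,
                        float(best.x), float(best.fun), n)


def beta_table(site_layers: dict[str, list[LayerStock]],
               min_points: int = 3,
               bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS,
               ) -> list[BetaEstimate]:
    """One BetaEstimate per site x quantity; exclusions are explicit rows."""
    out = []
    for site_id in site_layers:
        for q in QUANTITIES:
            try:
                prof = cumulative_profile(site_layers[site_id], q)
            except ZeroTotalStockError:
                out.append(BetaEstimate(site_id, q, math.nan, math.nan, 0,
                                        excluded=True, reason=EXCL_ZERO_STOCK))
                continue
            out.append(fit_beta(prof, min_points=min_points, bounds=bounds))
    return out
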