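"""Carbon/proton error trade-off: 2-D sweeps, contours, reciprocal fits.

When carbon and proton shifts are used together, identification degrades
along both error axes. Sweeping Top-1 identification over a (sigma_C,
sigma_H) grid yields a surface; the iso-identification contour at a given
level (e.g. 90%) collects, for every proton-error column, the largest
carbon error still meeting the level. Such contours are well described by a
reciprocal law

    sigma_C = a / (sigma_H - b) + c

fitted by nonlinear least squares. Each contour has a trade-off optimum:
the point minimizing the normalized cumulative error
sigma_C / norm_C + sigma_H / norm_H, where the norms default to the sweep
grid maxima (50 ppm carbon, 10 ppm proton). On the reciprocal curve the
optimum has the closed form

    sigma_H* = b + sqrt(a * norm_H / norm_C)
    sigma_C* = c + sqrt(a * norm_C / norm_H)

clipped to the observed contour span when points are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .identification import SweepResult, _interpolate_threshold, sweep
from .library import ShiftLibrary

__all__ = [
    "SweepSurface",
    "ContourFit",
    "TradeoffOptimum",
    "grid_sweep",
    "extract_contour",
    "reciprocal",
    "fit_reciprocal",
    "optimum_point",
    "optimum_from_points",
]


@dataclass(frozen=True)
class SweepSurface:
    """Mean Top-1 percentage over a (sigma_C, sigma_H) grid (CH mode).

    ``top1_pct``/``top1_sd`` have shape (len(sigma_C_grid), len(sigma_H_grid)).
    """

    sigma_C_grid: tuple[float, ...]
    sigma_H_grid: tuple[float, ...]
    top1_pct: np.ndarray
    top1_sd: np.ndarray
    replicates: int


def grid_sweep(
    lib: ShiftLibrary,
    sigma_C_grid: Sequence[float],
    sigma_H_grid: Sequence[float],
    replicates: int,
    master_seed: int = 0,
    mu: float = 0.0,
) -> SweepSurface:
    """Top-1 identification surface in CH mode over the outer sigma grid."""
    sc = tuple(float(s) for s in sigma_C_grid)
    sh = tuple(float(s) for s in sigma_H_grid)
    if not sc or not sh:
        raise ValueError("both sigma grids must be non-empty")
    pairs = [(c, h) for c in sc for h in sh]
    result: SweepResult = sweep(
        lib, pairs, replicates, "CH", master_seed=master_seed, mu=mu, k_values=(1,)
    )
    pct = result.topk_pct[:, 0].reshape(len(sc), len(sh))
    sd = result.topk_sd[:, 0].reshape(len(sc), len(sh))
    return SweepSurface(
        sigma_C_grid=sc,
        sigma_H_grid=sh,
        top1_pct=pct,
        top1_sd=sd,
        replicates=replicates,
    )


def extract_contour(surface: SweepSurface, level: float) -> np.ndarray:
    """Iso-identification contour points at ``level`` percent.

    For each sigma_H column, linearly interpolate the Top-1 curve along
    sigma_C and record the largest sigma_C still meeting the level. Columns
    never reaching the level are omitted, and so are censored columns whose
    curve stays at/above the level across the whole sigma_C grid (their true
    crossing lies beyond the grid; emitting the grid maximum would bias a
    subsequent contour fit low). An empty result means the level is nowhere
    bracketed by the surface.
    """
    sc = np.asarray(surface.sigma_C_grid)
    points: list[tuple[float, float]] = []
    for j, sigma_h in enumerate(surface.sigma_H_grid):
        column = surface.top1_pct[:, j]
        res = _interpolate_threshold(sc, column, level)
        if res.status == "ok" and res.sigma is not None:
            points.append((float(sigma_h), float(res.sigma)))
    return np.asarray(points).reshape(-1, 2)


def reciprocal(sigma_H: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """The contour model sigma_C = a / (sigma_H - b) + c."""
    return a / (np.asarray(sigma_H, dtype=float) - b) + c


@dataclass(frozen=True)
class ContourFit:
    """Fitted reciprocal contour at one identification level."""

    level: float
    points: np.ndarray  # (sigma_H, sigma_C) pairs
    a: float
    b: float
    c: float
    fit_residual: float  # RMS of residuals in sigma_C (ppm)

    def predict(self, sigma_H: np.ndarray | float) -> np.ndarray:
        return reciprocal(np.asarray(sigma_H, dtype=float), self.a, self.b, self.c)


def fit_reciprocal(points: np.ndarray, level: float = float("nan")) -> ContourFit:
    """Nonlinear least-squares fit of the reciprocal law to contour points.

    ``points`` are (sigma_H, sigma_C) pairs, at least 4, with distinct
    sigma_H. Starting values keep the sigma_H = b singularity to the left of
    the data: b = 0.9 * min(sigma_H), c = 0.9 * min(sigma_C), a from the
    first point.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 4:
        raise ValueError("reciprocal fit needs at least 4 contour points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size != x.size:
        raise ValueError("contour sigma_H values must be distinct")
    b0 = 0.9 * float(np.min(x))
    c0 = 0.9 * float(np.min(y))
    a0 = (float(y[0]) - c0) * (float(x[0]) - b0)
    if a0 <= 0:
        a0 = 1.0
    try:
        params, _ = curve_fit(reciprocal, x, y, p0=(a0, b0, c0), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"reciprocal contour fit did not converge: {exc}") from exc
    a, b, c = (float(v) for v in params)
    residual = float(np.sqrt(np.mean((reciprocal(x, a, b, c) - y) ** 2)))
    return ContourFit(level=level, points=pts, a=a, b=b, c=c, fit_residual=residual)


@dataclass(frozen=True)
class TradeoffOptimum:
    """The point on a contour minimizing the normalized cumulative error."""

    sigma_C_star: float
    sigma_H_star: float
    normalized_cost: float
    clipped: bool = False


def optimum_point(
    fit: ContourFit, norm_C: float = 50.0, norm_H: float = 10.0
) -> TradeoffOptimum:
    """Minimize sigma_C/norm_C + sigma_H/norm_H on the fitted contour.

    Closed form on the reciprocal curve; the result is clipped to the span
    of the observed contour points (recomputing the conjugate coordinate
    from the curve) when it falls outside.
    """
    if norm_C <= 0 or norm_H <= 0:
        raise ValueError("normalization constants must be positive")
    if fit.a <= 0:
        raise ValueError("optimum is undefined for a non-decreasing contour (a <= 0)")
    sigma_h = fit.b + math.sqrt(fit.a * norm_H / norm_C)
    sigma_c = fit.c + math.sqrt(fit.a * norm_C / norm_H)
    clipped = False
    if fit.points.size:
        h_lo, h_hi = float(np.min(fit.points[:, 0])), float(np.max(fit.points[:, 0]))
        if sigma_h < h_lo or sigma_h > h_hi:
            sigma_h = min(max(sigma_h, h_lo), h_hi)
            sigma_c = float(fit.predict(sigma_h))
            clipped = True
    cost = sigma_c / norm_C + sigma_h / norm_H
    return TradeoffOptimum(
        sigma_C_star=float(sigma_c),
        sigma_H_star=float(sigma_h),
        normalized_cost=float(cost),
        clipped=clipped,
    )


def optimum_from_points(
    points: np.ndarray, norm_C: float = 50.0, norm_H: float = 10.0
) -> TradeoffOptimum:
    """Grid-search optimum: the raw contour point with minimal normalized cost.

    Fit-free alternative to :func:`optimum_point` for sparse or noisy
    contours where the reciprocal fit is underdetermined.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("no contour points to search")
    if norm_C <= 0 or norm_H <= 0:
        raise ValueError("normalization constants must be positive")
    costs = pts[:, 1] / norm_C + pts[:, 0] / norm_H
    i = int(np.argmin(costs))
    return TradeoffOptimum(
        sigma_C_star=float(pts[i, 1]),
        sigma_H_star=float(pts[i, 0]),
        normalized_cost=float(costs[i]),
        clipped=False,
    )
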