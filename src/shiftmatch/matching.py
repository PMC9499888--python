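"""Core scoring machinery for shift-list matching.

A query ("experimental") list of M shifts is matched one-to-one onto a
candidate ("computed") list of N shifts, M <= N, by minimizing the summed
squared differences over all one-to-one assignments — the classic linear
assignment problem, solved here by the Hungarian/Munkres algorithm (the
scipy implementation). Agreement over the assigned pairs is then quantified
by the usual chemical-shift error statistics:

    MAE  = sum |d_exp - d_calc| / N
    RMSE = sqrt( sum (d_exp - d_calc)^2 / N )
    CMAE = sum |d_exp - (d_calc - b)/m| / N

where (m, b) are the slope and intercept of an ordinary least-squares fit of
the calculated shifts against the experimental ones; CMAE is the MAE after
removing that fitted systematic distortion. When carbon and proton are used
together, each nucleus gets its own RMSE and the two are combined by
geometric mean so the larger carbon scale does not dominate.

The convention throughout: cost-matrix rows are query shifts, columns are
candidate shifts, and the identification score is the RMSE over the
min(M, N) assigned pairs only — unassigned candidate shifts contribute
nothing (mixture scoring relies on this).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

__all__ = [
    "Assignment",
    "ScalingFit",
    "MatchScore",
    "cost_matrix",
    "munkres_assign",
    "brute_force_assign",
    "assignment_rmse",
    "mae",
    "rmse",
    "fit_scaling",
    "cmae",
    "combined_score",
    "match_score",
]


@dataclass(frozen=True)
class Assignment:
    """A one-to-one assignment of row indices to column indices.

    ``pairs`` holds ``(row, col)`` index pairs, one per row of the cost
    matrix (rows are the smaller side); ``total_cost`` is the summed cost
    over those pairs, which is the global minimum for the instance.
    """

    pairs: tuple[tuple[int, int], ...]
    total_cost: float


@dataclass(frozen=True)
class ScalingFit:
    """Slope/intercept of calculated shifts regressed on experimental ones."""

    m: float
    b: float


@dataclass(frozen=True)
class MatchScore:
    """Per-nucleus RMSEs and their geometric-mean combination (ppm)."""

    rmse_C: float | None
    rmse_H: float | None
    combined: float


def _as_1d(shifts: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(shifts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence of shifts")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite shifts")
    return arr


def cost_matrix(query_shifts: Sequence[float], candidate_shifts: Sequence[float]) -> np.ndarray:
    """Squared-difference matrix with rows = query shifts, columns = candidate shifts."""
    q = _as_1d(query_shifts, "query_shifts")
    c = _as_1d(candidate_shifts, "candidate_shifts")
    return (q[:, None] - c[None, :]) ** 2


def munkres_assign(cost: np.ndarray) -> Assignment:
    """Minimum-total-cost one-to-one assignment of rows into columns.

    Requires M <= N (rows into columns); callers with a larger query side
    must transpose first and keep track of the orientation.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost must be a non-empty 2-D matrix")
    m, n = cost.shape
    if m > n:
        raise ValueError(f"cost matrix has more rows ({m}) than columns ({n}); swap the inputs")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())
    return Assignment(pairs=tuple(zip(rows.tolist(), cols.tolist())), total_cost=total)


_BRUTE_FORCE_MAX = 8


def brute_force_assign(cost: np.ndarray) -> Assignment:
    """Exact minimum assignment by exhaustive enumeration (test oracle).

    Limited to instances with at most 8 columns; enumerates every ordered
    selection of M columns for the M rows.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost must be a non-empty 2-D matrix")
    m, n = cost.shape
    if m > n:
        raise ValueError("cost matrix has more rows than columns; swap the inputs")
    if n > _BRUTE_FORCE_MAX:
        raise ValueError(f"instance too large for brute force (N={n} > {_BRUTE_FORCE_MAX})")
    best_cost = math.inf
    best_perm: tuple[int, ...] | None = None
    rows = np.arange(m)
    for perm in itertools.permutations(range(n), m):
        total = float(cost[rows, list(perm)].sum())
        if total < best_cost:
            best_cost = total
            best_perm = perm
    assert best_perm is not None
    return Assignment(pairs=tuple(zip(range(m), best_perm)), total_cost=best_cost)


def assignment_rmse(query_shifts: Sequence[float], candidate_shifts: Sequence[float]) -> float:
    """RMSE over the optimally assigned pairs of two shift lists.

    The smaller list is assigned into the larger one; the RMSE is computed
    over the min(M, N) assigned pairs only.
    """
    q = _as_1d(query_shifts, "query_shifts")
    c = _as_1d(candidate_shifts, "candidate_shifts")
    if len(q) <= len(c):
        assignment = munkres_assign(cost_matrix(q, c))
    else:
        assignment = munkres_assign(cost_matrix(c, q))
    n_pairs = min(len(q), len(c))
    return math.sqrt(assignment.total_cost / n_pairs)


def _pairs_to_arrays(pairs: Iterable[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(list(pairs), dtype=float)
    if data.size == 0:
        raise ValueError("at least one (exp, calc) pair is required")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be (exp, calc) 2-tuples")
    return data[:, 0], data[:, 1]


def mae(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean absolute error over assigned (experimental, calculated) pairs."""
    exp, calc = _pairs_to_arrays(pairs)
    return float(np.mean(np.abs(exp - calc)))


def rmse(pairs: Iterable[tuple[float, float]]) -> float:
    """Root-mean-square error over assigned (experimental, calculated) pairs."""
    exp, calc = _pairs_to_arrays(pairs)
    return float(np.sqrt(np.mean((exp - calc) ** 2)))


def fit_scaling(exp_shifts: Sequence[float], calc_shifts: Sequence[float]) -> ScalingFit:
    """OLS slope/intercept of calculated shifts with respect to experimental ones."""
    exp = _as_1d(exp_shifts, "exp_shifts")
    calc = _as_1d(calc_shifts, "calc_shifts")
    if exp.shape != calc.shape:
        raise ValueError("experimental and calculated shift lists differ in length")
    if np.unique(exp).size < 2:
        raise ValueError("scaling fit needs at least two distinct experimental shifts")
    result = linregress(exp, calc)
    return ScalingFit(m=float(result.slope), b=float(result.intercept))


def cmae(exp_shifts: Sequence[float], calc_shifts: Sequence[float], fit: ScalingFit) -> float:
    """MAE after removing the fitted affine distortion from the calculated shifts."""
    if fit.m == 0 or not math.isfinite(fit.m):
        raise ValueError("scaling fit slope must be finite and nonzero")
    exp = _as_1d(exp_shifts, "exp_shifts")
    calc = _as_1d(calc_shifts, "calc_shifts")
    if exp.shape != calc.shape:
        raise ValueError("experimental and calculated shift lists differ in length")
    corrected = (calc - fit.b) / fit.m
    return float(np.mean(np.abs(exp - corrected)))


def combined_score(rmse_C: float | None, rmse_H: float | None) -> float:
    """Geometric mean of the defined per-nucleus RMSEs.

    With both nuclei defined this is sqrt(rmse_C * rmse_H); with only one
    defined it is that component. A zero RMSE on either nucleus yields a
    combined score of zero, as the formula dictates.
    """
    if rmse_C is None and rmse_H is None:
        raise ValueError("at least one per-nucleus RMSE must be defined")
    if rmse_C is None:
        return float(rmse_H)  # type: ignore[arg-type]
    if rmse_H is None:
        return float(rmse_C)
    if rmse_C < 0 or rmse_H < 0:
        raise ValueError("RMSE components must be non-negative")
    return math.sqrt(rmse_C * rmse_H)


def match_score(
    query_carbon: Sequence[float] | None,
    query_proton: Sequence[float] | None,
    candidate_carbon: Sequence[float] | None,
    candidate_proton: Sequence[float] | None,
    nuclei_mode: str,
) -> MatchScore:
    """Score one candidate against a query in the given nuclei mode.

    ``nuclei_mode`` is ``"C"``, ``"H"`` or ``"CH"``. Per active nucleus the
    shift lists are assigned and an RMSE computed; the combined score is the
    geometric mean over the active, defined channels.
    """
    rC: float | None = None
    rH: float | None = None
    if nuclei_mode in ("C", "CH"):
        if query_carbon is not None and candidate_carbon is not None and len(query_carbon) and len(candidate_carbon):
            rC = assignment_rmse(query_carbon, candidate_carbon)
    if nuclei_mode in ("H", "CH"):
        if query_proton is not None and candidate_proton is not None and len(query_proton) and len(candidate_proton):
            rH = assignment_rmse(query_proton, candidate_proton)
    return MatchScore(rmse_C=rC, rmse_H=rH, combined=combined_score(rC, rH))
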