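"""Mixture identification: rank candidate tuples against a pooled query.

A mixture spectrum is assumed to be the union of its constituents' shift
lists. Candidates are therefore n-tuples of distinct library molecules whose
nucleus counts sum exactly to the query's counts; each tuple is scored by
optimally assigning the pooled query list onto the concatenated candidate
lists (a square assignment, so every shift is matched and each query shift
can belong to only one constituent), taking per-nucleus RMSE and combining
by geometric mean, exactly as in the pure-sample case.

Two regimes mirror the study design:

* known constituent count — only tuples of exactly that size are candidates;
* unknown count — tuples of every size 1..max_n compete in one pooled
  ranking, which is where identification collapses: a single molecule whose
  counts happen to equal the pooled totals can outrank the true pair.

Tuple enumeration never brute-forces the n-fold product: it walks the
library's (nC, nH) count index and probes complements, so only count-
feasible tuples are ever materialized. A configurable budget guards against
combinatorial blow-up on large libraries (failure is loud, never silent
truncation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .identification import _check_mode, _pessimistic_rank, eligible_records
from .library import ShiftLibrary, ShiftRecord
from .matching import MatchScore, match_score
from .synthetic import (
    NoiseModel,
    QuerySpectrum,
    derive_seed,
    make_mixture,
    rng_for,
)

__all__ = [
    "TupleCandidate",
    "MixtureRanking",
    "EnumerationBudgetError",
    "enumerate_tuples",
    "score_tuple",
    "identify_mixture",
    "mixture_experiment",
]

DEFAULT_TUPLE_BUDGET = 5_000_000


class EnumerationBudgetError(RuntimeError):
    """Tuple enumeration exceeded the configured budget."""


@dataclass(frozen=True)
class TupleCandidate:
    """One candidate tuple (unordered, distinct molecules) with its score."""

    ids: tuple[str, ...]  # sorted
    pooled_nC: int
    pooled_nH: int
    score: MatchScore


@dataclass(frozen=True)
class MixtureRanking:
    """Ascending-sorted tuple ranking for one mixture query."""

    ranked: tuple[TupleCandidate, ...]
    rank_of_truth: int | None
    n_mode: str  # "known" or "unknown"
    status: str = "ok"  # "ok" or "unidentifiable"


def _mode_key(rec_counts: tuple[int, int], nuclei_mode: str) -> tuple[int, ...]:
    """Project a (nC, nH) pair onto the active nuclei for count matching."""
    c, h = rec_counts
    if nuclei_mode == "C":
        return (c,)
    if nuclei_mode == "H":
        return (h,)
    return (c, h)


def _count_groups(
    lib: ShiftLibrary, nuclei_mode: str
) -> dict[tuple[int, ...], list[str]]:
    """Active-count -> sorted eligible molecule ids."""
    groups: dict[tuple[int, ...], list[str]] = {}
    for rec in eligible_records(lib, nuclei_mode):
        key = _mode_key((rec.n_carbon, rec.n_hydrogen), nuclei_mode)
        groups.setdefault(key, []).append(rec.molecule_id)
    for ids in groups.values():
        ids.sort()
    return groups


def _sub(total: tuple[int, ...], part: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(t - p for t, p in zip(total, part))


def _nonneg(key: tuple[int, ...]) -> bool:
    return all(v >= 0 for v in key)


def _pairs_from_groups(
    groups: Mapping[tuple[int, ...], list[str]],
    total: tuple[int, ...],
    min_id: str | None = None,
) -> Iterator[tuple[str, str]]:
    """All id pairs (a < b), both > min_id, whose count keys sum to total."""
    keys = sorted(groups)
    for k1 in keys:
        k2 = _sub(total, k1)
        if not _nonneg(k2) or k2 < k1:
            continue  # each unordered key pair visited once
        if k2 not in groups:
            continue
        ids1 = groups[k1]
        if min_id is not None:
            ids1 = [i for i in ids1 if i > min_id]
        if k1 == k2:
            for i, a in enumerate(ids1):
                for b in groups[k1]:
                    if b > a:
                        yield (a, b)
        else:
            ids2 = groups[k2]
            if min_id is not None:
                ids2 = [i for i in ids2 if i > min_id]
            for a in ids1:
                for b in ids2:
                    yield (a, b) if a < b else (b, a)


def _tuples_of_size(
    groups: Mapping[tuple[int, ...], list[str]],
    total: tuple[int, ...],
    n: int,
) -> Iterator[tuple[str, ...]]:
    if n == 1:
        for mid in groups.get(total, []):
            yield (mid,)
    elif n == 2:
        seen: set[tuple[str, str]] = set()
        for pair in _pairs_from_groups(groups, total):
            if pair not in seen:  # unequal-key branch can emit each pair once only
                seen.add(pair)
                yield pair
    elif n == 3:
        for key1 in sorted(groups):
            remaining = _sub(total, key1)
            if not _nonneg(remaining):
                continue
            for first in groups[key1]:
                for a, b in _pairs_from_groups(groups, remaining, min_id=first):
                    yield (first, a, b)
    else:
        raise ValueError(f"tuple size {n} not supported (max 3)")


def enumerate_tuples(
    lib: ShiftLibrary,
    total_nC: int,
    total_nH: int,
    n: int | str,
    max_n: int = 3,
    nuclei_mode: str = "CH",
    budget: int = DEFAULT_TUPLE_BUDGET,
) -> Iterator[tuple[str, ...]]:
    """Stream candidate id-tuples whose active counts sum to the query's.

    ``n`` is the tuple size when the constituent count is known, or
    ``"unknown"``, which enumerates all sizes 1..max_n. Tuples are unordered
    combinations of distinct molecules, emitted as sorted id tuples. Raises
    :class:`EnumerationBudgetError` beyond ``budget`` tuples.
    """
    _check_mode(nuclei_mode)
    if isinstance(n, int):
        if n < 1:
            raise ValueError("tuple size must be >= 1")
        if n > max_n:
            raise ValueError(f"tuple size {n} exceeds max_n={max_n}")
        sizes: tuple[int, ...] = (n,)
    elif n == "unknown":
        sizes = tuple(range(1, max_n + 1))
    else:
        raise ValueError(f"n must be an integer or 'unknown', got {n!r}")
    total = _mode_key((total_nC, total_nH), nuclei_mode)
    groups = _count_groups(lib, nuclei_mode)
    emitted = 0
    for size in sizes:
        for ids in _tuples_of_size(groups, total, size):
            emitted += 1
            if emitted > budget:
                raise EnumerationBudgetError(
                    f"tuple enumeration exceeded budget of {budget}; "
                    "reduce the library size or max_n"
                )
            yield ids


def score_tuple(
    query: QuerySpectrum,
    tuple_ids: Sequence[str],
    lib: ShiftLibrary,
    nuclei_mode: str = "CH",
) -> MatchScore:
    """Score a candidate tuple by assigning the pooled query onto its pooled shifts.

    The pooled candidate counts must equal the query's active counts (the
    enumeration guarantees this); the per-nucleus assignment is then square,
    so every query shift is matched to exactly one candidate nucleus.
    """
    _check_mode(nuclei_mode)
    records: list[ShiftRecord] = [lib[mid] for mid in sorted(tuple_ids)]
    pooled_c: list[float] = []
    pooled_h: list[float] = []
    for rec in records:
        pooled_c.extend(rec.carbon_shifts)
        pooled_h.extend(rec.proton_shifts)
    if nuclei_mode in ("C", "CH") and len(pooled_c) != query.n_carbon:
        raise ValueError(
            f"pooled carbon count {len(pooled_c)} != query carbon count {query.n_carbon}"
        )
    if nuclei_mode in ("H", "CH") and len(pooled_h) != query.n_hydrogen:
        raise ValueError(
            f"pooled proton count {len(pooled_h)} != query proton count {query.n_hydrogen}"
        )
    qc = query.carbon_shifts if nuclei_mode in ("C", "CH") else None
    qh = query.proton_shifts if nuclei_mode in ("H", "CH") else None
    return match_score(qc, qh, pooled_c, pooled_h, nuclei_mode)


def identify_mixture(
    lib: ShiftLibrary,
    query: QuerySpectrum,
    n_mode: str = "known",
    max_n: int = 3,
    nuclei_mode: str = "CH",
    budget: int = DEFAULT_TUPLE_BUDGET,
) -> MixtureRanking:
    """Enumerate, score and rank candidate tuples for a mixture query.

    With ``n_mode="known"`` the constituent count is taken from
    ``query.n_constituents``; with ``"unknown"`` all tuple sizes 1..max_n
    compete in a single pooled ranking. The true tuple's rank uses set
    equality and the pessimistic tie policy.
    """
    if n_mode not in ("known", "unknown"):
        raise ValueError(f"n_mode must be 'known' or 'unknown', got {n_mode!r}")
    if n_mode == "known":
        if not isinstance(query.n_constituents, int):
            raise ValueError("known-n identification requires query.n_constituents")
        n: int | str = query.n_constituents
    else:
        n = "unknown"
    scored: list[TupleCandidate] = []
    for ids in enumerate_tuples(
        lib, query.n_carbon, query.n_hydrogen, n, max_n=max_n,
        nuclei_mode=nuclei_mode, budget=budget,
    ):
        score = score_tuple(query, ids, lib, nuclei_mode)
        recs = [lib[mid] for mid in ids]
        scored.append(
            TupleCandidate(
                ids=tuple(sorted(ids)),
                pooled_nC=sum(r.n_carbon for r in recs),
                pooled_nH=sum(r.n_hydrogen for r in recs),
                score=score,
            )
        )
    if not scored:
        return MixtureRanking(ranked=(), rank_of_truth=None, n_mode=n_mode, status="unidentifiable")
    scored.sort(key=lambda t: (t.score.combined, t.ids))
    rank: int | None = None
    truth = frozenset(query.true_ids)
    if truth:
        combined = [t.score.combined for t in scored]
        truth_index = next(
            (i for i, t in enumerate(scored) if frozenset(t.ids) == truth), None
        )
        if truth_index is not None:
            rank = _pessimistic_rank(combined, truth_index)
    return MixtureRanking(
        ranked=tuple(scored), rank_of_truth=rank, n_mode=n_mode, status="ok"
    )


def mixture_experiment(
    lib: ShiftLibrary,
    n: int,
    noise_points: Sequence[tuple[float, float]],
    replicates: int,
    n_mode: str = "known",
    mixtures_per_replicate: int = 200,
    nuclei_mode: str = "CH",
    max_n: int = 3,
    master_seed: int = 0,
    mu: float = 0.0,
    budget: int = DEFAULT_TUPLE_BUDGET,
) -> pd.DataFrame:
    """Monte-Carlo mixture study: mean Top-1 percentage and mean rank per noise point.

    Each replicate draws ``mixtures_per_replicate`` random n-compound
    mixtures (distinct molecules, sampled without replacement per mixture)
    from the eligible records, perturbs the pooled spectra, and identifies
    them. Returns a tidy frame with one row per noise point.
    """
    if n < 1 or n > max_n:
        raise ValueError(f"mixture size n={n} must be in [1, max_n={max_n}]")
    records = eligible_records(lib, nuclei_mode)
    if len(records) < n:
        raise ValueError("library has fewer eligible molecules than the mixture size")
    rows = []
    for pi, (sigma_c, sigma_h) in enumerate(noise_points):
        noise = NoiseModel(sigma_C=float(sigma_c), sigma_H=float(sigma_h), mu=mu)
        top1_fracs = np.empty(replicates)
        mean_ranks = np.empty(replicates)
        for r in range(replicates):
            rng = rng_for(derive_seed(master_seed, pi, r))
            top1 = 0
            ranks: list[float] = []
            for _ in range(mixtures_per_replicate):
                picks = rng.choice(len(records), size=n, replace=False)
                constituents = [records[int(i)] for i in picks]
                query = make_mixture(constituents, noise, rng=rng, max_constituents=max_n)
                ranking = identify_mixture(
                    lib, query, n_mode=n_mode, max_n=max_n,
                    nuclei_mode=nuclei_mode, budget=budget,
                )
                rank = ranking.rank_of_truth
                assert rank is not None  # closed world: the true tuple is enumerable
                ranks.append(rank)
                if rank == 1:
                    top1 += 1
            top1_fracs[r] = top1 / mixtures_per_replicate
            mean_ranks[r] = float(np.mean(ranks))
        rows.append(
            {
                "n": n,
                "n_mode": n_mode,
                "sigma_C": float(sigma_c),
                "sigma_H": float(sigma_h),
                "mean_top1_pct": float(top1_fracs.mean() * 100.0),
                "sd_top1_pct": float(top1_fracs.std(ddof=1) * 100.0) if replicates > 1 else 0.0,
                "mean_rank": float(mean_ranks.mean()),
                "replicates": replicates,
                "mixtures_per_replicate": mixtures_per_replicate,
            }
        )
    return pd.DataFrame(rows)
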