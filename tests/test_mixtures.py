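"""Mixture identification: tuple enumeration, pooled scoring, known vs unknown n."""

import itertools
import math

import numpy as np
import pytest

from shiftmatch import (
    NoiseModel,
    QuerySpectrum,
    ShiftLibrary,
    ShiftRecord,
    enumerate_tuples,
    identify_mixture,
    make_mixture,
    mixture_experiment,
    score_tuple,
)
from shiftmatch.identification import filter_candidates, score_and_rank
from shiftmatch.mixtures import EnumerationBudgetError
from shiftmatch.synthetic import LibrarySpec, generate_library, rng_for


@pytest.fixture
def counts_toy():
    """Counts {m1:(3,2), m2:(1,4), m3:(4,6), m4:(2,3)} from the tuple-algebra example."""
    return ShiftLibrary(
        [
            ShiftRecord("m1", (1.0, 2.0, 3.0), (0.1, 0.2)),
            ShiftRecord("m2", (4.0,), (0.3, 0.4, 0.5, 0.6)),
            ShiftRecord("m3", (5.0, 6.0, 7.0, 8.0), (0.7, 0.8, 0.9, 1.0, 1.1, 1.2)),
            ShiftRecord("m4", (9.0, 10.0), (1.3, 1.4, 1.5)),
        ]
    )


# ---------------------------------------------------------------------------
# enumeration


def test_pair_enumeration_by_count_sums(counts_toy):
    pairs = set(enumerate_tuples(counts_toy, 4, 6, n=2))
    assert pairs == {("m1", "m2")}  # 3+1=4 C, 2+4=6 H; m3 alone matches but is no pair


def test_unknown_n_includes_all_sizes(counts_toy):
    tuples = set(enumerate_tuples(counts_toy, 4, 6, n="unknown", max_n=2))
    assert tuples == {("m3",), ("m1", "m2")}


def test_single_tuple_enumeration_equals_case1_filter(counts_toy):
    singles = {t[0] for t in enumerate_tuples(counts_toy, 4, 6, n=1)}
    assert singles == filter_candidates(counts_toy, 4, 6, "CH")


def test_infeasible_totals_give_empty_stream(counts_toy):
    assert list(enumerate_tuples(counts_toy, 100, 100, n=2)) == []


def test_enumeration_budget_is_enforced(small_library):
    rec = small_library.records[0]
    with pytest.raises(EnumerationBudgetError):
        # budget of 0 trips on the first tuple
        list(
            enumerate_tuples(
                small_library, rec.n_carbon, rec.n_hydrogen, n=1, budget=0
            )
        )


@pytest.mark.parametrize("n", [1, 2, 3])
def test_enumeration_complete_against_brute_force(n):
    """Complement-lookup enumeration agrees with brute force over all n-subsets."""
    lib = generate_library(LibrarySpec(n_molecules=25, seed=31))
    rng = rng_for(17)
    ids = [r.molecule_id for r in lib.records]
    for _ in range(5):
        picks = rng.choice(len(ids), size=n, replace=False)
        members = [lib.records[int(i)] for i in picks]
        tot_c = sum(r.n_carbon for r in members)
        tot_h = sum(r.n_hydrogen for r in members)
        fast = set(enumerate_tuples(lib, tot_c, tot_h, n=n))
        brute = {
            tuple(sorted(combo))
            for combo in itertools.combinations(ids, n)
            if sum(lib[m].n_carbon for m in combo) == tot_c
            and sum(lib[m].n_hydrogen for m in combo) == tot_h
        }
        assert fast == brute
        assert tuple(sorted(r.molecule_id for r in members)) in fast


# ---------------------------------------------------------------------------
# tuple scoring


def test_true_pair_scores_zero_at_zero_noise(counts_toy):
    q = make_mixture([counts_toy["m1"], counts_toy["m2"]], NoiseModel(0.0, 0.0))
    assert score_tuple(q, ("m1", "m2"), counts_toy).combined == 0.0


def test_pooled_rmse_hand_example():
    lib = ShiftLibrary([ShiftRecord("A", (10.0,), (1.0,)), ShiftRecord("B", (20.0,), (2.0,))])
    q = QuerySpectrum((10.0, 21.0), (1.0, 2.0), true_ids=("A", "B"), n_constituents=2)
    score = score_tuple(q, ("A", "B"), lib)
    assert score.rmse_C == pytest.approx(math.sqrt(0.5), abs=1e-12)
    assert score.rmse_H == 0.0


def test_score_invariant_to_member_order(counts_toy):
    q = make_mixture([counts_toy["m1"], counts_toy["m2"]], NoiseModel(0.5, 0.05, seed=2))
    assert score_tuple(q, ("m1", "m2"), counts_toy) == score_tuple(q, ("m2", "m1"), counts_toy)


def test_count_mismatch_is_hard_error(counts_toy):
    q = QuerySpectrum((1.0, 2.0), (0.1,), true_ids=("m1",), n_constituents=1)
    with pytest.raises(ValueError, match="count"):
        score_tuple(q, ("m1", "m2"), counts_toy)


# ---------------------------------------------------------------------------
# identification


def test_true_pair_ranks_first_at_zero_noise(small_library, rng):
    recs = small_library.records
    for _ in range(10):
        i, j = rng.choice(len(recs), size=2, replace=False)
        q = make_mixture([recs[int(i)], recs[int(j)]], NoiseModel(0.0, 0.0))
        result = identify_mixture(small_library, q, n_mode="known")
        assert result.rank_of_truth == 1


def test_exhaustive_pairs_zero_noise_top1():
    """100 random pairs from a 20-molecule library all identified at sigma=0."""
    lib = generate_library(LibrarySpec(n_molecules=20, seed=41))
    rng = rng_for(42)
    for _ in range(100):
        i, j = rng.choice(20, size=2, replace=False)
        q = make_mixture([lib.records[int(i)], lib.records[int(j)]], NoiseModel(0.0, 0.0))
        assert identify_mixture(lib, q, n_mode="known").rank_of_truth == 1


def test_unknown_n_collapse_on_adversarial_decoy():
    """A count-sum decoy singleton can outrank the true pair when n is unknown."""
    lib = ShiftLibrary(
        [
            ShiftRecord("A", (10.0,), (1.0,)),
            ShiftRecord("B", (20.0,), (2.0,)),
            # decoy: counts equal the pair's pooled counts, shifts nearer the query
            ShiftRecord("S", (10.2, 19.8), (1.02, 1.98)),
            ShiftRecord("C", (150.0,), (9.0,)),
        ]
    )
    q = QuerySpectrum(
        (10.15, 19.85), (1.015, 1.985), true_ids=("A", "B"), n_constituents=2
    )
    known = identify_mixture(lib, q, n_mode="known")
    unknown = identify_mixture(lib, q, n_mode="unknown")
    assert known.rank_of_truth == 1
    assert unknown.rank_of_truth > 1
    assert unknown.ranked[0].ids == ("S",)


def test_known_candidates_subset_of_unknown(small_library, rng):
    """Known-n tuples are a subset of unknown-n tuples, so ranks can only worsen."""
    recs = small_library.records
    noise = NoiseModel(2.0, 0.2, seed=8)
    for _ in range(5):
        i, j = rng.choice(len(recs), size=2, replace=False)
        q = make_mixture([recs[int(i)], recs[int(j)]], noise, rng=rng)
        known = identify_mixture(small_library, q, n_mode="known")
        unknown = identify_mixture(small_library, q, n_mode="unknown")
        known_set = {t.ids for t in known.ranked}
        unknown_set = {t.ids for t in unknown.ranked}
        assert known_set <= unknown_set
        assert unknown.rank_of_truth >= known.rank_of_truth


def test_single_constituent_identification_matches_case1(small_library):
    """n=1 mixture identification is bit-identical to the pure-sample pipeline."""
    rec = small_library.records[3]
    q = make_mixture([rec], NoiseModel(1.5, 0.15, seed=23))
    mix = identify_mixture(small_library, q, n_mode="known")
    cands = filter_candidates(small_library, rec.n_carbon, rec.n_hydrogen, "CH")
    pure = score_and_rank(q, cands, small_library, "CH", true_id=rec.molecule_id)
    assert [t.ids for t in mix.ranked] == [(cid,) for cid, _ in pure.ranked]
    assert [t.score for t in mix.ranked] == [s for _, s in pure.ranked]
    assert mix.rank_of_truth == pure.rank_of_truth


def test_no_tuples_is_unidentifiable(counts_toy):
    q = QuerySpectrum((1.0,) * 50, (0.1,) * 50, n_constituents=2)
    result = identify_mixture(counts_toy, q, n_mode="known")
    assert result.status == "unidentifiable"


# ---------------------------------------------------------------------------
# experiment driver


def test_zero_noise_experiment_is_perfect(small_library):
    df = mixture_experiment(
        small_library,
        n=2,
        noise_points=[(0.0, 0.0)],
        replicates=2,
        mixtures_per_replicate=20,
        master_seed=3,
    )
    assert df.loc[0, "mean_top1_pct"] == 100.0
    assert df.loc[0, "mean_rank"] == 1.0


def test_experiment_reproducible(small_library):
    kwargs = dict(
        n=2,
        noise_points=[(3.0, 0.4)],
        replicates=2,
        mixtures_per_replicate=15,
        master_seed=11,
    )
    a = mixture_experiment(small_library, **kwargs)
    b = mixture_experiment(small_library, **kwargs)
    assert a.equals(b)
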