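"""Pure-sample identification: filtering, ranking, replicates, sweeps."""

import math

import numpy as np
import pytest

from shiftmatch import (
    NoiseModel,
    QuerySpectrum,
    ShiftLibrary,
    ShiftRecord,
    filter_candidates,
    run_replicate,
    score_and_rank,
    sweep,
    threshold_sigma,
)
from shiftmatch.identification import (
    SweepResult,
    eligible_records,
    random_guess_top1_baseline,
)
from shiftmatch.synthetic import LibrarySpec, generate_library

# ---------------------------------------------------------------------------
# candidate filtering


@pytest.fixture
def counts_library():
    return ShiftLibrary(
        [
            ShiftRecord("m1", (1.0, 2.0, 3.0), (0.5, 0.6)),
            ShiftRecord("m2", (4.0,), ()),
            ShiftRecord("m3", (7.0, 8.0, 9.0), (1.5, 1.6)),
        ]
    )


def test_filter_exact_counts_both_nuclei(counts_library):
    assert filter_candidates(counts_library, 3, 2, "CH") == {"m1", "m3"}


def test_filter_zero_count_active_nucleus_is_empty(counts_library):
    # proton mode with a 0-proton query: such molecules are excluded by design
    assert filter_candidates(counts_library, 1, 0, "H") == set()


def test_filter_absent_counts(counts_library):
    assert filter_candidates(counts_library, 9, 9, "CH") == set()


def test_filter_single_nucleus_modes(counts_library):
    assert filter_candidates(counts_library, 3, 0, "C") == {"m1", "m3"}
    assert filter_candidates(counts_library, 1, 0, "C") == {"m2"}
    assert filter_candidates(counts_library, 0, 2, "H") == {"m1", "m3"}


def test_eligible_records_by_mode(counts_library):
    assert {r.molecule_id for r in eligible_records(counts_library, "C")} == {
        "m1", "m2", "m3"
    }
    assert {r.molecule_id for r in eligible_records(counts_library, "H")} == {"m1", "m3"}
    assert {r.molecule_id for r in eligible_records(counts_library, "CH")} == {"m1", "m3"}


# ---------------------------------------------------------------------------
# scoring and ranking


def test_rank_by_assignment_rmse_hand_example():
    lib = ShiftLibrary(
        [
            ShiftRecord("m1", (10.0, 20.0), ()),
            ShiftRecord("m2", (11.0, 19.0), ()),
            ShiftRecord("m3", (50.0, 60.0), ()),
        ]
    )
    query = QuerySpectrum((10.4, 19.6), (), true_ids=("m1",))
    result = score_and_rank(query, {"m1", "m2", "m3"}, lib, "C")
    order = [cid for cid, _ in result.ranked]
    assert order == ["m1", "m2", "m3"]
    scores = {cid: s.combined for cid, s in result.ranked}
    assert scores["m1"] == pytest.approx(0.4, abs=1e-12)
    assert scores["m2"] == pytest.approx(0.6, abs=1e-12)
    assert result.rank_of_truth == 1
    assert result.top_k_flags == {1: True, 2: True, 5: True, 10: True}


def test_pessimistic_tie_policy():
    """Candidates tied with the truth at score 0 all count against its rank."""
    dup = (10.0, 20.0)
    lib = ShiftLibrary(
        [
            ShiftRecord("t", dup, ()),
            ShiftRecord("d1", dup, ()),
            ShiftRecord("d2", dup, ()),
            ShiftRecord("far", (100.0, 200.0), ()),
        ]
    )
    query = QuerySpectrum(dup, (), true_ids=("t",))
    result = score_and_rank(query, {"t", "d1", "d2", "far"}, lib, "C")
    assert result.rank_of_truth == 3  # 1 + 0 smaller + 2 tied others
    assert not result.top_k_flags[2]
    assert result.top_k_flags[5]


def test_empty_candidates_is_unidentifiable():
    lib = ShiftLibrary([ShiftRecord("m", (1.0,), ())])
    result = score_and_rank(QuerySpectrum((1.0,), ()), set(), lib, "C")
    assert result.status == "unidentifiable"
    assert result.rank_of_truth is None


def test_zero_noise_exact_match_all_modes(small_library):
    for mode in ("C", "H", "CH"):
        ranks = run_replicate(small_library, NoiseModel(0.0, 0.0), mode, replicate_seed=1)
        assert set(ranks.values()) == {1}


def test_run_replicate_deterministic(small_library):
    noise = NoiseModel(20.0, 2.0)
    a = run_replicate(small_library, noise, "CH", replicate_seed=5)
    b = run_replicate(small_library, noise, "CH", replicate_seed=5)
    assert a == b
    c = run_replicate(small_library, noise, "CH", replicate_seed=6)
    assert a != c


def test_ranks_invariant_under_library_shuffle(small_library, rng):
    """Record order must not affect any molecule's rank (pessimistic ties)."""
    noise = NoiseModel(3.0, 0.3)
    base = run_replicate(small_library, noise, "CH", replicate_seed=9)
    perm = rng.permutation(len(small_library.records))
    shuffled = ShiftLibrary(
        [small_library.records[i] for i in perm], solvent=small_library.solvent
    )
    assert run_replicate(shuffled, noise, "CH", replicate_seed=9) == base


def test_extreme_noise_approaches_random_guessing():
    """At sigma far beyond the shift range, Top-1 falls to the 1/candidates baseline."""
    lib = generate_library(LibrarySpec(n_molecules=50, seed=21))
    baseline = random_guess_top1_baseline(lib, "C")
    fracs = []
    for rep in range(8):
        ranks = run_replicate(lib, NoiseModel(10000.0, 0.0), "C", replicate_seed=rep)
        fracs.append(np.mean([r == 1 for r in ranks.values()]))
    observed = float(np.mean(fracs)) * 100
    se = float(np.std(fracs, ddof=1)) / math.sqrt(8) * 100
    assert abs(observed - baseline) < max(4 * se, 5.0)


def test_replicate_requires_eligible_molecules():
    lib = ShiftLibrary([ShiftRecord("c_only", (1.0,), ())])
    with pytest.raises(ValueError, match="eligible"):
        run_replicate(lib, NoiseModel(0.0, 0.0), "H", replicate_seed=0)


# ---------------------------------------------------------------------------
# sweeps


def test_sweep_zero_sigma_point(small_library):
    res = sweep(small_library, [0.0], replicates=2, nuclei_mode="C", master_seed=1)
    assert np.all(res.topk_pct == 100.0)


def test_topk_nested_in_k(small_library):
    res = sweep(
        small_library, [1.0, 5.0, 20.0], replicates=3, nuclei_mode="C", master_seed=4
    )
    for si in range(len(res.sigma_grid)):
        row = res.topk_pct[si]
        assert np.all(np.diff(row) >= 0)  # Top-1 <= Top-2 <= Top-5 <= Top-10


def test_sweep_deterministic(small_library):
    a = sweep(small_library, [1.0, 4.0], replicates=2, nuclei_mode="H", master_seed=3)
    b = sweep(small_library, [1.0, 4.0], replicates=2, nuclei_mode="H", master_seed=3)
    np.testing.assert_array_equal(a.topk_fraction, b.topk_fraction)


def _mk_sweep(sigmas, top1_pct):
    n = len(sigmas)
    pct = np.asarray(top1_pct, dtype=float).reshape(n, 1)
    return SweepResult(
        nuclei_mode="C",
        sigma_grid=tuple((float(s), 0.0) for s in sigmas),
        replicates=1,
        k_values=(1,),
        topk_fraction=pct[:, None, :] / 100.0,
        topk_pct=pct,
        topk_sd=np.zeros_like(pct),
    )


def test_threshold_linear_interpolation():
    res = threshold_sigma(_mk_sweep([1.0, 2.0], [95.0, 85.0]), 90.0, k=1)
    assert res.status == "ok"
    assert res.sigma == pytest.approx(1.5, abs=1e-12)


def test_threshold_unattainable():
    res = threshold_sigma(_mk_sweep([1.0, 2.0], [80.0, 70.0]), 90.0, k=1)
    assert res.status == "unattainable"
    assert res.sigma is None


def test_threshold_attained_everywhere_flags_grid_max():
    res = threshold_sigma(_mk_sweep([1.0, 2.0, 3.0], [99.0, 97.0, 95.0]), 50.0, k=1)
    assert res.status == "everywhere"
    assert res.sigma == 3.0


def test_threshold_target_met_only_at_zero():
    res = threshold_sigma(_mk_sweep([0.0, 1.0, 2.0], [100.0, 90.0, 80.0]), 100.0, k=1)
    assert res.status == "ok"
    assert res.sigma == pytest.approx(0.0, abs=1e-12)
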