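# Methods

This note documents the models, defaults and design choices behind
`shiftmatch`. It describes what the code computes and why; every number
quoted as a result here is produced by the test suite, the `analysis/`
drivers, or `scripts/acceptance.py` — nothing is asserted that the code
does not recompute.

## Identification model

**Scoring.** A query shift list is matched onto a candidate shift list by
minimum-cost one-to-one assignment of the squared differences
(`scipy.optimize.linear_sum_assignment`; an exhaustive-enumeration oracle
cross-checks it in the tests on instances up to 8×8). The score is the RMSE
over the min(M, N) assigned pairs only; unassigned shifts on the larger
side contribute nothing. This is what lets a constituent's shifts be
matched *into* a larger pooled mixture query without penalty. The matrix
convention is rows = query ("experimental") shifts, columns = candidate
("computed") shifts; callers with a larger query side transpose first.

**Combined nuclei.** With both ¹³C and ¹H active, each nucleus is scored
separately and combined by geometric mean, √(RMSE_C·RMSE_H). The geometric
mean equalizes the very different numeric scales of the two nuclei
(≈0–220 ppm vs ≈0–12 ppm). It has a known edge: a perfect single-nucleus
match (RMSE = 0) annihilates the product and dominates the ranking
regardless of the other nucleus. The implementation follows the formula as
written; the edge is exercised in the tests, not "fixed".

**Candidate filtering.** Identification is closed-world: every query
molecule exists in the library, and candidates are the molecules with
exactly the query's nucleus counts for the active nuclei (carbon count in C
mode, hydrogen count in H mode, both in CH mode). Nuclei are listed
per atom — three methyl protons are three entries — because the assignment
matrix is defined over all nuclei. Molecules lacking an active nucleus can
never produce a defined score in that mode and are excluded from queries
and candidacies there (they stay in the library).

**Ranking and ties.** Candidates sort ascending by combined score.
The rank of the true answer is pessimistic:
1 + (#strictly better) + (#non-truth candidates with exactly equal score).
This makes reported identification rates conservative, deterministic, and
invariant to library record order (verified by a shuffle test). Rank 1
counts as positive identification; Top-k curves use k ∈ {1, 2, 5, 10}.

**MAE / RMSE / CMAE.** MAE = Σ|δ_exp − δ_calc|/N and CMAE — the MAE after
removing an OLS-fitted affine distortion, Σ|δ_exp − (δ_calc − b)/m|/N —
are provided for library reuse, but the identification pipeline itself
scores raw-shift RMSE; de-scaling before matching is an opt-in, not the
default path.

**σ versus MAE.** Error levels are expressed throughout as the Gaussian σ
of the injected noise. For zero-mean Gaussian errors the expected MAE is
σ·√(2/π) ≈ 0.798σ (`shiftmatch.synthetic.MAE_PER_SIGMA`); reported
thresholds in the literature sometimes mix the two conventions, so the
conversion factor is exposed rather than silently applied.

## Noise model

Surrogate experimental spectra are the library's own shifts plus
independent N(µ, σ) draws per nucleus, with µ = 0 by default (prediction
errors of referenced shifts are equally likely positive or negative) and
separate σ_C, σ_H. The study grids span σ_C ∈ 0.5–50 ppm and
σ_H ∈ 0.1–10 ppm. Effects deliberately not modeled: pH/temperature/salt
sensitivity, peak overlap, lineshape, missing or extra peaks, and
heavier-tailed (Student-t) error distributions.

## Synthetic libraries

Reference sets built from real metabolite databases are distributed on
request only, so the packaged studies run on synthetic libraries that
emulate their statistical structure. The generator
(`shiftmatch.synthetic.generate_library`) draws, per molecule:

* **Carbon count** from a negative binomial shifted to start at 1 and
  truncated to [1, 40], parameterized by dispersion r = 5 and mean 10 so
  the histogram is right-skewed with its mode near 8 — the shape of real
  per-molecule count histograms. The sampler's analytic pmf backs a
  chi-square check in the tests.
* **Hydrogen count**, by default, conditionally on the carbon count:
  nH = round(ρ·nC) with ρ ~ N(1.5, 0.15), clipped to [1, 60]. Real C and H
  counts are strongly correlated (hydrogens ride on the carbon skeleton),
  and that correlation concentrates the (nC, nH) occupancy — with
  independently drawn counts almost every count cell is a singleton and
  count filtering alone identifies everything, which is unrealistically
  easy. An independent truncated-negative-binomial hydrogen sampler
  (r = 5, mean 15 on [1, 60]) remains available via
  `hydrogen_per_carbon=None`.
* **Shifts** from 1–5 Gaussian clusters per molecule with spread 3 ppm
  (¹³C; the ¹H spread is scaled by the range-width ratio 12/220), cluster
  centers picked from a set of 8 *library-level* band centers placed
  uniformly at random in range, then clipped to [0, 220] / [0, 12] ppm.
  Sharing band centers across molecules mimics functional-group chemistry:
  distinct molecules collide at ppm scale, so identification degrades at
  single-digit σ the way it does on real libraries. With per-molecule
  cluster placement, same-count molecules differ by tens of ppm and
  identification would survive absurd error levels.

All randomness flows through `numpy` Generators seeded via `SeedSequence`.
Per-molecule noise streams are derived from (replicate seed, SHA-256 hash
of the molecule id), so results are independent of iteration order and any
single molecule's query is reproducible in isolation; sweep replicate r at
grid index s seeds from (master seed, s, r).

**What passing tests do and do not show.** The synthetic generator
reproduces count skew, count correlation, shift clumping and collision
rates — not the chemistry-driven fine structure of real shift
distributions, solvent effects, or real prediction-error correlations
(errors here are i.i.d. across nuclei; DFT errors are partially
systematic). Absolute thresholds measured on synthetic libraries therefore
characterize the pipeline under controlled conditions, not any particular
reference set; trends (monotone degradation, the combined-nuclei gain, the
reciprocal trade-off shape, the known/unknown-count ordering) are the
transferable results.

## Mixtures

A mixture spectrum is the union of its constituents' shift lists (no
concentration weighting, no peak merging). Candidate tuples are unordered
combinations of *distinct* molecules whose active-nucleus counts sum
exactly to the query's; enumeration walks the library's count index and
probes complements (for pairs: each count group against its complement
group; for triplets: first member × pair probe on the remainder), never the
brute-force n-fold product, and a budget (default 5·10⁶ tuples per query)
fails loudly rather than truncating silently. Incomplete tuples whose count
sums fall strictly below the query's are not scored — every candidate at
every size must account for the whole query.

With the constituent count known, only size-n tuples compete; unknown-count
identification pools sizes 1..max_n (default 3) into one ranking. The
known-count candidate set is a subset of the unknown-count set, so the true
tuple's rank can only worsen when the count is unknown — a deterministic
inequality, asserted as such. The collapse mechanism (a count-compatible
decoy of the wrong size outranking the true tuple) is demonstrated with a
constructed fixture in the tests; at the packaged 60-molecule study scale
the decoy density is low and both regimes stay near-perfect at the
(4.41, 0.6) ppm study noise point, whereas at reference-library scale
(thousands of molecules) decoys accumulate and unknown-count identification
degrades sharply. Mixture experiments sample mixtures per replicate
(default 200; the acceptance script uses 100×4 replicates) rather than
enumerating all pairs — full pair/triplet enumeration over a
thousands-strong library is cluster-scale, not desk-scale.

## Trade-off analysis

The combined-mode Top-1 surface is swept over an outer (σ_C, σ_H) grid
(replicate-averaged; contours are computed from the mean surface, matching
how averaged identification percentages are plotted). The
iso-identification contour at level L takes, per σ_H column, the largest
σ_C where the linearly interpolated Top-1 curve still meets L. Columns
whose curve never reaches L are omitted; so are *censored* columns whose
curve stays at/above L across the whole σ_C grid — their true crossing lies
beyond the grid, and substituting the grid maximum would bias the fit low.

Contours are fitted with σ_C = a/(σ_H − b) + c by nonlinear least squares
(`scipy.optimize.curve_fit`), with starting values b = 0.9·min(σ_H),
c = 0.9·min(σ_C), a from the first point — keeping the σ_H = b singularity
left of the data. The trade-off optimum minimizes the normalized cumulative
error σ_C/norm_C + σ_H/norm_H; the norms default to the sweep grid maxima
(50 and 10 ppm), the only ranges the study design defines, and are
configurable. On the reciprocal curve the optimum is closed-form
(σ_H* = b + √(a·norm_H/norm_C), σ_C* = c + √(a·norm_C/norm_H)), clipped to
the observed contour span; a fit-free grid-search optimum over raw contour
points (`optimum_from_points`) covers sparse contours.

## Study problem sizes

The packaged studies are desk-scale by design: a 300-molecule study library
(seed-pinned) for pure-sample sweeps (10-point log-spaced σ grids, 8
replicates) and the trade-off surface (8×10 grid, 4 replicates), and a
60-molecule library for mixtures (4 replicates × 100 mixtures per
condition). The full design the pipeline supports — the complete σ grids at
0.05/0.01 ppm increments with 16 replicates over thousands of molecules —
is reachable through the same interfaces (`replicates=16` is the CLI sweep
default) but takes cluster-scale compute.

## Numerical details and edge cases

* Scores are compared exactly for tie counting; ties at nonzero scores are
  measure-zero with continuous noise, but duplicate-spectrum ties at zero
  are real and handled pessimistically.
* `threshold_sigma` distinguishes "ok" (interpolated crossing),
  "unattainable" (curve never reaches the target) and "everywhere" (target
  met across the grid; the grid maximum is returned with that flag). If a
  non-monotone curve recovers after dipping below the target, the last
  at/above point is reported.
* Canonical CSV/JSON serialization uses `repr`-precision floats, so
  write→read round-trips are bit-exact (property-tested); an optional
  affine referencing correction (slope, intercept) can be applied at read
  time for unreferenced prediction output.
* Shielding-to-shift conversion from raw quantum-chemistry output is out
  of scope; ingestion expects referenced shifts in ppm.

## Known limitations

* Synthetic absolute thresholds are generator-dependent (band count,
  cluster spread and count correlation move them); only their order of
  magnitude and the qualitative trends should be read across libraries.
* The unknown-count mixture regime requires exact count sums at every
  tuple size; scoring incomplete tuples ("equal or less" counting) is a
  plausible alternative convention that is deliberately not implemented.
* The enumeration budget makes mixture identification over large libraries
  fail fast rather than run for days; Set-scale mixture studies need
  sampling and patience, not this package's defaults.
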