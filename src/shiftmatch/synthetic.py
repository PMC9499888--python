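"""Synthetic shift libraries, Gaussian noise injection, and mixture queries.

Real in silico reference sets are not redistributable, so the studies in this
package run on synthetic libraries that emulate their statistical structure:

* per-molecule carbon counts of roughly 1-40 and hydrogen counts of roughly
  1-60, with right-skewed histograms peaking near 8-12 carbons and 12-18
  hydrogens (truncated negative-binomial samplers, configurable);
* 13C shifts spanning 0-220 ppm and 1H shifts 0-12 ppm, drawn from a small
  random number of Gaussian clusters per molecule so that shifts clump the
  way functional groups make them clump — uniform i.i.d. draws would make
  identification unrealistically easy.

Surrogate "experimental" spectra are produced by adding zero-mean Gaussian
noise, N(mu, sigma), independently to every shift; sigma is the error level
under study (0.5-50 ppm for 13C, 0.1-10 ppm for 1H in the sweeps). Mixture
queries pool the shift lists of 2-3 constituent molecules before noise.

All randomness flows through numpy Generators seeded via SeedSequence; a
library spec or noise model with the same seed reproduces bit-identical
output, and per-replicate / per-molecule substreams are derived by hashing
so results do not depend on iteration order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .library import ShiftLibrary, ShiftRecord

__all__ = [
    "NoiseModel",
    "TruncatedNegativeBinomial",
    "LibrarySpec",
    "QuerySpectrum",
    "generate_library",
    "add_noise",
    "make_mixture",
    "stable_id_hash",
    "rng_for",
]

#: MAE of |N(0, sigma)| relative to sigma: E|X| = sigma * sqrt(2/pi).
#: Reported error tolerances are treated as sigma values throughout; multiply
#: by this factor to express them as the equivalent Gaussian MAE.
MAE_PER_SIGMA = math.sqrt(2.0 / math.pi)


def stable_id_hash(molecule_id: str) -> int:
    """Platform-stable 32-bit hash of a molecule id (for RNG substreams)."""
    digest = hashlib.sha256(molecule_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def rng_for(*entropy: int) -> np.random.Generator:
    """A Generator seeded from a tuple of integers (order-sensitive)."""
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def derive_seed(*entropy: int) -> int:
    """A reproducible integer seed (< 2**31) derived from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian error specification for surrogate experimental spectra.

    ``sigma_C`` and ``sigma_H`` are the per-nucleus standard deviations in
    ppm; ``mu`` is the (normally zero) mean. ``seed`` anchors the noise
    stream when the model is used standalone.
    """

    sigma_C: float
    sigma_H: float
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_C", "sigma_H"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")


class TruncatedNegativeBinomial:
    """Negative-binomial count sampler shifted to start at 1 and truncated.

    The underlying NB(r, p) is parameterized by its dispersion ``r`` and mean
    ``mean`` (of the shifted variable ``1 + NB``); samples outside
    ``[low, high]`` are rejected. Right-skewed, like per-molecule nucleus
    counts in metabolite libraries.
    """

    def __init__(self, r: float, mean: float, low: int = 1, high: int = 40):
        if r <= 0:
            raise ValueError("dispersion r must be positive")
        if not low <= mean <= high:
            raise ValueError("mean must lie inside [low, high]")
        if low < 1 or high <= low:
            raise ValueError("need 1 <= low < high")
        self.r = float(r)
        self.mean = float(mean)
        self.low = int(low)
        self.high = int(high)
        nb_mean = self.mean - 1.0  # mean of the unshifted NB
        self.p = self.r / (self.r + nb_mean)

    def pmf(self, k: int | np.ndarray) -> np.ndarray:
        """Truncated pmf on the support [low, high]."""
        from scipy.stats import nbinom

        k = np.asarray(k)
        support = np.arange(self.low, self.high + 1)
        raw = nbinom.pmf(support - 1, self.r, self.p)
        norm = raw.sum()
        out = np.zeros(k.shape if k.ndim else (), dtype=float)
        mask = (k >= self.low) & (k <= self.high)
        out = np.where(mask, nbinom.pmf(k - 1, self.r, self.p) / norm, 0.0)
        return out

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size, dtype=int)
        filled = 0
        while filled < size:
            draw = 1 + rng.negative_binomial(self.r, self.p, size=size)
            keep = draw[(draw >= self.low) & (draw <= self.high)]
            take = min(len(keep), size - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out

    def __repr__(self) -> str:
        return (
            f"TruncatedNegativeBinomial(r={self.r}, mean={self.mean}, "
            f"low={self.low}, high={self.high})"
        )


def _default_carbon_sampler() -> TruncatedNegativeBinomial:
    return TruncatedNegativeBinomial(r=5.0, mean=10.0, low=1, high=40)


def _default_hydrogen_sampler() -> TruncatedNegativeBinomial:
    return TruncatedNegativeBinomial(r=5.0, mean=15.0, low=1, high=60)


@dataclass
class LibrarySpec:
    """Recipe for a synthetic shift library.

    ``cluster_spread`` (ppm, on the carbon scale) controls how tightly a
    molecule's shifts clump around cluster centers; the proton spread is
    scaled down by the ratio of the shift-range widths so clumping is
    comparable on both nuclei.

    By default hydrogen counts are drawn conditionally on the carbon count,
    nH ~ round(ratio * nC) with Gaussian jitter on the ratio
    (``hydrogen_per_carbon = (mean_ratio, ratio_sd)``): in real molecule
    sets the two counts are strongly correlated, and that correlation is
    what concentrates the (nC, nH) occupancy and makes count-filtered
    identification non-trivial. Set ``hydrogen_per_carbon=None`` to draw
    hydrogen counts independently from ``hydrogen_count_sampler``.
    """

    n_molecules: int
    carbon_count_sampler: TruncatedNegativeBinomial = field(
        default_factory=_default_carbon_sampler
    )
    hydrogen_count_sampler: TruncatedNegativeBinomial = field(
        default_factory=_default_hydrogen_sampler
    )
    hydrogen_per_carbon: tuple[float, float] | None = (1.5, 0.15)
    carbon_shift_range: tuple[float, float] = (0.0, 220.0)
    proton_shift_range: tuple[float, float] = (0.0, 12.0)
    cluster_spread: float = 3.0
    n_bands: int = 8
    solvent: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        for name in ("carbon_shift_range", "proton_shift_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)) or hi <= lo:
                raise ValueError(f"{name} must be a non-degenerate finite interval")
        if self.cluster_spread <= 0:
            raise ValueError("cluster_spread must be positive")
        if self.n_bands < 1:
            raise ValueError("n_bands must be positive")


def _draw_clustered_shifts(
    rng: np.random.Generator,
    n: int,
    bands: np.ndarray,
    shift_range: tuple[float, float],
    spread: float,
) -> np.ndarray:
    """Draw n shifts from 1-5 Gaussian clusters centered on shared bands.

    The band centers are a library-level resource (think functional-group
    regions): every molecule picks a small number of them and scatters its
    shifts around the picks. Sharing bands across molecules is what makes
    distinct molecules collide at ppm scale, the way real spectra do.
    """
    lo, hi = shift_range
    n_clusters = int(rng.integers(1, min(5, n) + 1))
    centers = rng.choice(bands, size=n_clusters, replace=True)
    membership = rng.integers(0, n_clusters, size=n)
    shifts = centers[membership] + rng.normal(0.0, spread, size=n)
    return np.clip(shifts, lo, hi)


def generate_library(spec: LibrarySpec) -> ShiftLibrary:
    """Generate a synthetic library; bit-identical across runs for one spec."""
    rng = rng_for(spec.seed)
    n_c = spec.carbon_count_sampler.sample(rng, spec.n_molecules)
    if spec.hydrogen_per_carbon is not None:
        ratio_mean, ratio_sd = spec.hydrogen_per_carbon
        lo = spec.hydrogen_count_sampler.low
        hi = spec.hydrogen_count_sampler.high
        ratios = rng.normal(ratio_mean, ratio_sd, size=spec.n_molecules)
        n_h = np.clip(np.rint(ratios * n_c).astype(int), lo, hi)
    else:
        n_h = spec.hydrogen_count_sampler.sample(rng, spec.n_molecules)
    c_lo, c_hi = spec.carbon_shift_range
    h_lo, h_hi = spec.proton_shift_range
    h_width = h_hi - h_lo
    c_width = c_hi - c_lo
    proton_spread = spec.cluster_spread * h_width / c_width
    # shared band centers, placed uniformly in range once per library
    carbon_bands = rng.uniform(c_lo, c_hi, size=spec.n_bands)
    proton_bands = rng.uniform(h_lo, h_hi, size=spec.n_bands)
    width = len(str(spec.n_molecules))
    records = []
    for i in range(spec.n_molecules):
        carbons = _draw_clustered_shifts(
            rng, int(n_c[i]), carbon_bands, spec.carbon_shift_range, spec.cluster_spread
        )
        protons = _draw_clustered_shifts(
            rng, int(n_h[i]), proton_bands, spec.proton_shift_range, proton_spread
        )
        records.append(
            ShiftRecord(
                molecule_id=f"SYN{i:0{width}d}",
                carbon_shifts=tuple(carbons.tolist()),
                proton_shifts=tuple(protons.tolist()),
            )
        )
    return ShiftLibrary(records, solvent=spec.solvent)


def add_noise(
    shifts: Sequence[float],
    sigma: float,
    mu: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add one independent N(mu, sigma) draw to every shift.

    Output preserves length and order; sigma = 0 returns the input values
    (plus mu) exactly. The generator state advances deterministically.
    """
    if sigma < 0 or not math.isfinite(sigma):
        raise ValueError(f"sigma must be finite and non-negative, got {sigma!r}")
    arr = np.asarray(shifts, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    if sigma == 0.0:
        return arr + mu
    return arr + rng.normal(mu, sigma, size=arr.shape)


@dataclass(frozen=True)
class QuerySpectrum:
    """A query shift list with its ground truth, when known.

    ``true_ids`` is empty for externally supplied spectra; ``n_constituents``
    is an integer for known-composition queries and ``"unknown"`` otherwise.
    """

    carbon_shifts: tuple[float, ...]
    proton_shifts: tuple[float, ...]
    true_ids: tuple[str, ...] = ()
    n_constituents: int | str = 1

    @property
    def n_carbon(self) -> int:
        return len(self.carbon_shifts)

    @property
    def n_hydrogen(self) -> int:
        return len(self.proton_shifts)


def make_mixture(
    records: Sequence[ShiftRecord],
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    max_constituents: int = 3,
) -> QuerySpectrum:
    """Pool constituent spectra and add noise: a surrogate mixture query.

    Carbon and proton shift lists are the concatenations of the
    constituents' lists (in input order), each perturbed with the noise
    model. With a single record and sigma = mu = 0 the query equals the
    record's spectrum.
    """
    if not records:
        raise ValueError("a mixture needs at least one constituent record")
    if len(records) > max_constituents:
        raise ValueError(
            f"{len(records)} constituents exceeds the configured maximum {max_constituents}"
        )
    if rng is None:
        rng = rng_for(noise.seed)
    carbons = np.concatenate([r.carbon_shifts for r in records]) if any(
        r.carbon_shifts for r in records
    ) else np.empty(0)
    protons = np.concatenate([r.proton_shifts for r in records]) if any(
        r.proton_shifts for r in records
    ) else np.empty(0)
    noisy_c = add_noise(carbons, noise.sigma_C, noise.mu, rng) if carbons.size else carbons
    noisy_h = add_noise(protons, noise.sigma_H, noise.mu, rng) if protons.size else protons
    return QuerySpectrum(
        carbon_shifts=tuple(noisy_c.tolist()),
        proton_shifts=tuple(noisy_h.tolist()),
        true_ids=tuple(r.molecule_id for r in records),
        n_constituents=len(records),
    )
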