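"""Folded minor-allele site frequency spectra from genotype matrices.

Missing genotypes are compensated per site by bootstrap resampling of the
alleles observed at that site within the resampling unit (the whole sample
for the 1D spectrum, each population separately for the 2D spectrum):
missing chromosome slots are drawn with replacement from the observed allele
copies until the full 2n chromosomes are reached. Sites with no observed
allele in a unit are dropped with a logged count.

Folding conventions (used consistently for observed and expected spectra):

* 1D: for n diploids the classes are i = 0..n minor-allele chromosomes out
  of 2n; an exact 50/50 tie (count n of 2n) goes to the top class i = n.
* 2D: cell (i, j) with i of 2n1 and j of 2n2 chromosomes, folded on the
  total minor allele; a tie (i + j = n1 + n2) keeps the lexicographically
  smaller of (i, j) and its complement.

Sites that are (or become, after filling) monomorphic are kept in the zero
class so that the spectrum always sums to the number of retained sites; the
likelihood machinery masks that class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("demog")

__all__ = [
    "SFS1D",
    "SFS2D",
    "bootstrap_fill",
    "sfs_1d",
    "sfs_2d",
    "fold_1d",
    "fold_2d",
    "fold_cell_2d",
]


@dataclass
class SFS1D:
    """Folded 1D minor-allele SFS: counts[i] sites with i minor chromosomes
    out of 2n, i = 0..n for n diploids."""

    counts: np.ndarray
    n: int
    seed: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n + 1:
            raise ValueError("counts must have length n + 1")
        if (self.counts < 0).any():
            raise ValueError("negative SFS entries")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SFS1D)
            and self.n == other.n
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SFS2D:
    """Folded joint minor-allele SFS over two population samples of n1 and
    n2 diploids; counts has shape (2*n1 + 1, 2*n2 + 1) with mass only on
    canonical (minor-orientation) cells."""

    counts: np.ndarray
    n1: int
    n2: int
    seed: int | None = None
    n_dropped: int = 0
    # optional number of surveyed sites (incl. monomorphic) behind this SNP
    # panel; when set, absolute parameter scale becomes identifiable through
    # the mutation rate (segregating-sites term in the likelihood)
    mutation_opportunity: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2 * self.n1 + 1, 2 * self.n2 + 1):
            raise ValueError("counts shape must be (2*n1+1, 2*n2+1)")
        if (self.counts < 0).any():
            raise ValueError("negative SFS entries")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SFS2D)
            and (self.n1, self.n2) == (other.n1, other.n2)
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# Folding


def fold_1d(vec: np.ndarray) -> np.ndarray:
    """Fold a spectrum over classes 0..2n down to minor classes 0..n.

    Idempotent: a vector of length n + 1 (already folded) is returned as-is
    if passed with its zero-padded upper half, and folding the result again
    changes nothing.
    """
    vec = np.asarray(vec)
    m = len(vec) - 1  # = 2n chromosomes
    n = m // 2
    out = np.zeros(n + 1, dtype=vec.dtype)
    for i in range(m + 1):
        out[min(i, m - i)] += vec[i]
    return out


def fold_cell_2d(i: int, j: int, nc1: int, nc2: int) -> tuple[int, int]:
    """Canonical (minor) orientation of unfolded cell (i, j) with nc1, nc2
    chromosomes per population; folding is on the total minor allele."""
    tot = nc1 + nc2
    ci, cj = nc1 - i, nc2 - j
    if 2 * (i + j) > tot:
        return ci, cj
    if 2 * (i + j) == tot:
        return (i, j) if (i, j) <= (ci, cj) else (ci, cj)
    return i, j


from functools import lru_cache


@lru_cache(maxsize=32)
def _fold_map(nc1: int, nc2: int) -> np.ndarray:
    """Flat canonical-cell index for every unfolded cell of a 2D spectrum."""
    idx = np.empty((nc1 + 1) * (nc2 + 1), dtype=np.int64)
    for i in range(nc1 + 1):
        for j in range(nc2 + 1):
            fi, fj = fold_cell_2d(i, j, nc1, nc2)
            idx[i * (nc2 + 1) + j] = fi * (nc2 + 1) + fj
    return idx


def fold_2d(mat: np.ndarray) -> np.ndarray:
    """Fold an unfolded 2D spectrum onto canonical cells (idempotent)."""
    mat = np.asarray(mat)
    nc1, nc2 = mat.shape[0] - 1, mat.shape[1] - 1
    out = np.zeros(mat.size, dtype=mat.dtype)
    np.add.at(out, _fold_map(nc1, nc2), mat.ravel())
    return out.reshape(mat.shape)


# ---------------------------------------------------------------------------
# Bootstrap compensation of missing data


def bootstrap_fill(
    site_alleles: tuple[int, int], target_chromosomes: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Complete one site's allele counts within one resampling unit.

    site_alleles = (ref_copies, alt_copies) observed among the non-missing
    genotypes of the unit. Missing slots are filled by drawing from the
    observed copies with replacement until target_chromosomes is reached.
    Raises ValueError if the unit has no observed allele.
    """
    ref, alt = int(site_alleles[0]), int(site_alleles[1])
    obs = ref + alt
    if obs == 0:
        raise ValueError("no observed alleles in resampling unit")
    if obs > target_chromosomes:
        raise ValueError("observed alleles exceed target chromosome count")
    n_miss = target_chromosomes - obs
    if n_miss:
        extra_alt = int(rng.binomial(n_miss, alt / obs))
        alt += extra_alt
        ref += n_miss - extra_alt
    return ref, alt


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _observed_counts(column: np.ndarray) -> tuple[int, int]:
    """(ref, alt) allele copies among non-missing genotypes of one site."""
    obs = column[column != MISSING]
    alt = int(obs.sum())
    return 2 * len(obs) - alt, alt


def sfs_1d(
    G: GenotypeMatrix, individuals: list[str] | None = None, seed: int | None = 0
) -> SFS1D:
    """Folded 1D minor-allele SFS over the given individuals (default all),
    with per-site bootstrap completion of missing genotypes."""
    if individuals is None:
        individuals = list(G.individuals)
    if not individuals:
        raise ValueError("individuals must be nonempty")
    sub = G.subset_individuals(individuals)
    rng = _as_rng(seed)
    n = sub.n_individuals
    target = 2 * n
    counts = np.zeros(n + 1, dtype=np.int64)
    dropped = 0
    for s in range(sub.n_sites):
        ref, alt = _observed_counts(sub.dosage[:, s])
        if ref + alt == 0:
            dropped += 1
            continue
        _, alt_full = bootstrap_fill((ref, alt), target, rng)
        counts[min(alt_full, target - alt_full)] += 1
    if dropped:
        logger.info("sfs_1d: dropped %d all-missing sites", dropped)
    return SFS1D(counts, n=n, seed=seed if isinstance(seed, int) else None, n_dropped=dropped)


def sfs_2d(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str],
    seed: int | None = 0,
) -> SFS2D:
    """Folded joint minor-allele SFS for two disjoint population samples,
    with bootstrap completion performed independently within each population
    and folding on the total minor allele."""
    m1 = [i for i in G.individuals if i in set(popmap.members(pops[0]))]
    m2 = [i for i in G.individuals if i in set(popmap.members(pops[1]))]
    if not m1 or not m2:
        raise ValueError("both populations must be nonempty")
    if set(m1) & set(m2):
        raise ValueError("populations must be disjoint")
    sub1 = G.subset_individuals(m1)
    sub2 = G.subset_individuals(m2)
    rng = _as_rng(seed)
    n1, n2 = len(m1), len(m2)
    nc1, nc2 = 2 * n1, 2 * n2
    counts = np.zeros((nc1 + 1, nc2 + 1), dtype=np.int64)
    dropped = 0
    for s in range(G.n_sites):
        r1, a1 = _observed_counts(sub1.dosage[:, s])
        r2, a2 = _observed_counts(sub2.dosage[:, s])
        if r1 + a1 == 0 or r2 + a2 == 0:
            dropped += 1
            continue
        _, i = bootstrap_fill((r1, a1), nc1, rng)
        _, j = bootstrap_fill((r2, a2), nc2, rng)
        fi, fj = fold_cell_2d(i, j, nc1, nc2)
        counts[fi, fj] += 1
    if dropped:
        logger.info("sfs_2d: dropped %d sites unobserved in one population", dropped)
    return SFS2D(
        counts, n1=n1, n2=n2, seed=seed if isinstance(seed, int) else None, n_dropped=dropped
    )
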