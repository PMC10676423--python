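"""Two-population coalescent simulator with piecewise-constant sizes and a
single divergence event; no migration.

This module doubles as the synthetic-data generator: it produces SNP
genotype matrices with missingness (stand-ins for reduced-representation
MIG-seq-style data), Monte Carlo expected site frequency spectra for the
composite likelihood, and toy cpDNA haplotype alignments.

Conventions: sizes N are diploid effective sizes, so k lineages coalesce at
rate C(k,2)/(2N) per generation; times are in generations before present
and increase into the past. At TDIV all lineages of population 2 join
population 1's ancestral pool.

The expected SFS is computed from per-class expected branch lengths
(E[L_c] / E[L_tot]) rather than by placing literal mutations: for
independently ascertained segregating sites in the small-mutation-rate
limit this ratio is the exact per-site class law, and averaging branch
lengths removes the mutational sampling noise. Genotype data are generated
consistently by sampling genealogies proportionally to total branch length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotype_io import MISSING, Alignment, GenotypeMatrix, PopulationMap
from .sfs_builder import fold_2d

logger = logging.getLogger("demog")

__all__ = [
    "PopEpochs",
    "DemographicModel",
    "SampleConfig",
    "Genealogy",
    "single_population_model",
    "simulate_genealogy",
    "simulate_snp",
    "simulate_sites",
    "simulate_dataset",
    "expected_sfs_mc",
    "implied_mutation_opportunity",
    "simulate_cpdna",
]


@dataclass(frozen=True)
class PopEpochs:
    """Piecewise-constant sizes: sizes[0] applies from the epoch start up to
    times[0], sizes[1] from times[0] to times[1], ..., sizes[-1] onward.
    Times are absolute generations before present, strictly increasing."""

    sizes: tuple[float, ...]
    times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.times) + 1:
            raise ValueError("need exactly len(times) + 1 sizes")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")
        t = np.asarray(self.times, dtype=float)
        if (t < 0).any() or (np.diff(t) <= 0).any():
            raise ValueError("epoch times must be non-negative and increasing")


@dataclass(frozen=True)
class DemographicModel:
    """Two extant populations that merge (backward in time) at tdiv into an
    ancestral population. pop1 is the Mt. Ibuki-like lineage, pop2 the
    Hokkaido-like lineage. No migration."""

    pop1: PopEpochs
    pop2: PopEpochs
    tdiv: float
    ancestral: PopEpochs  # times absolute, all > tdiv

    def __post_init__(self) -> None:
        if self.tdiv < 0:
            raise ValueError("tdiv must be non-negative")
        for pe in (self.pop1, self.pop2):
            if any(t > self.tdiv for t in pe.times):
                raise ValueError("within-population size changes must predate tdiv")
        if any(t <= self.tdiv for t in self.ancestral.times):
            raise ValueError("ancestral size changes must be older than tdiv")

    def rescaled(self, c: float) -> "DemographicModel":
        """All sizes and times multiplied by c (coalescent scale map)."""
        def sc(pe: PopEpochs) -> PopEpochs:
            return PopEpochs(
                tuple(s * c for s in pe.sizes), tuple(t * c for t in pe.times)
            )
        return DemographicModel(sc(self.pop1), sc(self.pop2), self.tdiv * c, sc(self.ancestral))


@dataclass(frozen=True)
class SampleConfig:
    """Diploid sample sizes, SNP count and per-genotype missingness."""

    n1: int
    n2: int = 0
    n_snps: int = 1
    missingness: float = 0.0
    seed: int = 0
    # optional Beta(a, b) per-site missingness rates (locus-clustered
    # missingness); None = i.i.d. per genotype at `missingness`
    missing_beta: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 0:
            raise ValueError("need n1 >= 1 and n2 >= 0")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must be in [0, 1)")


def _flatten(model: DemographicModel):
    return (
        np.asarray(model.pop1.times, float),
        np.asarray(model.pop1.sizes, float),
        np.asarray(model.pop2.times, float),
        np.asarray(model.pop2.sizes, float),
        float(model.tdiv),
        np.asarray(model.ancestral.times, float),
        np.asarray(model.ancestral.sizes, float),
    )


def single_population_model(
    sizes: tuple[float, ...], times: tuple[float, ...] = ()
) -> DemographicModel:
    """A panmictic population with piecewise-constant sizes, expressed as a
    degenerate two-population model (tdiv = 0, all history ancestral).
    Sample it with n2 = 0."""
    shifted = tuple(t for t in times)
    if shifted and shifted[0] <= 0:
        raise ValueError("size-change times must be positive")
    return DemographicModel(
        pop1=PopEpochs((sizes[0],)),
        pop2=PopEpochs((sizes[0],)),
        tdiv=0.0,
        ancestral=PopEpochs(tuple(sizes), shifted),
    )


# ---------------------------------------------------------------------------
# Fast branch-length kernel (expected SFS)


@njit(cache=True)
def _phase(active, k, t0, t_end, times, sizes, d1, d2, birth, L, exps, us, next_node):
    """Coalesce lineages active[:k] from t0 to t_end under piecewise sizes,
    accumulating each dying lineage's branch length into its descendant
    class in L. One Exp(1) draw and one uniform are consumed per event
    attempt, keeping the random stream aligned across nearby parameter
    values (common random numbers). Returns (k, next_node)."""
    t = t0
    ne = times.shape[0]
    ei = 0
    while ei < ne and times[ei] <= t:
        ei += 1
    slot = 0
    while k > 1:
        lam = 0.5 * k * (k - 1)
        need = exps[slot] / lam  # remaining waiting time in scaled (tau) units
        event = False
        while True:
            if ei < ne:
                seg_end = times[ei]
            else:
                seg_end = np.inf
            if seg_end > t_end:
                seg_end = t_end
            N2 = 2.0 * sizes[ei]
            avail = (seg_end - t) / N2
            if need <= avail:
                t = t + need * N2
                event = True
                break
            need -= avail
            t = seg_end
            if t >= t_end:
                break
            ei += 1
        if not event:
            break
        # one uniform encodes an ordered pair: integer and fractional parts
        u = us[slot] * k
        i = int(u)
        if i >= k:
            i = k - 1
        j = int((u - i) * (k - 1))
        if j >= k - 1:
            j = k - 2
        if j >= i:
            j += 1
        slot += 1
        a = active[i]
        b = active[j]
        L[d1[a], d2[a]] += t - birth[a]
        L[d1[b], d2[b]] += t - birth[b]
        node = next_node
        d1[node] = d1[a] + d1[b]
        d2[node] = d2[a] + d2[b]
        birth[node] = t
        next_node += 1
        lo = i if i < j else j
        hi = j if i < j else i
        active[lo] = node
        active[hi] = active[k - 1]
        k -= 1
    return k, next_node


@njit(cache=True)
def _branch_lengths(nc1, nc2, t1, s1, t2, s2, tdiv, ta, sa, n_reps, seed):
    """Accumulated expected branch length per unfolded descendant class
    (i copies in pop1, j in pop2), averaged over n_reps genealogies."""
    np.random.seed(seed)
    L = np.zeros((nc1 + 1, nc2 + 1))
    ntot = nc1 + nc2
    cap = 2 * ntot
    d1 = np.zeros(cap, np.int64)
    d2 = np.zeros(cap, np.int64)
    birth = np.zeros(cap)
    act = np.zeros(ntot, np.int64)
    act2 = np.zeros(ntot, np.int64)
    for _ in range(n_reps):
        for i in range(nc1):
            act[i] = i
            d1[i] = 1
            d2[i] = 0
            birth[i] = 0.0
        for i in range(nc2):
            act2[i] = nc1 + i
            d1[nc1 + i] = 0
            d2[nc1 + i] = 1
            birth[nc1 + i] = 0.0
        next_node = ntot
        exps = np.random.exponential(1.0, 2 * ntot)
        us = np.random.random(2 * ntot)
        k1, next_node = _phase(
            act, nc1, 0.0, tdiv, t1, s1, d1, d2, birth, L,
            exps[:nc1], us[:nc1], next_node,
        )
        k2, next_node = _phase(
            act2, nc2, 0.0, tdiv, t2, s2, d1, d2, birth, L,
            exps[nc1:ntot], us[nc1:ntot], next_node,
        )
        for i in range(k2):
            act[k1 + i] = act2[i]
        k = k1 + k2
        k, next_node = _phase(
            act, k, tdiv, np.inf, ta, sa, d1, d2, birth, L,
            exps[ntot:], us[ntot:], next_node,
        )
    return L / n_reps


# ---------------------------------------------------------------------------
# Genealogy objects (python path, used for data generation)


@dataclass
class Genealogy:
    """Ultrametric genealogy of 2*n1 + 2*n2 tips: tips 0..2n1-1 belong to
    population 1, the rest to population 2. parent[x] = -1 marks the root."""

    n_tips1: int
    n_tips2: int
    parent: np.ndarray
    time: np.ndarray  # node times (tips at 0)

    @property
    def n_tips(self) -> int:
        return self.n_tips1 + self.n_tips2

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def edge_lengths(self) -> np.ndarray:
        """Parent-edge length per node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has = self.parent >= 0
        out[has] = self.time[self.parent[has]] - self.time[has]
        return out

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def tips_under(self, node: int) -> np.ndarray:
        """Tip indices descending from (and including) the given node."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for x, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(x)
        out = []
        stack = [node]
        while stack:
            x = stack.pop()
            if x < self.n_tips:
                out.append(x)
            else:
                stack.extend(children[x])
        return np.array(sorted(out), dtype=int)


def _py_phase(active, t0, t_end, times, sizes, parent, time, rng):
    t = t0
    times = list(times)
    ei = 0
    while ei < len(times) and times[ei] <= t:
        ei += 1
    k = len(active)
    while k > 1:
        need = rng.exponential() / (0.5 * k * (k - 1))
        event = False
        while True:
            seg_end = times[ei] if ei < len(times) else np.inf
            seg_end = min(seg_end, t_end)
            N2 = 2.0 * sizes[ei]
            avail = (seg_end - t) / N2
            if need <= avail:
                t += need * N2
                event = True
                break
            need -= avail
            t = seg_end
            if t >= t_end:
                break
            ei += 1
        if not event:
            break
        i, j = rng.choice(k, size=2, replace=False)
        node = len(parent)
        parent.append(-1)
        time.append(t)
        parent[active[i]] = node
        parent[active[j]] = node
        lo, hi = min(i, j), max(i, j)
        active[lo] = node
        active[hi] = active[-1]
        active.pop()
        k -= 1
    return t


def simulate_genealogy(
    model: DemographicModel, sample_config: SampleConfig, seed=None
) -> Genealogy:
    """Draw one genealogy of 2*n1 + 2*n2 chromosome tips under the model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nc1, nc2 = 2 * sample_config.n1, 2 * sample_config.n2
    parent: list[int] = [-1] * (nc1 + nc2)
    time: list[float] = [0.0] * (nc1 + nc2)
    act1 = list(range(nc1))
    act2 = list(range(nc1, nc1 + nc2))
    _py_phase(act1, 0.0, model.tdiv, model.pop1.times, model.pop1.sizes, parent, time, rng)
    if act2:
        _py_phase(act2, 0.0, model.tdiv, model.pop2.times, model.pop2.sizes, parent, time, rng)
    merged = act1 + act2
    _py_phase(
        merged, model.tdiv, np.inf, model.ancestral.times, model.ancestral.sizes,
        parent, time, rng,
    )
    return Genealogy(nc1, nc2, np.array(parent), np.array(time))


def _mutate(gen: Genealogy, rng: np.random.Generator) -> np.ndarray:
    """Place one mutation uniformly on total branch length; return the 0/1
    derived-allele vector over tips (guaranteed polymorphic)."""
    lengths = gen.edge_lengths()
    probs = lengths / lengths.sum()
    node = rng.choice(gen.n_nodes, p=probs)
    alleles = np.zeros(gen.n_tips, dtype=np.int8)
    alleles[gen.tips_under(node)] = 1
    return alleles


def _genealogy_pool(model, sample_config, n_sites, rng, pool_factor=2):
    """Genealogies sampled with probability proportional to total branch
    length (importance pool), so that per-site class frequencies follow the
    segregating-site law E[L_c]/E[L_tot]."""
    n_pool = max(int(pool_factor * n_sites), 100)
    pool = [simulate_genealogy(model, sample_config, rng) for _ in range(n_pool)]
    w = np.array([g.total_length() for g in pool])
    idx = rng.choice(n_pool, size=n_sites, replace=True, p=w / w.sum())
    return [pool[i] for i in idx]


def simulate_snp(
    model: DemographicModel, sample_config: SampleConfig, seed=None
) -> np.ndarray:
    """One biallelic site's derived-allele assignment over the 2n1 + 2n2
    chromosomes (infinite sites: a single mutation, always polymorphic)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gen = _genealogy_pool(model, sample_config, 1, rng, pool_factor=32)[0]
    return _mutate(gen, rng)


def simulate_sites(
    model: DemographicModel, sample_config: SampleConfig, seed=None
) -> np.ndarray:
    """Matrix (n_snps, 2n1+2n2) of derived-allele assignments at independent
    SNPs (each SNP on its own genealogy)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gens = _genealogy_pool(model, sample_config, sample_config.n_snps, rng)
    return np.vstack([_mutate(g, rng) for g in gens])


def simulate_dataset(
    model: DemographicModel, sample_config: SampleConfig, seed=None
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Synthetic SNP dataset: independent SNPs, chromosomes paired randomly
    into diploids within each population, genotypes masked i.i.d. at the
    configured missingness rate. Returns a VCF-writable matrix + popmap."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(sample_config.seed if seed is None else seed)
    )
    n1, n2 = sample_config.n1, sample_config.n2
    nc1, nc2 = 2 * n1, 2 * n2
    sites_alleles = simulate_sites(model, sample_config, rng)
    # random pairing of chromosomes into diploids within each population
    perm1 = rng.permutation(nc1)
    perm2 = nc1 + rng.permutation(nc2) if n2 else np.array([], dtype=int)
    order = np.concatenate([perm1, perm2]).astype(int)
    hap = sites_alleles[:, order]  # (S, chroms) reordered
    dosage = (hap[:, 0::2] + hap[:, 1::2]).T.astype(np.int8)  # (n1+n2, S)
    S = sample_config.n_snps
    if sample_config.missing_beta is not None:
        a, b = sample_config.missing_beta
        site_rates = rng.beta(a, b, size=S)
        mask = rng.random(dosage.shape) < site_rates[None, :]
    elif sample_config.missingness > 0:
        mask = rng.random(dosage.shape) < sample_config.missingness
    else:
        mask = np.zeros(dosage.shape, dtype=bool)
    dosage[mask] = MISSING
    individuals = [f"pop1_{i}" for i in range(n1)] + [f"pop2_{i}" for i in range(n2)]
    sites = [f"1:{1000 * (s + 1)}" for s in range(S)]
    labels = {ind: ("pop1" if i < n1 else "pop2") for i, ind in enumerate(individuals)}
    return GenotypeMatrix(individuals, sites, dosage), PopulationMap(labels)


# ---------------------------------------------------------------------------
# Expected SFS by Monte Carlo


def expected_sfs_mc(
    model: DemographicModel,
    sample_config: SampleConfig,
    n_sims: int,
    seed: int = 0,
    fold: bool = True,
    n_batches: int = 1,
    return_total: bool = False,
):
    """Expected (normalized) SFS over polymorphic classes by Monte Carlo.

    Returns a (2n1+1, 2n2+1) matrix of class probabilities (mass only on
    canonical cells when folded; the monomorphic class is structurally
    zero). With return_total=True, returns (probs, total) where total is
    the expected total genealogy length in generations (the mutation
    opportunity scale). With n_batches > 1, returns (probs, se) where se is
    the per-cell Monte Carlo standard error estimated from batch means.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    t1, s1, t2, s2, tdiv, ta, sa = _flatten(model)
    nc1, nc2 = 2 * sample_config.n1, 2 * sample_config.n2
    seed = int(seed) % (2**31 - 1)

    def one(batch_seed: int, reps: int) -> tuple[np.ndarray, float]:
        L = _branch_lengths(nc1, nc2, t1, s1, t2, s2, tdiv, ta, sa, reps, batch_seed)
        if fold:
            L = fold_2d(L)
        tot = L.sum()
        return L / tot, float(tot)

    if n_batches <= 1:
        probs, tot = one(seed, n_sims)
        return (probs, tot) if return_total else probs
    per = max(n_sims // n_batches, 1)
    pairs = [one(seed + b, per) for b in range(n_batches)]
    mats = np.array([p for p, _ in pairs])
    probs = mats.mean(axis=0)
    se = mats.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return probs, se


def implied_mutation_opportunity(
    model: DemographicModel,
    sample_config: SampleConfig,
    n_snps: int,
    mu: float,
    n_sims: int = 20_000,
    seed: int = 0,
) -> float:
    """Number of surveyed sites L that would yield n_snps segregating sites
    in expectation under the model: L = S / (mu * E[T_total]). Used to give
    synthetic SNP panels the absolute-scale information that a real assay's
    known site count provides."""
    _, tot = expected_sfs_mc(model, sample_config, n_sims, seed=seed, return_total=True)
    return n_snps / (mu * tot)


# ---------------------------------------------------------------------------
# cpDNA fixture generator


def simulate_cpdna(
    haplotype_definitions: dict[str, list[tuple[int, str]]],
    counts: dict[str, int],
    length: int,
    seed: int = 0,
) -> Alignment:
    """Toy aligned cpDNA matrix with an exact haplotype multiset.

    haplotype_definitions maps a haplotype label to its variant positions
    (0-based) and bases relative to a random background sequence; counts
    gives the number of copies of each haplotype.
    """
    rng = np.random.default_rng(seed)
    background = rng.choice(list("ACGT"), size=length)
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for name, variants in haplotype_definitions.items():
        seq = background.copy()
        for pos, base in variants:
            if not (0 <= pos < length):
                raise ValueError(f"variant position {pos} out of range for length {length}")
            # guarantee a real substitution even if the random background
            # already carries the requested base
            seq[pos] = base if background[pos] != base else rot[base]
        for c in range(counts.get(name, 0)):
            ids.append(f"{name}_{c}")
            rows.append(seq)
    if not rows:
        raise ValueError("no sequences requested")
    return Alignment(ids, np.array(rows))
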