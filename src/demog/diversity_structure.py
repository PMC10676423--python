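"""Per-individual heterozygosity, pairwise LD (r2), greedy LD pruning, and
Evanno-style delta-K post-processing of clustering log-likelihoods.

r2 is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete individuals (the PLINK convention for unphased SNPs).
Pruning removes, from every pair with r2 above the threshold, the site with
the lower genotyping rate, iterating to a fixpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("demog")

__all__ = [
    "LDPruneConfig",
    "StructureLogLik",
    "heterozygosity_proportion",
    "pairwise_r2",
    "ld_prune",
    "delta_k",
]


@dataclass(frozen=True)
class LDPruneConfig:
    """r2 threshold above which one of a site pair is removed; ties on equal
    genotyping rate remove the later site (deterministic total order)."""

    r2_threshold: float = 0.6
    tie_rule: str = "remove-later"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2 threshold must be in [0, 1]")


@dataclass
class StructureLogLik:
    """Replicate log-likelihoods per assumed number of ancestral clusters K
    (K = 1..Kmax, >= 2 replicates each for a standard deviation)."""

    loglik: dict[int, list[float]]

    def __post_init__(self) -> None:
        ks = sorted(self.loglik)
        if len(ks) < 3:
            raise ValueError("need at least 3 consecutive K values for delta-K")
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("K values must be consecutive")
        for k, reps in self.loglik.items():
            if len(reps) < 2:
                raise ValueError(f"K={k}: need >= 2 replicates")


def heterozygosity_proportion(G: GenotypeMatrix) -> dict[str, float]:
    """Proportion of heterozygous sites per individual: (# dosage-1 sites) /
    (# non-missing sites). Individuals with no called site map to NaN
    (undefined, never 0)."""
    out: dict[str, float] = {}
    for i, ind in enumerate(G.individuals):
        row = G.dosage[i]
        called = row != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            logger.warning("heterozygosity: individual %s has no called sites", ind)
            out[ind] = math.nan
        else:
            out[ind] = float((row[called] == 1).sum() / n_called)
    return out


def pairwise_r2(G: GenotypeMatrix, site_a: int, site_b: int) -> float:
    """Squared Pearson correlation of the two sites' dosages over
    pairwise-complete individuals; NaN when fewer than two complete
    individuals remain or either site is monomorphic on the overlap."""
    a = G.dosage[:, site_a].astype(float)
    b = G.dosage[:, site_b].astype(float)
    ok = (G.dosage[:, site_a] != MISSING) & (G.dosage[:, site_b] != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return math.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(G: GenotypeMatrix, cfg: LDPruneConfig | None = None) -> list[int]:
    """Greedy LD pruning: scan site pairs in ascending index order; whenever
    r2 > threshold remove the lower-genotyping-rate site (tie: the later
    site); repeat until no violating pair remains. Returns retained site
    indices. Undefined (NaN) r2 never triggers removal."""
    cfg = cfg or LDPruneConfig()
    rates = G.site_genotyping_rate()
    retained = list(range(G.n_sites))
    changed = True
    while changed:
        changed = False
        removed: set[int] = set()
        for ai in range(len(retained)):
            sa = retained[ai]
            if sa in removed:
                continue
            for bi in range(ai + 1, len(retained)):
                if sa in removed:
                    break
                sb = retained[bi]
                if sb in removed:
                    continue
                r2 = pairwise_r2(G, sa, sb)
                if not math.isnan(r2) and r2 > cfg.r2_threshold:
                    if rates[sa] < rates[sb]:
                        removed.add(sa)
                    elif rates[sb] < rates[sa]:
                        removed.add(sb)
                    else:
                        removed.add(sb)  # tie: remove the later site
                    changed = True
        if removed:
            retained = [s for s in retained if s not in removed]
    return retained


def delta_k(L: StructureLogLik) -> dict[int, float]:
    """Evanno-style delta-K for each interior K: the mean over replicates of
    |L(K+1) - 2 L(K) + L(K-1)| divided by the replicate standard deviation
    of L(K). Undefined (NaN, with a warning) when that sd is zero."""
    ks = sorted(L.loglik)
    out: dict[int, float] = {}
    for k in ks[1:-1]:
        prev, cur, nxt = (np.asarray(L.loglik[j], float) for j in (k - 1, k, k + 1))
        n = min(len(prev), len(cur), len(nxt))
        second = np.abs(nxt[:n] - 2 * cur[:n] + prev[:n]).mean()
        sd = cur.std(ddof=1)
        if sd == 0:
            logger.warning("delta_k: zero replicate sd at K=%d; undefined", k)
            out[k] = math.nan
        else:
            out[k] = float(second / sd)
    return out
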