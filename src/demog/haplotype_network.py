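"""Collapse an aligned cpDNA matrix into haplotypes and build a
parsimony-style mutational network.

The network is a minimum spanning network on Hamming distances: edges are
added level by level in increasing distance, keeping all ties (so it is a
network, not a tree), and any edge of d > 1 steps is expanded through d - 1
inferred intermediate ("missing") haplotypes, each edge then representing
exactly one mutational step. Alignment columns containing ambiguous
characters or gaps are masked before comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .genotype_io import Alignment

logger = logging.getLogger("demog")

__all__ = ["HaplotypeSet", "HaplotypeNetwork", "collapse_haplotypes", "build_network"]


@dataclass
class HaplotypeSet:
    """Distinct sequences (over the masked columns) with frequencies and
    member lists, ordered and labelled by first occurrence (H1, H2, ...)."""

    sequences: list[str]
    labels: list[str]
    members: list[list[str]]
    masked_columns: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def frequencies(self) -> list[int]:
        return [len(m) for m in self.members]


@dataclass
class HaplotypeNetwork:
    """Graph whose nodes are observed haplotypes plus inferred
    intermediates (``inferred`` node attribute) and whose edges each
    represent one mutational step."""

    graph: nx.Graph
    haplotypes: HaplotypeSet

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("inferred")]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("inferred")]

    def steps_between(self, a: str, b: str) -> int:
        return nx.shortest_path_length(self.graph, a, b)


def collapse_haplotypes(
    aln: Alignment, ignore_chars: frozenset[str] | set[str] = frozenset("N-")
) -> HaplotypeSet:
    """Merge sequences identical after masking every column that contains
    any of ignore_chars in any sequence."""
    if aln.n_seqs == 0:
        raise ValueError("empty alignment")
    bad = np.zeros(aln.length, dtype=bool)
    for ch in ignore_chars:
        bad |= (aln.seqs == ch).any(axis=0)
    keep = ~bad
    if bad.any():
        logger.info("collapse_haplotypes: masked %d ambiguous/gap columns", int(bad.sum()))
    seen: dict[str, int] = {}
    sequences: list[str] = []
    members: list[list[str]] = []
    for i, name in enumerate(aln.ids):
        key = "".join(aln.seqs[i][keep])
        if key not in seen:
            seen[key] = len(sequences)
            sequences.append(key)
            members.append([])
        members[seen[key]].append(name)
    labels = [f"H{i + 1}" for i in range(len(sequences))]
    return HaplotypeSet(sequences, labels, members, masked_columns=np.where(bad)[0])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(haps: HaplotypeSet, limit: int | None = None) -> HaplotypeNetwork:
    """Minimum spanning network with all minimal-distance ties kept and
    multi-step edges expanded through inferred intermediate nodes.
    Haplotype pairs farther apart than ``limit`` are left unconnected."""
    if haps.n_haplotypes == 0:
        raise ValueError("no haplotypes")
    g = nx.Graph()
    for lab, freq in zip(haps.labels, haps.frequencies):
        g.add_node(lab, inferred=False, frequency=freq)
    dist = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(haps.sequences), 2):
        dist[(i, j)] = _hamming(a, b)
    inferred_count = 0
    for d in sorted(set(dist.values())):
        if d == 0:
            continue
        if limit is not None and d > limit:
            break
        # component structure before this distance level; all level-d edges
        # joining distinct components are kept (ties yield loops)
        comp = {n: c for c, nodes in enumerate(nx.connected_components(g)) for n in nodes}
        for (i, j), dij in dist.items():
            if dij != d:
                continue
            a, b = haps.labels[i], haps.labels[j]
            if comp[a] == comp[b]:
                continue
            prev = a
            for step in range(d - 1):
                inferred_count += 1
                mid = f"m{inferred_count}"
                g.add_node(mid, inferred=True, frequency=0)
                g.add_edge(prev, mid)
                prev = mid
            g.add_edge(prev, b)
    net = HaplotypeNetwork(g, haps)
    for n in net.inferred_nodes:
        assert g.degree[n] >= 2
    return net
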