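"""Readers and writers for the external formats the pipeline touches.

Genotypes are held as a dense diploid dosage matrix (individuals x sites)
counting copies of the ALT allele, with ``MISSING = -1`` for no-calls.
Coordinates follow the VCF convention (1-based positions); a site is
identified by its ``chrom:pos`` string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("demog")

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "ScalingConfig",
    "Alignment",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "write_sfs",
    "read_sfs",
]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with explicit missing data.

    dosage[i, s] is the number of ALT-allele copies carried by individual i
    at site s: 0, 1, 2, or MISSING (-1). Half-calls are treated as missing.
    """

    individuals: list[str]
    sites: list[str]
    dosage: np.ndarray  # (n_individuals, n_sites) int8

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("dosage shape does not match individuals x sites")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_genotyping_rate(self) -> np.ndarray:
        """Fraction of non-missing individuals per site."""
        return (self.dosage != MISSING).mean(axis=0)

    def individual_genotyping_rate(self) -> np.ndarray:
        """Fraction of non-missing sites per individual."""
        return (self.dosage != MISSING).mean(axis=1)

    def subset_individuals(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(n) for n in names]
        return GenotypeMatrix(list(names), list(self.sites), self.dosage[idx, :])

    def subset_sites(self, keep: list[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            list(self.individuals), [self.sites[i] for i in keep], self.dosage[:, keep]
        )


@dataclass
class PopulationMap:
    """Mapping individual -> population label, e.g. I1-I3 / H1-H3 / G,
    with an optional coarser lineage grouping (e.g. Mt. Ibuki = I1+I2+I3)."""

    labels: dict[str, str]
    lineages: dict[str, list[str]] = field(default_factory=dict)

    def population(self, individual: str) -> str:
        return self.labels[individual]

    def members(self, group: str) -> list[str]:
        """Individuals belonging to a population label or lineage group."""
        pops = self.lineages.get(group, [group])
        return [ind for ind, lab in self.labels.items() if lab in pops]

    def check_covers(self, G: GenotypeMatrix) -> None:
        missing = [i for i in G.individuals if i not in self.labels]
        if missing:
            raise ValueError(f"individuals without population label: {missing[:5]}")


@dataclass(frozen=True)
class ScalingConfig:
    """Mutation rate per site per generation and generation time in years.

    Defaults: mu = 7e-9 (an A. thaliana-derived spontaneous rate commonly
    borrowed for herbaceous plants) and g = 2 years for a perennial herb.
    """

    mu: float = 7e-9
    generation_years: float = 2.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_years <= 0:
            raise ValueError("mu and generation time must be positive")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Read diploid biallelic SNPs from a VCF v4.x file.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    dropped with a logged count. Phased and unphased genotypes are treated
    identically; any genotype containing a missing allele (including
    half-calls such as ``0/.``) becomes MISSING.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_subset is not None:
        keep = [s for s in sample_subset if s in samples]
        if not keep:
            raise ValueError("no samples overlap the requested subset")
        vcf.close()
        vcf = VCF(str(path), samples=keep)
        samples = list(vcf.samples)

    sites: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
            n_dropped += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) < 3:
                raise ValueError(f"malformed GT at {var.CHROM}:{var.POS}")
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                dos[i] = MISSING
            else:
                dos[i] = a0 + a1
        sites.append(f"{var.CHROM}:{var.POS}")
        rows.append(dos)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    dosage = (
        np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    )
    return GenotypeMatrix(samples, sites, dosage)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal uncompressed VCF 4.2 file (REF=A, ALT=T)."""
    path = Path(path)
    chroms = sorted({s.split(":")[0] for s in G.sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individuals)
            + "\n"
        )
        for s_idx, site in enumerate(G.sites):
            chrom, pos = site.split(":")
            gts = "\t".join(_GT_STR[int(d)] for d in G.dosage[:, s_idx])
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Population map


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column TSV (individual, population). Extra columns are
    ignored with a warning; duplicate individuals are an error."""
    path = Path(path)
    labels: dict[str, str] = {}
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            if len(parts) > 2 and not warned:
                logger.warning("read_popmap: ignoring extra columns in %s", path)
                warned = True
            ind, pop = parts[0].strip(), parts[1].strip()
            if ind in labels:
                raise ValueError(f"duplicate individual id {ind!r}")
            labels[ind] = pop
    if not labels:
        raise ValueError(f"empty population map {path}")
    return PopulationMap(labels)


def write_popmap(pm: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, pop in pm.labels.items():
            fh.write(f"{ind}\t{pop}\n")


# ---------------------------------------------------------------------------
# FASTA alignment


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A, C, G, T, N, -}."""

    ids: list[str]
    seqs: np.ndarray  # (n_seqs, length) of single-character unicode

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs)
        if self.seqs.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(self.seqs[i])


_ALPHABET = set("ACGTN-")


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; sequences are uppercased and must be of
    equal length over the alphabet {A, C, G, T, N, -}."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    ids = [r.id for r in records]
    rows = []
    for r in records:
        s = str(r.seq).upper()
        bad = set(s) - _ALPHABET
        if bad:
            raise ValueError(f"invalid characters {bad} in sequence {r.id}")
        rows.append(list(s))
    return Alignment(ids, np.array(rows))


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(aln.ids):
            fh.write(f">{name}\n{aln.sequence(i)}\n")


# ---------------------------------------------------------------------------
# SFS text formats
#
# Dialect "obs" mirrors the fastsimcoal2 observed-SFS text convention
# (header line "1 observations", labelled entries); dialect "tsv" is a plain
# table. Reading back what was written is the identity for both dialects.


def write_sfs(sfs, path: str | Path, dialect: str = "obs") -> None:
    from .sfs_builder import SFS1D, SFS2D

    path = Path(path)
    if dialect not in ("obs", "tsv"):
        raise ValueError(f"unknown SFS dialect {dialect!r}")
    with open(path, "w") as fh:
        if isinstance(sfs, SFS1D):
            counts = sfs.counts
            if dialect == "obs":
                fh.write("1 observations\n")
                fh.write("\t".join(f"d0_{i}" for i in range(len(counts))) + "\n")
                fh.write("\t".join(str(int(c)) for c in counts) + "\n")
            else:
                fh.write("# sfs1d\tn=%d\n" % sfs.n)
                for i, c in enumerate(counts):
                    fh.write(f"{i}\t{int(c)}\n")
        elif isinstance(sfs, SFS2D):
            m = sfs.counts
            if dialect == "obs":
                fh.write("1 observations\n")
                fh.write("\t" + "\t".join(f"d0_{j}" for j in range(m.shape[1])) + "\n")
                for i in range(m.shape[0]):
                    fh.write(
                        f"d1_{i}\t" + "\t".join(str(int(c)) for c in m[i]) + "\n"
                    )
            else:
                fh.write("# sfs2d\tn1=%d\tn2=%d\n" % (sfs.n1, sfs.n2))
                for i in range(m.shape[0]):
                    fh.write("\t".join(str(int(c)) for c in m[i]) + "\n")
        else:
            raise TypeError("sfs must be SFS1D or SFS2D")


def read_sfs(path: str | Path, dialect: str = "obs"):
    from .sfs_builder import SFS1D, SFS2D

    path = Path(path)
    if dialect not in ("obs", "tsv"):
        raise ValueError(f"unknown SFS dialect {dialect!r}")
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if dialect == "obs":
        if not lines or "observations" not in lines[0]:
            raise ValueError(f"{path} is not an obs-dialect SFS file")
        header = lines[1]
        if header.startswith("\t") or header.split("\t")[0] == "":
            # 2D: column labels then row-labelled count rows
            rows = []
            for ln in lines[2:]:
                parts = ln.split("\t")
                rows.append([int(float(x)) for x in parts[1:]])
            m = np.array(rows, dtype=np.int64)
            return SFS2D(m, n1=(m.shape[0] - 1) // 2, n2=(m.shape[1] - 1) // 2)
        counts = np.array([int(float(x)) for x in lines[2].split("\t")], dtype=np.int64)
        return SFS1D(counts, n=len(counts) - 1)
    # tsv
    meta = lines[0]
    if "sfs1d" in meta:
        counts = np.array([int(ln.split("\t")[1]) for ln in lines[1:]], dtype=np.int64)
        return SFS1D(counts, n=len(counts) - 1)
    if "sfs2d" in meta:
        m = np.array([[int(x) for x in ln.split("\t")] for ln in lines[1:]], np.int64)
        return SFS2D(m, n1=(m.shape[0] - 1) // 2, n2=(m.shape[1] - 1) // 2)
    raise ValueError(f"unrecognized tsv SFS header in {path}")
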