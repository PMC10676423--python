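import numpy as np
import pytest

from demog.genotype_io import (
    MISSING,
    GenotypeMatrix,
    read_fasta_alignment,
    read_popmap,
    read_sfs,
    read_vcf,
    write_sfs,
    write_vcf,
)
from demog.sfs_builder import SFS1D, SFS2D

from conftest import random_genotypes

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB\n"
)


def _write(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_direct_dosage_encoding(self, tmp_path):
        p = _write(tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        G = read_vcf(p)
        assert G.individuals == ["sampleA", "sampleB"]
        assert G.sites == ["1:100"]
        assert G.dosage[:, 0].tolist() == [1, 2]

    def test_missing_and_half_calls_become_missing(self, tmp_path):
        body = (
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t0/0\n"
            "1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t0/.\t1|1\n"
        )
        G = read_vcf(_write(tmp_path, body))
        assert G.dosage[0, 0] == MISSING
        assert G.site_genotyping_rate()[0] == 0.5
        # half-call treated as missing; phased genotype treated as unphased
        assert G.dosage[0, 1] == MISSING
        assert G.dosage[1, 1] == 2

    def test_non_snp_records_dropped_with_hand_count(self, tmp_path):
        lines = []
        for pos in range(100, 2100, 100):  # 20 records
            lines.append(f"1\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n")
        # make 3 of them multiallelic / indel
        lines[3] = "1\t400\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        lines[7] = "1\t800\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        lines[12] = "1\t1300\t.\tA\tATT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        G = read_vcf(_write(tmp_path, "".join(lines)))
        assert G.n_sites == 17

    def test_sample_subset_and_errors(self, tmp_path):
        p = _write(tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        G = read_vcf(p, sample_subset=["sampleB"])
        assert G.individuals == ["sampleB"]
        assert G.dosage[0, 0] == 2
        with pytest.raises(ValueError):
            read_vcf(p, sample_subset=["nobody"])
        with pytest.raises(FileNotFoundError):
            read_vcf(tmp_path / "absent.vcf")

    def test_site_rates_match_brute_force_recount(self, tmp_path, rng):
        G0 = random_genotypes(rng, n_ind=6, n_sites=15, missing=0.3)
        path = tmp_path / "rt.vcf"
        write_vcf(G0, path)
        G = read_vcf(path)
        raw = [ln.split("\t")[9:] for ln in path.read_text().splitlines() if not ln.startswith("#")]
        brute = np.array(
            [sum(gt != "./." for gt in row) / len(row) for row in raw]
        )
        np.testing.assert_allclose(G.site_genotyping_rate(), brute)
        np.testing.assert_array_equal(G.dosage, G0.dosage)


class TestSfsFiles:
    @pytest.mark.parametrize("dialect", ["obs", "tsv"])
    def test_1d_roundtrip(self, tmp_path, dialect):
        sfs = SFS1D(np.array([0, 3, 1]), n=2)
        path = tmp_path / "a.sfs"
        write_sfs(sfs, path, dialect=dialect)
        assert read_sfs(path, dialect=dialect) == sfs

    @pytest.mark.parametrize("dialect", ["obs", "tsv"])
    def test_2d_roundtrip(self, tmp_path, dialect, rng):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[0, 1] = 4
        counts[1, 0] = 2
        counts[1, 1] = 1
        sfs = SFS2D(counts, n1=1, n2=1)
        path = tmp_path / "b.sfs"
        write_sfs(sfs, path, dialect=dialect)
        assert read_sfs(path, dialect=dialect) == sfs

    def test_randomized_roundtrip(self, tmp_path, rng):
        for _ in range(5):
            n = int(rng.integers(1, 6))
            sfs = SFS1D(rng.integers(0, 50, n + 1), n=n)
            write_sfs(sfs, tmp_path / "r.sfs", "obs")
            assert read_sfs(tmp_path / "r.sfs", "obs") == sfs

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError):
            write_sfs(SFS1D(np.array([0, 1]), n=1), tmp_path / "x", dialect="xyz")


class TestPopmap:
    def test_three_lines(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("a\tI1\nb\tI1\nc\tG\n")
        pm = read_popmap(p)
        assert len(pm.labels) == 3
        assert pm.population("c") == "G"

    def test_duplicate_rejected(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("a\tI1\na\tI2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_popmap(p)

    def test_extra_columns_ignored(self, tmp_path, caplog):
        p = tmp_path / "pm.tsv"
        p.write_text("a\tI1\textra\nb\tI2\tmore\n")
        pm = read_popmap(p)
        assert pm.labels == {"a": "I1", "b": "I2"}

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_popmap(p)


class TestFasta:
    def test_read_and_uppercase(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nacgtacgtnn\n>s2\nACGTACGTAC\n>s3\nACGT-CGTAC\n")
        aln = read_fasta_alignment(p)
        assert aln.n_seqs == 3 and aln.length == 10
        assert aln.sequence(0) == "ACGTACGTNN"

    def test_ragged_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n>s2\nACG\n")
        with pytest.raises(ValueError, match="ragged"):
            read_fasta_alignment(p)

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta_alignment(p)


def test_genotype_matrix_invariants():
    with pytest.raises(ValueError):
        GenotypeMatrix(["a"], ["1:1"], np.array([[5]], dtype=np.int8))
    G = GenotypeMatrix(["a", "b"], ["1:1"], np.array([[1], [MISSING]], dtype=np.int8))
    assert G.individual_genotyping_rate().tolist() == [1.0, 0.0]
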