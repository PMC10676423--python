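import numpy as np
import pytest

from demog.coalescent_sim import (
    DemographicModel,
    PopEpochs,
    SampleConfig,
    expected_sfs_mc,
    simulate_cpdna,
    simulate_dataset,
    simulate_genealogy,
    simulate_sites,
    simulate_snp,
    single_population_model,
)
from demog.genotype_io import MISSING, read_vcf, write_vcf
from demog.sfs_builder import fold_2d


class TestModelValidation:
    def test_size_change_must_predate_divergence(self):
        with pytest.raises(ValueError):
            DemographicModel(
                PopEpochs((1e3, 1e4), (500.0,)),
                PopEpochs((1e3,)),
                tdiv=100.0,
                ancestral=PopEpochs((1e4,)),
            )

    def test_ancestral_changes_must_be_older_than_divergence(self):
        with pytest.raises(ValueError):
            DemographicModel(
                PopEpochs((1e3,)),
                PopEpochs((1e3,)),
                tdiv=100.0,
                ancestral=PopEpochs((1e4, 1e5), (50.0,)),
            )

    def test_positive_sizes_required(self):
        with pytest.raises(ValueError):
            PopEpochs((0.0,))

    def test_sample_config_bounds(self):
        with pytest.raises(ValueError):
            SampleConfig(n1=0)
        with pytest.raises(ValueError):
            SampleConfig(n1=1, missingness=1.0)


class TestGenealogy:
    def test_pairwise_tmrca_two_epoch_closed_form(self):
        # E[T2] = int_0^inf P(T2 > t) dt
        #       = 2 N0 (1 - e^{-t1/(2 N0)}) + 2 N1 e^{-t1/(2 N0)}
        N0, N1, t1 = 1_000.0, 10_000.0, 800.0
        model = single_population_model((N0, N1), (t1,))
        rng = np.random.default_rng(42)
        sample = SampleConfig(n1=1, n2=0)
        times = np.array(
            [simulate_genealogy(model, sample, rng).tmrca() for _ in range(8_000)]
        )
        expected = 2 * N0 * (1 - np.exp(-t1 / (2 * N0))) + 2 * N1 * np.exp(
            -t1 / (2 * N0)
        )
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se

    def test_ultrametric_and_tip_counts(self):
        model = single_population_model((5_000.0,))
        gen = simulate_genealogy(model, SampleConfig(n1=4, n2=0), 7)
        assert gen.n_tips == 8 and gen.n_nodes == 15
        assert (gen.time[:8] == 0).all()
        root = int(np.argmax(gen.time))
        assert gen.parent[root] == -1
        assert len(gen.tips_under(root)) == 8

    def test_two_tip_mutation_is_always_singleton(self):
        model = single_population_model((1_000.0,))
        for seed in range(10):
            alleles = simulate_snp(model, SampleConfig(n1=1, n2=0), seed)
            assert alleles.sum() == 1


class TestExpectedSfs:
    def test_constant_size_matches_folded_neutral_law(self):
        model = single_population_model((10_000.0,))
        probs = expected_sfs_mc(model, SampleConfig(n1=5, n2=0), 100_000, seed=1)[:, 0]
        law = np.zeros(6)
        for i in range(1, 10):
            law[min(i, 10 - i)] += 1 / i
        law /= law.sum()
        assert probs[6:].sum() == 0  # folded: no mass above n
        np.testing.assert_allclose(probs[:6], law, atol=0.01)

    def test_scale_invariance_is_exact_under_common_random_numbers(self):
        model = DemographicModel(
            PopEpochs((2e3, 4e4), (175.0,)),
            PopEpochs((1e3, 2e4), (2.5e3,)),
            tdiv=1.6e4,
            ancestral=PopEpochs((4e4,)),
        )
        sample = SampleConfig(n1=6, n2=4)
        a = expected_sfs_mc(model, sample, 3_000, seed=9)
        b = expected_sfs_mc(model.rescaled(3.0), sample, 3_000, seed=9)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_population_swap_symmetry_at_zero_divergence(self):
        model = DemographicModel(
            PopEpochs((5e3,)), PopEpochs((5e3,)), tdiv=0.0, ancestral=PopEpochs((5e3,))
        )
        sample = SampleConfig(n1=4, n2=4)
        probs, se = expected_sfs_mc(model, sample, 200_000, seed=3, n_batches=20)
        sym = fold_2d(probs.T.copy())
        err = np.abs(probs - sym)
        tol = 3 * np.sqrt(2) * np.maximum(se, 1e-4)
        assert (err <= tol + 1e-9).all()

    def test_deep_divergence_kills_shared_polymorphism(self):
        model = DemographicModel(
            PopEpochs((1e3,)), PopEpochs((1e3,)), tdiv=1e6, ancestral=PopEpochs((1e3,))
        )
        probs = expected_sfs_mc(model, SampleConfig(n1=4, n2=4), 30_000, seed=2)
        shared = sum(
            probs[i, j]
            for i in range(1, 8)
            for j in range(1, 8)
        )
        assert shared < 0.01


class TestMsprimeOracle:
    def test_two_population_expected_sfs_against_msprime(self):
        import msprime

        N1, N1A, T1 = 2_000.0, 20_000.0, 300.0
        N2, TDIV, NANC = 500.0, 4_000.0, 15_000.0
        model = DemographicModel(
            PopEpochs((N1, N1A), (T1,)),
            PopEpochs((N2,)),
            tdiv=TDIV,
            ancestral=PopEpochs((NANC,)),
        )
        n1, n2 = 5, 3
        ours, se = expected_sfs_mc(
            model, SampleConfig(n1=n1, n2=n2), 200_000, seed=11, n_batches=20
        )

        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=N1)
        dem.add_population(name="p2", initial_size=N2)
        dem.add_population(name="anc", initial_size=NANC)
        dem.add_population_parameters_change(time=T1, population="p1", initial_size=N1A)
        dem.add_population_split(time=TDIV, derived=["p1", "p2"], ancestral="anc")
        reps = msprime.sim_ancestry(
            samples={"p1": n1, "p2": n2},
            demography=dem,
            num_replicates=3_000,
            random_seed=17,
        )
        afs = np.zeros((2 * n1 + 1, 2 * n2 + 1))
        afs_sq = np.zeros_like(afs)
        nrep = 0
        for ts in reps:
            one = ts.allele_frequency_spectrum(
                sample_sets=[
                    ts.samples(population=0),
                    ts.samples(population=1),
                ],
                mode="branch",
                polarised=True,
                span_normalise=True,
            )
            afs += one
            afs_sq += one**2
            nrep += 1
        mean = afs / nrep
        se_ms_unfold = np.sqrt(
            np.maximum(afs_sq / nrep - mean**2, 0.0) / nrep
        )
        theirs_raw = fold_2d(mean)
        theirs = theirs_raw / theirs_raw.sum()
        se_ms = fold_2d(se_ms_unfold) / theirs_raw.sum()
        z = np.abs(ours - theirs) / np.sqrt(se**2 + se_ms**2 + 1e-12)
        mask = (ours > 1e-4) | (theirs > 1e-4)
        assert z[mask].max() < 4.0


class TestDataset:
    def test_no_missingness_gives_full_genotyping_rate(self):
        model = single_population_model((2e3,))
        G, _ = simulate_dataset(model, SampleConfig(n1=5, n2=0, n_snps=30, seed=1))
        assert (G.dosage != MISSING).all()

    def test_missingness_rate_matches_target(self):
        model = single_population_model((2e3,))
        G, _ = simulate_dataset(
            model, SampleConfig(n1=20, n2=0, n_snps=300, missingness=0.4, seed=2)
        )
        rate = (G.dosage != MISSING).mean()
        assert rate == pytest.approx(0.6, abs=0.02)

    def test_vcf_roundtrip_identity(self, tmp_path):
        model = DemographicModel(
            PopEpochs((2e3,)), PopEpochs((1e3,)), tdiv=500.0, ancestral=PopEpochs((5e3,))
        )
        G, pm = simulate_dataset(
            model, SampleConfig(n1=6, n2=3, n_snps=40, missingness=0.2, seed=3)
        )
        write_vcf(G, tmp_path / "sim.vcf")
        G2 = read_vcf(tmp_path / "sim.vcf")
        np.testing.assert_array_equal(G.dosage, G2.dosage)
        assert set(pm.labels.values()) == {"pop1", "pop2"}

    def test_every_simulated_site_is_polymorphic(self):
        model = single_population_model((2e3,))
        sites = simulate_sites(model, SampleConfig(n1=5, n2=0, n_snps=50, seed=4), 4)
        counts = sites.sum(axis=1)
        assert ((counts > 0) & (counts < 10)).all()


class TestCpDna:
    DEFS = {"J": [], "UG": [(100, "G"), (400, "C")], "CG": [(100, "G")]}

    def test_haplotype_multiset_and_length(self):
        aln = simulate_cpdna(self.DEFS, {"J": 32, "UG": 4, "CG": 6}, 1064, seed=0)
        assert aln.n_seqs == 42 and aln.length == 1064
        assert len({aln.sequence(i) for i in range(42)}) == 3

    def test_single_haplotype_has_no_segregating_sites(self):
        aln = simulate_cpdna({"J": []}, {"J": 5}, 200, seed=0)
        assert len({aln.sequence(i) for i in range(5)}) == 1

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_cpdna({"X": [(500, "A")]}, {"X": 1}, 100, seed=0)
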