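import numpy as np
import pytest

from demog.coalescent_sim import SampleConfig, implied_mutation_opportunity, simulate_dataset
from demog.demographic_inference import (
    InferenceConfig,
    composite_loglik,
    convert_time,
    fit_model,
    model1_spec,
    model2_spec,
    parametric_bootstrap,
    select_model,
    FitResult,
)
from demog.genotype_io import ScalingConfig
from demog.pipeline import DEFAULT_MODEL2_TRUTH
from demog.sfs_builder import SFS2D, sfs_2d


def _fit(name, loglik, k):
    return FitResult(
        model_name=name, params={}, loglik=loglik, k=k, seed=0,
        n_starts=1, cycles_used=1, best_start=0,
    )


class TestCompositeLoglik:
    def test_two_class_arithmetic(self):
        obs = np.array([[0, 5, 5]])
        p = np.array([[0.0, 0.5, 0.5]])
        assert composite_loglik(obs, p) == pytest.approx(10 * np.log(0.5))

    def test_empirical_frequencies_maximize(self, rng):
        for _ in range(10):
            m = rng.integers(0, 30, size=(1, 6)).astype(float)
            m[0, 0] = 0
            if m.sum() == 0:
                continue
            p_hat = m / m.sum()
            best = composite_loglik(m, p_hat)
            delta = rng.dirichlet(np.ones(5)) - 0.2
            p_alt = p_hat.copy()
            p_alt[0, 1:] = np.maximum(p_hat[0, 1:] + 0.2 * delta, 1e-6)
            p_alt /= p_alt.sum()
            assert composite_loglik(m, p_alt) <= best + 1e-9

    def test_zero_probability_class_hits_floor(self):
        obs = np.array([[0, 4, 0], [3, 0, 0]])
        p = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        ll = composite_loglik(obs, p, prob_floor=1e-10)
        assert np.isfinite(ll)
        assert ll == pytest.approx(3 * np.log(1e-10))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loglik(np.ones((2, 2)), np.ones((3, 2)))

    def test_monomorphic_class_masked(self):
        obs = np.array([[7, 5, 5]])
        p = np.array([[0.9, 0.05, 0.05]])
        # the (0,0) entry contributes nothing; p renormalized over the rest
        assert composite_loglik(obs, p) == pytest.approx(10 * np.log(0.5))


class TestModelSpecs:
    def test_model1_divergence_bound_and_build(self):
        spec = model1_spec()
        assert spec.ranges["TDIV"][0] == 5_000.0
        assert spec.k == 8
        params = dict(
            N1CUR=2e3, N1ANC=4e4, T1=175.0, N2CUR=1e3, N2ANC=2e4, T2=2.5e3,
            NANC=4e4, TDIV=1.6e4,
        )
        model = spec.build(params)
        assert model.tdiv == 1.6e4
        with pytest.raises(ValueError):
            spec.validate({**params, "TDIV": 4_000.0})
        with pytest.raises(ValueError):
            model1_spec({"TDIV": (100.0, 1e5)})

    def test_model2_bounds_and_founding_topology(self):
        spec = model2_spec()
        assert spec.ranges["TDIV"][1] == 100.0
        assert spec.k == 6
        params = dict(DEFAULT_MODEL2_TRUTH)
        model = spec.build(params)
        # pop2 merges into pop1's ancestral lineage at TDIV (two extant
        # populations, a single ancestral population, no third lineage)
        assert model.tdiv <= 100.0
        assert len(model.ancestral.sizes) == 2
        with pytest.raises(ValueError):
            spec.validate({**params, "TDIV": 150.0})
        with pytest.raises(ValueError):
            spec.validate({**params, "TANC": params["TDIV"] / 2})

    def test_constraint_aware_bounds(self):
        spec = model1_spec()
        params = dict(
            N1CUR=2e3, N1ANC=4e4, T1=175.0, N2CUR=1e3, N2ANC=2e4, T2=2.5e3,
            NANC=4e4, TDIV=6_000.0,
        )
        lo, hi = spec.bounds_for("T1", params)
        assert hi < 6_000.0
        lo, hi = spec.bounds_for("TDIV", params)
        assert lo >= 2.5e3


class TestSelectModel:
    def test_delta_aic_matches_reported_scale(self):
        best, delta = select_model([_fit("a", -42.0, 8), _fit("b", -69.45, 8)])
        assert best.model_name == "a"
        assert delta["b"] == pytest.approx(54.9)
        assert delta["a"] == 0.0

    def test_tie_keeps_first(self):
        best, delta = select_model([_fit("a", -10.0, 2), _fit("b", -10.0, 2)])
        assert best.model_name == "a"

    def test_three_fits_nonnegative_deltas(self):
        fits = [_fit("a", -12.0, 2), _fit("b", -10.0, 2), _fit("c", -11.0, 2)]
        best, delta = select_model(fits)
        assert best.model_name == "b"
        assert all(v >= 0 for v in delta.values())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


def test_aic_identity():
    f = _fit("m", loglik=-123.4, k=7)
    assert f.aic == pytest.approx(2 * 7 - 2 * -123.4)


class TestConvertTime:
    def test_paper_scale_arithmetic(self):
        assert convert_time(16_396, ScalingConfig(generation_years=2.0)) == 32_792

    def test_zero_and_identity(self):
        assert convert_time(0, ScalingConfig()) == 0
        assert convert_time(123.0, ScalingConfig(generation_years=1.0)) == 123.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_time(-1, ScalingConfig())


def _small_model2_obs(seed=5, snps=250, n1=8, n2=4):
    spec = model2_spec()
    truth = dict(DEFAULT_MODEL2_TRUTH)
    model = spec.build(truth)
    sample = SampleConfig(n1=n1, n2=n2, n_snps=snps, missingness=0.1, seed=seed)
    G, pm = simulate_dataset(model, sample)
    obs = sfs_2d(G, pm, ("pop1", "pop2"), seed=seed + 1)
    obs.mutation_opportunity = implied_mutation_opportunity(
        model, sample, obs.n_sites, ScalingConfig().mu, n_sims=5_000, seed=seed + 2
    )
    return spec, truth, obs


class TestFitModel:
    def test_best_loglik_monotone_in_starts_with_common_random_numbers(self):
        spec, truth, obs = _small_model2_obs()
        lls = []
        for n_starts in (1, 2, 3):
            cfg = InferenceConfig(
                n_starts=n_starts, ecm_cycles=2, sims_per_eval=1_000, seed=7,
                brent_maxiter=4, polish_cycles=0,
            )
            lls.append(fit_model(obs, spec, cfg).loglik)
        assert lls[0] <= lls[1] + 1e-9 <= lls[2] + 2e-9

    def test_refit_from_truth_stays_near_truth(self):
        spec, truth, obs = _small_model2_obs()
        cfg = InferenceConfig(
            n_starts=1, ecm_cycles=3, sims_per_eval=2_000, seed=3,
            brent_maxiter=5, polish_cycles=1,
        )
        fit = fit_model(obs, spec, cfg, start=truth)
        assert fit.model_name == "model2"
        assert fit.loglik > -1e7
        assert 2.0 <= fit.params["TDIV"] <= 100.0

    def test_empty_sfs_rejected(self):
        spec = model2_spec()
        empty = SFS2D(np.zeros((17, 9), dtype=int), n1=8, n2=4)
        with pytest.raises(ValueError):
            fit_model(empty, spec, InferenceConfig())


class TestParametricBootstrap:
    def test_small_bootstrap_returns_ci_per_parameter(self):
        spec, truth, obs = _small_model2_obs()
        cfg = InferenceConfig(
            n_starts=1, ecm_cycles=2, sims_per_eval=1_500, n_bootstrap=4,
            bootstrap_cycles=1, seed=9, brent_maxiter=4, polish_cycles=0,
        )
        fit = fit_model(obs, spec, cfg, start=truth)
        res = parametric_bootstrap(obs, fit, spec, cfg)
        assert res.n_replicates == 4
        assert set(res.ci) == set(spec.param_names)
        for lo, hi in res.ci.values():
            assert lo <= hi
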