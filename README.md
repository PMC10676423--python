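# demog

Coalescent demographic inference from folded minor-allele site frequency
spectra, built around the question of whether two small, disjunct plant
populations (a Mt. Ibuki-like and a central-Hokkaido-like lineage of the
bush vetch *Vicia sepium*) split anciently and naturally or were introduced
recently by humans.

The package provides, as a library and a `demog` command line:

* **`genotype_io`** — VCF/FASTA/population-map readers, fastsimcoal-style
  `.obs` and TSV SFS files, a diploid dosage matrix with explicit missing
  data and genotyping rates.
* **`sfs_builder`** — folded 1D and joint 2D minor-allele spectra with
  per-site bootstrap compensation of missing genotypes (resampling observed
  allele copies within each population).
* **`coalescent_sim`** — a two-population coalescent simulator with
  piecewise-constant diploid sizes and a divergence event (no migration);
  doubles as the synthetic-data generator (SNP panels with missingness,
  Monte Carlo expected spectra via a numba branch-length kernel, toy cpDNA
  alignments).
* **`demographic_inference`** — multinomial composite likelihood on the
  2D-mSFS plus a segregating-sites term that pins the absolute (N, T)
  scale through the mutation rate; cyclic-conditional (ECM-style)
  maximization with common random numbers; AIC model selection between an
  ancient-divergence model (TDIV ≥ 5,000 generations, 8 parameters) and a
  recent-introduction model (TDIV ≤ 100 generations, 6 parameters);
  parametric-bootstrap confidence intervals.
* **`stairway_estimator`** — flexible piecewise-constant Ne trajectories
  from a folded 1D SFS, with a deterministic expected-SFS evaluator
  (pure-death lineage chain + Polanski–Kimmel-type weights) and held-out
  likelihood control of the number of epochs.
* **`diversity_structure`** — per-individual heterozygosity, pairwise r²
  and greedy LD pruning (r² > 0.6 removes the lower-genotyping-rate site),
  Evanno-style ΔK.
* **`haplotype_network`** — haplotype collapsing and a minimum spanning
  network with inferred intermediate ("missing") haplotypes.
* **`pipeline`** — end-to-end orchestration from a JSON config with
  derived per-stage seeds.

The central statistic: for observed folded class counts m_c and expected
class probabilities p_c(θ) from 10⁴–10⁵ coalescent simulations,

    ln L(θ) = Σ_c m_c ln max(p_c(θ), ε)  +  S ln q(θ) + (L − S) ln(1 − q(θ))

with S segregating sites out of L surveyed and q = μ·E[T_total]; models are
ranked by AIC = 2k − 2 ln L. Times convert to years via the generation
time (defaults: μ = 7×10⁻⁹ per site per generation, g = 2 years).

## Worked example

Simulate a dataset under the ancient-divergence model at the package's
default study conditions (67 + 10 diploids, 766 SNPs, 16.3% missing
genotypes, divergence 16,396 generations ago), build the spectra, and fit
both models:

```python
from demog import (SampleConfig, simulate_dataset, sfs_2d, fit_model,
                   select_model, model1_spec, model2_spec, InferenceConfig,
                   implied_mutation_opportunity, convert_time, ScalingConfig)
from demog.pipeline import DEFAULT_MODEL1_TRUTH

spec = model1_spec()
model = spec.build(DEFAULT_MODEL1_TRUTH)
sample = SampleConfig(n1=67, n2=10, n_snps=766, missingness=0.163, seed=11)
G, popmap = simulate_dataset(model, sample)
obs = sfs_2d(G, popmap, ("pop1", "pop2"), seed=12)
obs.mutation_opportunity = implied_mutation_opportunity(
    model, sample, obs.n_sites, ScalingConfig().mu, seed=99)

cfg = InferenceConfig(n_starts=10, ecm_cycles=15, sims_per_eval=10_000, seed=1)
fit1 = fit_model(obs, spec, cfg)
print(round(fit1.params["TDIV"]), "generations =",
      round(convert_time(fit1.params["TDIV"], ScalingConfig())), "years")
```

Output from this exact run:

```
14247 generations = 28495 years
```

i.e. the fitted divergence time lands within ~13% of the generating value
(16,396 generations / 32,792 years) — inside the relative width that the
parametric bootstrap assigns to this quantity at 766 SNPs. Adding a
recent-introduction fit and comparing:

```python
fit2 = fit_model(obs, model2_spec(), InferenceConfig(
    n_starts=3, ecm_cycles=5, sims_per_eval=3_000, seed=2))
best, delta_aic = select_model([fit1, fit2])
print(best.model_name, delta_aic)
```

selects `model1` with ΔAIC ≈ 675 in favor of ancient divergence: at this SNP count, data simulated under an ancient split are
decisively incompatible with a two-century-old founding.

The same analyses run from the shell:

```bash
demog simulate --model model1 --n1 67 --n2 10 --snps 766 --missing 0.163 --seed 11 --out sim/
demog sfs sim/simulated.vcf sim/popmap.tsv --dim 2 --seed 12 --out sim/sfs2d.obs
demog fit --obs sim/sfs2d.obs --starts 10 --cycles 15 --sims 10000 --seed 1
demog run config.json          # whole pipeline from a JSON config
```

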