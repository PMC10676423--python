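# Methods

This package re-implements, as a tested pipeline, the population-genetic
analyses used to decide whether two small, disjunct populations of a
perennial herb (a Mt. Ibuki-like lineage and a central-Hokkaido-like
lineage of *Vicia sepium*) derive from an ancient natural split or from a
recent human-mediated introduction. The decision instrument is the joint
folded minor-allele site frequency spectrum (2D-mSFS) of the two samples,
compared under two explicit coalescent models by composite likelihood and
AIC, supported by a stairway-style effective-size trajectory, per-individual
heterozygosity, LD pruning, Evanno-style delta-K post-processing, and a
cpDNA haplotype network.

## Genotype data and spectra

Genotypes are diploid ALT-dosage codes {0, 1, 2, missing} over biallelic
SNPs read from VCF (multiallelic and non-SNP records are dropped; half
calls count as missing). Spectra are *folded* on the minor allele because
ancestral states are unknown: for n diploids the 1D classes are i = 0..n
minor chromosomes out of 2n (an exact 50/50 tie goes to class n); 2D cells
(i, j) are folded on the total minor allele, with ties resolved to the
lexicographically smaller orientation. The same conventions are applied to
observed and expected spectra, so the tie rule cancels in the likelihood.

Missing genotypes are compensated per site by bootstrap resampling within
the resampling unit (whole sample for the 1D spectrum, each population
separately for the 2D spectrum): missing chromosome slots are drawn with
replacement from the allele copies observed at that site, which is a
binomial draw on the observed allele frequency. One completed draw is made
per site (a single imputation); replicate seeds quantify imputation noise.
Sites that become monomorphic after filling stay in the zero class so that
class counts always sum to the number of retained sites; the likelihood
masks that class. Allele resampling (rather than genotype resampling) is
the minimal scheme consistent with per-site bootstrap compensation; it adds
binomial noise that slightly blurs the spectrum, identically for observed
data and for any refit of simulated data.

## Coalescent simulator

The generator is a standard continuous-time Kingman coalescent with
piecewise-constant diploid sizes: k lineages coalesce at rate C(k,2)/(2N)
per generation; at the divergence time TDIV all lineages of population 2
join population 1's ancestral pool. Migration is deliberately absent (the
two ranges are far apart). Epoch boundaries are honored by integrating the
rescaled time tau = int dt/(2N(t)) across epochs. Sizes are diploid Ne, so
"4 Ne mu" is the usual theta.

Expected spectra are computed from expected branch lengths: each lineage's
lifetime is accumulated into its descendant-class cell (i tips in pop 1, j
in pop 2), and the expected SFS is E[L_ij] / E[L_tot]. For independent
sites ascertained as polymorphic in the small-mutation-rate limit this
ratio is the exact per-site class law, and it removes the mutational
sampling noise of placing literal mutations (a Rao-Blackwellization). The
kernel is numba-compiled and consumes one Exp(1) draw plus one uniform per
event attempt, so the random stream stays aligned across nearby parameter
values — common random numbers make each fit's likelihood surface
deterministic. A direct consequence (and a property test): the expected
spectrum is *bit-identical* under the coalescent scale map
(N, T) -> (cN, cT) with the same seed.

Synthetic SNP datasets are generated consistently: genealogies are drawn
into an importance pool and sampled proportionally to total branch length
(a genealogy carrying a segregating site is length-biased), one mutation is
placed uniformly on the branches, chromosomes are paired randomly into
diploids, and genotypes are masked i.i.d. at the configured missingness
rate (a Beta-distributed per-site rate is available to mimic the
locus-clustered missingness of reduced-representation assays, off by
default). A naive one-genealogy-one-mutation scheme would sample
E[L_c/L_tot], a subtly different law; the pool makes data and expectation
agree, which the chi-squared test on the 1/i law verifies.

Default study conditions (the generator's defaults throughout tests and
the acceptance script): samples of 67 and 10 diploids, 766 SNPs, 16.3%
missing genotypes (an 83.7% genotyping rate), mutation rate 7e-9 per site
per generation, two years per generation.

## Identifiability and the segregating-sites term

Folded SFS *proportions* are exactly invariant under (N, T) -> (cN, cT),
so a spectrum of fixed SNP count cannot identify absolute sizes or times.
The absolute scale enters through the mutation rate: if L sites were
surveyed to yield S SNPs, then S ~ Binomial(L, q) with q = mu E[T_total],
and the likelihood gains the term S ln q + (L - S) ln(1 - q). For real
data L is the assay's surveyed-site count; for synthetic panels the
generator reports the implied opportunity L = S / (mu E[T_total]) at the
generating model. Without L the fitter still runs but warns that only the
parameter *shape* is identified. The stairway estimator uses the same term,
which also makes its epoch-ladder anchor (the Watterson-equivalent size) a
fixpoint, so no iterative grid update is needed.

## Divergence models

* **Model 1 — ancient divergence** (8 parameters): the lineages split at
  TDIV in [5,000, 100,000] generations (i.e. no later than 10^4 years ago
  at g = 2). Each extant lineage carries one size change — a recent crash
  in the Mt. Ibuki-like lineage, a mid-Holocene decline in the
  Hokkaido-like lineage — and the ancestral size is constant. The epoch
  structure is fixed; magnitudes and times are free.
* **Model 2 — recent introduction** (6 parameters): population 2 is
  founded from population 1's lineage at TDIV in [2, 100] generations
  (within two centuries). Extant sizes are constant; the shared ancestral
  lineage carries one size change (the pre-crash size), because the old
  events predate this divergence.

Search ranges are log-uniform: sizes in [1e2, 2e5] diploids, times as
above, with ordering constraints (size-change times younger than TDIV)
enforced by constraint-aware bounds during optimization. Defaults are the
package's own choices of wide, biologically plausible ranges.

## Fitting, model choice, uncertainty

The objective is the multinomial composite log-likelihood over polymorphic
2D classes, sum_c m_c ln max(p_c, 1e-10), plus the segregating-sites term.
"ECM" is realized as cyclic conditional maximization: bounded 1-D Brent
steps in log-parameter space, cycled over parameters, from random
log-uniform starts, each start with its own fixed simulation seed. Because
per-start surfaces are noisy at finite simulation counts, all start
endpoints are re-scored under one common seed at a higher simulation count
(default 4x) before choosing a winner — comparing starts on their own seeds
systematically favors lucky seeds — and the winner is polished for a few
extra cycles at that precision. Cycling stops early when a full cycle gains
less than cycle_tol (default 0.01 log-units).

Models are compared by AIC = 2k - 2 lnL; both fits share the same data
terms, so the segregating-sites term cancels from delta-AIC only insofar
as both models fit the scale equally — which is part of the comparison.
Confidence intervals are a parametric bootstrap: spectra are re-simulated
at the MLE (with the replicate SNP count redrawn from Binomial(L, q_MLE),
so scale uncertainty propagates), refit from the MLE start with a reduced
cycle count, and summarized by 2.5/97.5 percentiles. Full-scale effort
defaults (50 starts, 40 cycles, 1e5 simulations per evaluation, 100
bootstrap replicates at 15 cycles) are configured down to desk scale in
tests (documented per test); the acceptance runs use 10 starts, 15 cycles
and 1e4 simulations per evaluation for the primary fit.

## Stairway-style trajectory

The deterministic expected SFS under piecewise-constant Ne combines the
pure-death lineage chain with the classical subtending-probability
weights: E[T_k] is obtained per epoch from the bidiagonal chain generator
via matrix exponentials and their integrals (v Q^{-1}(e^{Q dtau} - I)),
which is numerically stable at sample sizes where the alternating-sum
eigenexpansion is not (the evaluator caps at 400 chromosomes); then
E[L_i] = sum_k k E[T_k] C(n-i-1, k-2)/C(n-1, k-1), folded and normalized.
Constant size reproduces the folded 1/i + 1/(2n-i) law to machine
precision, and the evaluator agrees with the Monte Carlo kernel within
Monte Carlo error (a cross-implementation oracle in the tests).

The fitter controls overfitting the way stairway-type estimators do, in a
compact form: per multinomial bootstrap replicate of the SFS, sites are
split 67/33 into training and testing; per-epoch log-sizes are maximized
(L-BFGS-B) on the training spectrum for each candidate breakpoint count on
a geometric time ladder (0.002–0.5 of 4 Ne_Watterson); the breakpoint
count with the best held-out likelihood wins, ties keeping fewer epochs;
the winner is refit on the full replicate. The trajectory is summarized by
pointwise median and 2.5/97.5 bands across replicates on a common log time
grid, in generations and years. Epochs straddling a true size change can
show inflated upper bands (a known stairway artifact); the median curve is
the estimator.

## Haplotype network

cpDNA sequences are collapsed to haplotypes after masking every alignment
column containing N or a gap (gaps are not a fifth state). The network is
a minimum spanning network on Hamming distances: distances are processed in
increasing order, and every minimal edge joining two components that were
distinct *before* that distance level is kept, so equal-length alternative
connections survive (a network, not a tree); edges of d > 1 steps pass
through d - 1 inferred "missing" haplotypes. The classical 95%
statistical-parsimony connection limit is replaced by an optional integer
step limit (default unlimited), which is sufficient at the scale of a
three-haplotype cpDNA panel; the probability calculation of
statistical-parsimony cladogram estimation is out of scope.

## Supporting statistics

* Heterozygosity: per individual, the proportion of called sites with
  dosage 1; individuals with no called site are NaN, never 0. Invariant to
  REF/ALT relabeling.
* LD pruning: r2 is the squared Pearson correlation of dosages over
  pairwise-complete individuals (the PLINK convention for unphased data);
  pairs with r2 > 0.6 lose the lower-genotyping-rate site (ties remove the
  later site), iterated to a fixpoint. Undefined r2 (monomorphic overlap)
  never removes a site. Because r2 is a static pairwise property, the
  greedy scan is order-deterministic and matches an independent
  remove-one-restart reference pruner.
* delta-K: mean over replicates of |L(K+1) - 2L(K) + L(K-1)| divided by
  the replicate standard deviation of L(K); undefined (with a warning)
  when that deviation is zero. Only the external clustering tool's
  log-likelihoods are consumed; the clustering model itself is out of
  scope, as is CV error.

## What the generator does and does not emulate

The generator reproduces the study conditions that matter to the methods:
sample sizes, SNP counts, genotyping rates, the divergence demographies,
and a cpDNA panel with a fixed haplotype multiset. It does not emulate
linked SNPs within a sequencing locus (all sites are exchangeable and
unlinked, matching the composite-likelihood assumption), locus-clustered
missingness (available but off by default), genotyping error, or selection.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions at desk scale, not robustness to assay artifacts.

## Numerical choices and limitations

* Probability floor 1e-10 per expected cell; probabilities renormalized
  over polymorphic classes after masking.
* Brent steps use xatol 0.01 in log space and a bounded iteration count;
  coordinate ascent on strongly correlated ridges (TDIV against sizes) is
  slow, which the endpoint re-scoring and polish mitigate but do not
  eliminate — divergence-time point estimates at desk-scale effort carry
  roughly the same relative uncertainty as the parametric CI.
* Monte Carlo expected spectra make the likelihood stochastic across
  fits (not within one: common random numbers); reported log-likelihoods
  from different runs agree only to a few units.
* The stairway ladder anchors on the Watterson-equivalent size; events
  much more recent than 0.002 x 4 Ne or older than the TMRCA scale are
  outside the estimator's resolution.
* Absolute sizes and times require the mutation opportunity L; without
  it, only trajectory/parameter shape is meaningful.
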