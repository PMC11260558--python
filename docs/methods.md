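# Methods

This note documents the models behind each module, the parameters that
matter, the synthetic-data generator's assumptions, and the numerical
choices made where the design was genuinely open.

## Genotype container and filtering (`vcfio`)

Genotypes are alternate-allele copy counts (0/1/2, −1 missing) for
biallelic SNPs only; multiallelic and non-SNP VCF records are skipped with
a logged count. Coordinates are 1-based, matching VCF.

Filtering presets bundle the thresholds used at different pipeline stages:
`hybrid` (MAF ≥ 0.03, locus missingness ≤ 0.5), `pca` (≤ 0.25), `sauger`
(≤ 0.25, applied after removing hybrids/walleye), and `demography` (no MAF
filter, sex loci retained, missingness ≤ 0.7 — frequency filters distort
the SFS, so the demographic dataset keeps rare variants). MAF and
missingness criteria are both evaluated on the input matrix and failing
loci dropped at once, so the result is order-independent and idempotent.
Individuals at or above 80% missing data are dropped by default; the
threshold is exposed because reasonable analyses also use 0.7.

## Ancestry estimation (`ancestry`)

The estimator targets the hybrid index q and interspecific ancestry Q of
the two-cluster admixture model. Per individual, each locus has a latent
ancestry state z ∈ {AA, AB, BB}; genotype likelihoods given z are
Hardy–Weinberg draws from the two parental allele-frequency pools (state
AB draws one allele from each). EM over the genome-wide state proportions
π converges when the log-likelihood gain drops below 1e−8 (≤ 500
iterations); the log-likelihood is non-decreasing by construction and this
is asserted in tests.

Design choices:

* Parental allele frequencies are estimated from reference panels with
  additive smoothing (0.5 per allele) and held **fixed** during EM, so
  hybrid query individuals cannot drag the parental frequencies.
* A full hierarchical Bayesian treatment (joint estimation with genotype
  uncertainty, MCMC credible intervals) would lower estimator variance at
  low coverage; the EM estimator targets the same (q, Q) estimands and is
  deterministic and fast. Percentile bootstrap over loci (B ≥ 100)
  substitutes for credible intervals.
* Classification thresholds are closed intervals ("between 0.4 and 0.6"
  includes the endpoints); the pure cutoffs are strict (q < 0.1, q > 0.9).
  Sub-rules are applied in the fixed order F1 → F2 → BC_sauger →
  BC_walleye; hybrids matching no sub-rule are `hybrid_unassigned` (the
  q–Q triangle is larger than the union of the named regions).

## Sex-linked locus screen (`sexscan`)

A PCA of the mean-imputed, centred genotype matrix retains by default the
smallest number of PCs explaining ≥ 90% of variance, capped at n/3 (the
cap guards against the discriminant overfitting noise axes). A linear
discriminant of sex on the PC scores is back-projected into locus space;
squared normalised coefficients are the loadings (non-negative, sum to 1,
invariant to which sex is labelled first). Loci at or above the 0.99
loading quantile are flagged (ties included). A complementary
label-randomization threshold — the 95th percentile of the maximum loading
over B = 100 permutations — bounds the loading magnitude expected with no
true sex linkage; the quantile rule decides removal, the randomization
threshold calibrates false positives.

## Population statistics (`popstats`)

* **Reich–Patterson F_ST** is the allele-count estimator combined as a
  ratio of sums, unbiased for small and unequal sample sizes; loci with
  fewer than two called chromosomes in either population are skipped. The
  bootstrap resamples loci (B = 1000 default) and reports the 95%
  percentile interval; significance = interval excludes zero. The locus
  bootstrap assumes loci are quasi-independent; on strongly linked data it
  understates the genealogical variance.
* **PCA** eigendecomposes the individual × individual covariance of
  mean-imputed centred genotypes (deterministic full SVD).
* **Diversity** per site requires an explicit `total_sites` denominator
  (variant + invariant), since per-site θ_W and π are meaningless from
  variant counts alone: θ_W = S / (H_{n−1} · total_sites) with n the
  rounded mean called chromosomes, π sums per-site heterozygosity
  2p(1−p)·n/(n−1). Observed heterozygosity is computed per individual then
  averaged; expected heterozygosity (mean 2p(1−p) over segregating loci)
  is reported alongside because the two differ by orders of magnitude when
  the denominator includes invariant sites.
* **River distance** attaches sites to an edge list at offsets and takes
  along-network shortest paths (Dijkstra); **isolation by distance** uses
  F_ST/(1−F_ST), a one-sided Mantel test (999 permutations by default;
  exact enumeration for small n), and a least-squares slope. Pairs with
  F_ST = 1 give an infinite response and are excluded with a warning.

## Demographic inference (`demography`)

### Expected joint SFS

The isolation model (`split_nomig`) is computed on a discrete
Wright–Fisher grid of `grid_diploids` diploids (default 100):

1. Ancestral standing variation per unit θ = 4 N_ref μ L uses the
   diffusion-equilibrium density: weight 1/a on derived count a of the 2N
   grid chromosomes.
2. The split's first generation is a binomial founding draw at the
   daughter size ⌊ν·2N⌉ (the behaviour of a discrete-time WF split);
   subsequent generations apply the exact binomial transition matrix.
   T is measured in units of 2 N_ref generations, so g = T·2N transitions.
3. New mutations enter each daughter at count 1 at rate ν/2 per unit θ per
   generation and drift for the remaining generations; they populate the
   (k, 0) and (0, k) margins, including differential fixation at (n1, 0)
   and (0, n2).
4. Sampling to (n1, n2) is hypergeometric (without replacement), which
   reproduces the equilibrium sample spectrum θ/k exactly; fractional
   generation counts and fractional daughter sizes are handled by linear
   interpolation (in the sample domain), keeping the likelihood surface
   smooth in all parameters.

The migration model (`split_mig`) propagates the full joint
frequency-pair distribution with deterministic migration mixing (fraction
m = M/(2N_ref) of a population's gene pool drawn from the other each
generation) followed by binomial drift, on a coarse grid (default 30
diploids) — accurate enough for the nested LRT, and documented as an
approximation. At M = 0 it reproduces the isolation backend to machine
precision (asserted in tests). An independent oracle — msprime
discrete-time WF simulation — is compared cell-wise against the matrix
backend in the test suite, using the empirical across-replicate Monte
Carlo error (within-replicate sites share genealogies, so Poisson errors
would be understated).

Two grid-resolution caveats: at T = 0 the two samples are drawn
independently rather than jointly, which depresses shared-singleton
expectations by O(n/2N); and masked corners absorb fixed/absent classes
that a variant-only dataset cannot observe.

### Fitting, LRT, scaling

The Poisson composite log-likelihood over unmasked cells profiles θ
analytically (θ̂ = Σobs/ΣM). Optimization is COBYLA (derivative-free,
honouring ν₁+ν₂ ≤ 1 and box bounds) from `n_restarts` random starts
(default 26), with an optional tight polish pass from the best restart;
restarts more than 10 log-likelihood units below the best are flagged as
probable local optima. When fitting the migration model for a nested LRT,
the isolation optimum (with M = 0) is supplied as an extra start and kept
as a candidate, guaranteeing a non-negative LRT statistic up to numerical
noise. The LRT uses χ² with df = 2 at α = 0.05; because the null pins the
migration rates to the boundary of the parameter space, the test is
conservative (empirical type-I well below nominal, verified on 100
parametric null simulations).

Real-time scaling: N_ref = θ̂/(4μL) with the effective length
L = total_sites × (SNPs retained / SNPs before filtering);
T_generations = T × 2 N_ref; T_years = T_generations × 3 (configurable
generation time). Mutation-rate defaults span published estimates:
2.5e−8 (human), 3.5e−9 (cichlid), 2e−9 (Atlantic herring), 5.97e−9
(across-fish average). Uncertainty comes from a 1-Mb block bootstrap of
the SFS (100 replicates by default) rather than an information-matrix
approximation.

## Synthetic data (`simdata`)

The generator emulates the statistical structure the pipeline assumes, with
defaults chosen to be GBS-realistic:

* **Parental pools**: shared ancestral frequency ~ U(0.05, 0.95), then
  independent Balding–Nichols draws with differentiation d (default study
  condition d = 0.3 — strong but incomplete divergence, so ancestry
  assignment is non-trivial); 5% of loci diagnostic by default. No
  published estimate of genome-wide sauger–walleye allele-frequency
  divergence exists, so d is a testability choice, not a measured value.
* **Crosses**: per-locus ancestry states drawn from the class distribution
  (F1: AB everywhere; F2: 1/4, 1/2, 1/4; BC: 1/2, 1/2), then alleles from
  the corresponding pool; realized per-individual (q, Q) recorded as truth.
* **Missingness**: missing-completely-at-random at a per-locus rate
  (default 0.2, matching GBS-like median locus missingness).
* **Sex block**: planted loci whose allele frequencies differ between the
  sexes by `effect` (0.5 ± effect/2), on one chromosome.
* **Split and river**: msprime coalescent simulations (population split
  with size constraint; linear stepping-stone demes with adjacent
  migration and a distance matrix proportional to deme spacing).

What the generator does **not** emulate: linkage disequilibrium within the
cross simulator (loci independent given ancestry state), genotype
uncertainty/allelic dropout, selection, missingness correlated with
genotype, and recombination maps. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling models, not
robustness to those real-data complications.

## Problem sizes used in tests and the acceptance script

Ancestry recovery: 50 replicates × 6 classes at 5000 loci, d = 0.3, 20
reference individuals per panel. F_ST calibration: 100 panmictic
replicates (40 individuals × 300 loci, B = 150). Demography: self-fit at
n1 = n2 = 20 on a 100-diploid grid; backend agreement at 400 msprime
replicates of 10 kb; LRT calibration on 100 Poisson null spectra
(n1 = n2 = 10, 30-diploid grid, θ·M ≈ 800 per-cell scale). Sex screen: 80
planted loci of effect 0.8 among 8000 loci, 150 individuals. These sizes
were chosen as the smallest at which the statistical targets are stable.

## Known limitations

* The EM ancestry estimator ignores genotype uncertainty; very low-coverage
  data should be pre-filtered or handled upstream.
* The migration-model grid is coarse; absolute migration-rate estimates
  from it are approximate even though the nested test is calibrated.
* Per-site diversity values depend entirely on the user-supplied
  `total_sites`; comparing across datasets requires a consistent
  invariant-site accounting.
* The locus bootstrap (F_ST, ancestry CIs) assumes exchangeable,
  quasi-independent loci.
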