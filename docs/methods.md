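# Methods

`palmgs` implements a genomic-selection workflow for multi-family half-sib
breeding populations: simulation of such populations, pairwise relatedness,
genomic heritability, five whole-genome regression models with k-fold
cross-validation, and two marker-density-reduction strategies.  This note
records the models, the numerical choices, and the limits of what the
synthetic experiments can show.

## The additive marker model

All prediction machinery rests on the linear model

    y = 1 mu + M u + e,    e ~ N(0, I sigma2_e),

where `M` is the n x m matrix of additive dosages (0/1/2 copies of the
counted allele) and `u` the vector of per-marker allelic substitution
effects.  An individual's genomic estimated breeding value (GEBV) is
`mu + m_i' u`.  The five fitted models differ only in the prior on `u`:

| method | prior on u_j | fitting |
|---|---|---|
| RR-BLUP | N(0, sigma2_u), common variance | REML + BLUP, closed form |
| BRR | N(0, sigma2_u), common variance | Gibbs |
| Bayes A | N(0, sigma2_j), scaled-inv-chi2 per marker | Gibbs |
| Bayes Cpi | 0 w.p. pi, else N(0, sigma2_u); pi ~ Beta(1,1) | Gibbs |
| Bayesian lasso | double exponential (Park–Casella scale mixture) | Gibbs |

Dosage columns are centered before fitting (required for the ridge/GBLUP
equivalence); the reported intercept is translated back to the raw-dosage
scale so `GEBV = intercept + G @ marker_effects` holds verbatim for 0/1/2
dosages, including the degenerate all-zero row.

### RR-BLUP / REML

Variance components are estimated by restricted maximum likelihood profiled
to a one-dimensional search over delta = sigma2_e/sigma2_u on the
eigenspectrum of the centered marker cross-product.  Two numerical details
matter:

* Only clearly positive eigenvalues (relative tolerance 1e-9) enter the
  rotated spectrum; the null-space mass is folded in analytically as
  `y'Py - sum(eta^2)`.  Naively keeping the n - p "largest" eigenpairs is
  wrong for rank-deficient relationship matrices because the numerical
  null-space basis mixes the fixed-effect span with residual directions.
* The search runs on log(delta) in [-23, 28] with a bounded scalar
  minimizer at tolerance 1e-8.  The m x m cross-product route is used when
  m < n, the n x n kernel route otherwise.

Marker effects are then `u = (Mc'Mc + delta I)^-1 Mc' (y - ybar)`
(equivalently `sigma2_u Mc' V^-1 (y - ybar)`), and a fixed `lambda_`
argument bypasses REML for oracle comparisons.

### Gibbs samplers

All four Bayesian models share one sweep structure (intercept, each marker
effect with its residual update, variance components) compiled with numba;
chains default to 20,000 iterations with 2,500 burn-in and no thinning, and
posterior means/SDs are accumulated online.  Hyperpriors: residual and
marker-variance scales are set so the prior *mode* matches a 50/50 split of
the phenotypic variance, with 5 degrees of freedom (the convention of the
reference implementations of this model family); Bayes Cpi uses a Beta(1,1)
prior on the exclusion probability pi with the slab scale adjusted by the
expected inclusion fraction; the Bayesian lasso samples 1/tau_j^2 from an
inverse-Gaussian full conditional, lambda^2 from a gamma full conditional
(prior shape 0.55, rate 1e-4; lambda initialized at 25), and includes the
`u'D^-1 u` term in the residual-variance update as the full hierarchy
requires.  Convergence is summarized by the effective sample size of the
sigma2_e chain (initial-positive-sequence estimator).  A non-finite
residual variance aborts the chain with an error naming the failure.

## Relatedness (Lynch & Li)

For a biallelic locus the genotype-similarity score is 1 (identical), 0.75
(homozygote vs heterozygote sharing an allele) or 0 (opposite homozygotes);
its expectation under unrelatedness is `S0 = 2 a2 - a3` with
`a_k = p^k + q^k`.  Relatedness is the ratio of locus averages
`(S - S0)/(1 - S0)` — a ratio of means rather than a mean of ratios, which
stays stable when low-MAF loci push per-locus S0 toward 1.  Allele
frequencies come from the full analyzed sample, so estimates are relative to
that sample: half sibs center on ~0.25 and full sibs on ~0.5 *when the
sample contains many families*, and shrink when the sample is a single
family (the reference frequencies are then themselves family-biased).  The
protocol subsamples 15,000 SNPs at random and bootstraps loci (100
replicates) for per-pair standard errors; no inbreeding adjustment.

## Association scan and marker reduction

The scan is single-marker OLS (dosage + intercept, optional covariates)
with two-sided t-test p-values reported as -log10; it deliberately omits
mixed-model structure correction — it is a ranking device inside
cross-validation, not an inference tool, and the inclusive cutoff 1.3
(= -log10 0.05 rounded) only gates the descriptive heritability subset.
Ranking ties break by genome order for determinism.

RR-BLUP B refits RR-BLUP on growing top-k subsets of the ranking (default
+10 markers up to 20,000).  The scan runs on training individuals only,
independently per fold, so validation phenotypes can never influence the
ranking — an injection test (noising validation phenotypes) asserts the
rankings are bit-identical.  The optimal-density rule reads the accuracy at
100-marker windows and returns the last count before the next increment
falls below 0.05 (raw increments, no smoothing).

LD pruning walks the ranked list greedily, keeping a marker only if its
squared dosage correlation with every kept marker is < 0.6; the
best-ranked member of each LD group survives.  A cutoff >= 1.0 disables the
filter.  Markers monomorphic in the training subset cannot carry LD and are
kept.

## Genomic heritability

h2 = sigma2_g/(sigma2_g + sigma2_e) by REML under a VanRaden-style
relationship matrix (centered cross-products scaled by sum 2p(1-p); any
fixed positive scale leaves h2 invariant), clamped to [0, 1].  Estimates are
produced on the full marker panel and on the association-score subset; the
subset scan uses the full sample because heritability is descriptive, unlike
the per-fold scans used for prediction.  Traits with subset h2 >= 0.6 are
tagged "high", others "medium".

## Cross-validation and selection response

`make_cv_plan` draws a balanced random partition (fold sizes differ by at
most 1; 1,218 individuals in 5 folds give 975/243 training/validation
splits).  Accuracy is the Pearson correlation between GEBVs and observed
phenotypes of the validation fold — the estimand available on real
populations; the simulator additionally exposes true breeding values for
diagnostics.  Fold standard deviations (not standard errors) are reported.
Selection response is mean(top 25% by phenotype) - mean(all); a per-trait
`maximize` flag selects from the other tail for traits bred downward, in
which case the signed response is negative when selection gains ground.

## The synthetic-data generator

Founders are drawn in linkage equilibrium with allele frequencies uniform
on [0.05, 0.5]; a single generation of crossing creates the study
population: each family is one dam x sire cross, with a small pool of sires
(default 2) shared round-robin across families, so progeny are full sibs
within families and half sibs across families sharing a sire.  Gametes
recombine with Poisson crossover counts per chromosome (expectation = map
length, positions uniform, no interference).  Defaults emulate a desk-scale
commercial half-sib population: 40 families x 30 progeny (1,200
individuals), 16 chromosomes of 1 Morgan with 313 SNPs each (5,008
markers).  Traits place QTL on genotyped markers (perfect tagging) with
either Gaussian effects (polygenic preset: 600 QTL, h2 0.45) or a
geometric series 0.8^k with random signs (oligogenic preset: 8 QTL,
h2 0.7); Gaussian homoscedastic noise is scaled so the realized
heritability matches the target in expectation.  A target of exactly zero
produces a pure-noise phenotype with all effects zero.

What the generator does *not* emulate: ancestral (population-level) LD —
founders are unlinked, so all LD is family LD from one meiosis; real
populations carry longer-range ancestral haplotype structure.  It also
omits dominance and epistasis, genotyping error and missingness, selection
over breeding cycles, and real genome coordinates.  Passing tests therefore
demonstrate internal consistency and correct recovery under the stated
model, not performance on any particular real crop population.  Because two
shared sires dominate the relationship structure, the population mean
relatedness lands around 0.15–0.25 with range ~0 to ~0.6, approximating a
commercial half-sib population without claiming fidelity to any specific
pedigree.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run every experiment at reduced,
fixed sizes chosen so the whole battery completes on one CPU in minutes
while keeping each check's Monte-Carlo error well inside its tolerance:
oracle checks at 30x100 and 200x1000; sampler agreement at 300x1000 with
the full 20,000 iterations; heritability recovery at 500x2000 over 20
replicates per level; five-method cross-validation at 400x800; marker
reduction at 600x5000; LD-filter comparisons at 480x1000 averaged over
three replicate populations (the reach-the-plateau count is a noisy
order statistic for a single population); kinship calibration at the full
15,000-SNP protocol.  The full-scale configuration (1,218 x 92,057) is
expressible through `SimConfig` but reserved for scaled runs.

## Known limitations

* The association scan is plain OLS; in strongly structured samples the
  score distribution is inflated relative to its nominal null, which is
  acceptable for ranking but not for significance claims.
* The Bayesian lasso's effective shrinkage depends on the lambda prior;
  with very small m the posterior for lambda is prior-dominated.
* `optimal_density` applies the threshold to raw window increments; a noisy
  curve can trigger early.  Use more folds or wider windows for smoother
  curves.
* Bootstrap kinship SDs resample loci only; they do not propagate
  uncertainty in the sample allele frequencies.
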