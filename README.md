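# palmgs

Genomic selection tooling for commercial breeding populations composed of
multi-family half sibs — the structure of a typical oil-palm (or similar
perennial crop) progeny trial, where a few elite pollen parents are crossed
onto many seed parents and thousands of progeny are genotyped on a dense SNP
array.

The package answers three questions breeders ask of such data:

1. **How heritable and predictable is each trait?**  Genomic heritability
   h² = σ²g/(σ²g + σ²e) by REML on a marker-based relationship matrix, and
   cross-validated prediction accuracy r(GEBV, phenotype) under five
   whole-genome regressions of the model y = 1μ + Mu + e: RR-BLUP (closed
   form), Bayes A, Bayes Cπ, Bayesian ridge and the Bayesian lasso (Gibbs
   samplers).
2. **How related is the population?**  Pairwise Lynch & Li allele-sharing
   relatedness r = (S − S₀)/(1 − S₀) with SNP subsampling and a locus
   bootstrap (half sibs ≈ 0.25, full sibs ≈ 0.5 on this scale).
3. **How few markers are enough?**  RR-BLUP B: rank markers by a
   training-only association scan, refit on growing top-k panels and read
   off the accuracy-vs-density curve and its optimal density (last count
   before gains per 100 markers drop below 0.05); optionally prune the
   ranked list by LD (r² < 0.6) so each haplotype block contributes one
   marker.

Since commercial phenotype/genotype data are proprietary, the package ships
a first-class simulator (`palmgs.simulate`) that generates half-sib
populations with recombination-generated LD and traits of oligogenic or
polygenic architecture at a target heritability, with full ground truth for
validation.

## Worked example

```python
from palmgs import (SimConfig, simulate_population, kinship_matrix,
                    genomic_heritability, make_cv_plan, run_cv, WGRConfig,
                    selection_response)

cfg = SimConfig(n_founders=22, n_families=20, progeny_per_family=25,
                n_chromosomes=4, markers_per_chromosome=250,
                n_qtl=8, qtl_effect_distribution="geometric-series",
                target_h2=0.7, seed=11)
G, traits, truth = simulate_population(cfg)
y = traits.values("trait", G.individual_ids)

kin = kinship_matrix(G, n_snps=1000, n_bootstrap=0, seed=1)
h2 = genomic_heritability(G, y)
plan = make_cv_plan(G.n_individuals, n_folds=5, seed=1)
res = run_cv(G, y, ["RRBLUP", "BC"], plan,
             config=WGRConfig(n_iter=4000, burn_in=1000, seed=1))
```

printed results:

```
population: 500 individuals x 1000 markers
realized h2: 0.739
kinship mean 0.08, range [-0.28, 0.84]
genomic heritability: 0.702
RRBLUP: accuracy 0.70 (0.04)
BC: accuracy 0.82 (0.02)
selection response (top 25%): 0.91 trait units
```

Reading it: the simulated trait's realized heritability (0.739) is recovered
by REML (0.702); 5-fold cross-validated accuracy is 0.70 for RR-BLUP, and
the spike-slab Bayes Cπ gains on this deliberately oligogenic trait (0.82,
fold SD in brackets) because 8 QTL carry the signal; truncation-selecting
the top quarter of the population shifts the mean by 0.91 trait units.

The same analyses are exposed as a CLI (`palmgs simulate | kinship | gwas |
herit | fit | cv | reduce-assoc | reduce-ld | pipeline`); `palmgs pipeline
--config study.yaml --out results/` runs the whole study end to end and
writes TSV/JSON tables, plots and a manifest with the resolved
configuration.

Model objects follow the model/results idiom:

```python
from palmgs import RRBLUP, BayesianWGR, WGRConfig
fit = RRBLUP(y, G).fit()               # -> WGRResults
print(fit.summary())
gebv = fit.predict(G_new)              # intercept + dosages @ effects
bc = BayesianWGR(y, G, method="BC").fit()
```

See `docs/methods.md` for the models, priors, numerical choices and the
simulator's scope.

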