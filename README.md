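# landgen

Landscape genetics of diploid microsatellite data: from genotypes and raster
landscape layers to differentiation statistics, Bayesian admixture
clustering, least-cost-path and circuit-theory effective distances, and
multivariate model selection over distance matrices.

## Who this is for

Population and landscape geneticists asking *which features of a landscape
shape gene flow*. The motivating system is a study of leaf-toed geckos
(*Phyllodactylus tuberculosus*) sampled at 12 sites in the tropical dry
forest near Alamos, Sonora — ~336 diploids, 10 microsatellite loci, moderate
differentiation — but every stage is generic: any Genepop file plus
co-registered ESRI ASCII grids and a site table will do. A synthetic-data
module generates landscapes and genotypes with the same statistical
structure, so the entire pipeline is testable without downloading anything.

## The methods at its core

- **Differentiation.** Weir & Cockerham's variance-components estimator
  θ (the multilocus F_ST), with permutation significance, and Jost's
  D_est from nearly unbiased H_S / H_T estimates, combined across loci by
  harmonic means. Diversity per site: H_O, unbiased H_E, allele counts and
  rarefied allelic richness A_g. Hardy–Weinberg exact tests run a Markov
  chain over genotype tables with fixed allele counts.
- **Clustering.** A Gibbs sampler for the admixture model (uncorrelated
  allele frequencies, Dirichlet priors, Metropolis update of α), model
  choice by ln Pr(X|K) ≈ mean(lnL) − var(lnL)/2 and by the ΔK second-order
  statistic, label alignment across runs, and individual-based barrier
  Mantel tests on shared-allele distances.
- **Effective distances.** Landscape layers reclassified to cost surfaces
  (categorical cost ratios 1:2 … 1:1000, or 32 equal-interval continuous
  classes); least-cost cumulative cost-distance by 8-neighbour Dijkstra;
  isolation-by-resistance distances by solving the landscape graph
  Laplacian, with optional cumulative current maps.
- **Model selection.** Distance matrices unfolded to pairwise vectors;
  Mantel tests and multiple regression on distance matrices (MRM) with
  response-matrix permutation; VIF collinearity screening; AICc, Akaike
  weights and the 95% confidence set; and maximum-likelihood population
  effects (MLPE) mixed models — a random intercept shared by pairs
  containing the same population — fitted by REML with R²_β and a
  likelihood-ratio test of the population effect.

## Worked example

Simulate the bundled stream-driven scenario (migration decays with the
effective resistance of the buffered stream network) and run the full
analysis:

```sh
landgen simulate --scenario stream-driven --seed 5 --out demo
landgen differentiate demo/genotypes.gen --out demo/diff.csv
```

which prints

```
wrote stream-driven dataset (250 individuals, 10 loci) to demo
global theta = 0.1025, global D_est = 0.3739
```

Global θ ≈ 0.10 and D_est ≈ 0.37 say the twelve demes are moderately
differentiated — a fixation index of this size means roughly 10% of allelic
variance lies among demes, the regime where landscape effects on gene flow
are detectable but not trivially so. `demo/diff.csv` holds the dual-triangle
table (D_est above the diagonal, θ below). The full pipeline — diversity,
differentiation, cost-ratio optimization, least-cost and circuit distances,
MRM + AICc + MLPE — runs from one YAML config:

```python
from landgen.pipeline import RunConfig, run
report = run(RunConfig(out_dir="demo_report", scenario="stream-driven",
                       seed=5, n_perm=999))
print(report.model_tables["mrm"][["R2", "AICc", "dAICc", "weight"]].head(3))
```

```
                        R2        AICc      dAICc    weight
model
euclidean+stream  0.239058  116.229727   0.000000  0.953266
stream            0.134731  122.513041   6.283313  0.041192
euclidean+forest  0.084500  128.434071  12.204344  0.002133
```

The model combining Euclidean distance with stream-network connectivity
carries essentially all Akaike weight — the pipeline recovers the process
that generated the data.

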