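# Methods

This note records the statistical models landgen implements, the estimators
and numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the field's
conventions leave room.

## Data model and formats

Genotypes are diploid, unordered allele pairs (microsatellite repeat sizes)
per individual × locus, with one population label per individual; a call is
either fully typed or fully missing, and missingness is handled pairwise per
locus, so per-site sample sizes are fractional when averaged over loci.
Rasters follow the ESRI ASCII convention: row 0 is the northernmost row,
coordinates refer to cell centers, points map to cells by floor division,
NODATA cells are non-traversable. Genepop files are written in the 3-digit
dialect (missing = `000000`); 2-digit files are accepted on read, and the
anonymous `POP` blocks adopt site-table names in file order when counts
match. Pairwise matrices must be symmetric to 1e-12; the CSV reader mirrors
a single filled triangle and rejects asymmetry beyond 1e-9.

## Diversity and differentiation

**Heterozygosity.** H_O is the observed heterozygote fraction among typed
individuals; H_E is Nei's unbiased gene diversity, (2n/(2n−1))(1 − Σp²) with
n typed diploids at the locus; site values average over loci.

**Allelic richness.** Rarefaction to a standard sample of g genes:
A_g = Σ_alleles [1 − C(N−N_a, g)/C(N, g)], evaluated as an exact product so
no factorials overflow; g defaults to twice the smallest population sample.
When a population has fewer than g typed genes at a locus, that locus is
rarefied at the smaller of g and the locus-wide minimum, and flagged.

**Hardy–Weinberg exact test.** The test conditions on allele counts and
walks a Markov chain over genotype tables. The chain state is the pairing of
the 2n gene copies; a step proposes swapping two gene copies between
genotypes. Because any transposition of slots is a bijection on pairings,
the chain's stationary law is uniform over pairings — exactly the
conditional distribution of tables under random union of gametes — so no
acceptance ratio is needed. The p-value is the chain frequency of tables
whose conditional probability (∝ 2^h / Π n_ij!) does not exceed the observed
table's, reported with a standard error from batch means (default 100
batches × 1000 iterations after a 1000-step burn-in). On all two-allele
tables the chain agrees with complete enumeration within three batch
standard errors (tested), and its null rejection rate at α = 0.05 is
calibrated within [0.03, 0.07].

**Linkage disequilibrium.** A log-likelihood-ratio G statistic on the
two-locus genotype contingency table per population; the null permutes one
locus's genotypes among individuals within the population; populations are
combined by Fisher's method.

**Weir–Cockerham θ.** Per locus and allele, the a (among populations),
b (among individuals within populations) and c (within individuals)
variance components with unequal sample sizes and observed heterozygote
frequencies; the multilocus estimator is Σa / Σ(a+b+c) over loci and
alleles. A locus monomorphic across the analysed subset contributes zero
components. Significance permutes individuals among populations (between
the two members only, for a pairwise value), with the +1 permutation
correction throughout. The implementation is verified to 1e-12 against an
independent mean-squares (nested ANOVA) evaluation of the same estimator.

**Jost's D.** Per locus, H_S and H_T with small-sample corrections
(H_S scaled by 2ñ/(2ñ−1), ñ the harmonic mean of typed diploids;
H_T corrected by H_S/(2ñk)), then D = (k/(k−1))(H_T−H_S)/(1−H_S).
Loci are combined by the harmonic mean, which is undefined at zero:
nonpositive per-locus values are floored at 1e-6 and flagged. The floor
makes near-undifferentiated pairs report D ≈ 0, matching how such pairs
print as 0.000 in published tables, at the cost of a strongly nonlinear
response near zero.

**Multiple testing.** Benjamini–Hochberg step-up (via scipy) or Bonferroni;
with α = 0.05 over the 66 pairwise tests of a 12-site design the Bonferroni
threshold is 0.000758.

## Admixture clustering

The implemented model is the admixture model with uncorrelated allele
frequencies: cluster frequencies have Dirichlet(1) priors, individual
admixture vectors Dirichlet(α), and every gene copy carries a latent cluster
assignment. One Gibbs sweep updates assignments, frequencies and admixture,
then a Metropolis step on log α (proposal SD 0.3, prior Uniform(0, 10),
Jacobian included). The correlated-frequencies F-model is out of scope; on
separable data the uncorrelated model recovers the clusters, which is what
the tests require. Model evidence is estimated by the penalized mean
ln Pr(X|K) ≈ mean(lnL) − var(lnL)/2; at K = 1 this matches the closed-form
multinomial-Dirichlet evidence within about 5% (the estimator is a normal
approximation, not unbiased). ΔK is the mean absolute second difference of
ln Pr(X|K) divided by the replicate SD, defined for interior K and flagged
infinite at zero SD.

Cluster labels are aligned across runs by minimizing the Frobenius distance
between admixture matrices over label permutations. That minimization is a
linear assignment problem, so it is solved exactly for every K with the
Hungarian algorithm (verified against brute-force enumeration); no greedy
fallback is needed. Alignment is a simplified substitute for the full
CLUMPP-style multi-start search.

Barrier tests correlate an individual genetic distance — 1 − proportion of
shared alleles averaged over co-typed loci, counting shared copies so a
heterozygote pair can share 0, 0.5 or 1 — with a binary same-side/
opposite-side matrix, permuting individuals. The shared-allele metric was an
open choice; it is the most common individual-level distance for
microsatellites and requires no frequency estimation.

## Effective distances

Cost surfaces come from categorical reclassification (favoured classes at
the low cost, everything else at the high cost; ratios 1:2, 1:10, 1:100,
1:1000 are the conventional grid) or equal-interval continuous
reclassification of the observed range into 32 classes mapped to costs
1..32, inverted for layers where high values mean easy movement
(temperature). Costs start at 1, not 0: a zero cost breaks shortest-path
positivity, and an additive offset changes least-cost geometry only by a
constant per step. Binning uses the observed raster range, matching GIS
reclassify defaults.

Both engines share one landscape graph: nodes are finite cells, edges join
8-neighbours, and an edge's base cost is the arithmetic mean of its two cell
values, scaled by √2 on diagonals. Least-cost distances multiply by the cell
size and run Dijkstra (scipy's sparse implementation; with a fixed CSR
layout the result and predecessor tree are deterministic, which serves the
reproducible-tie-break requirement); the geometric path length is
accumulated from the predecessor tree. Circuit distances use edge
conductance 1/(mean resistance), no cell-size factor, ground one focal node,
factorize the reduced Laplacian once (sparse LU restricted to the ground's
connected component) and solve one system per focal site;
R(s,t) = G_ss + G_tt − 2G_st. Pairs in different components are flagged
infinite. Current maps sum |edge current|/2 into each endpoint over all
focal pairs with unit injection. Points snap to the nearest traversable cell
center with the offset logged. Cost-ratio selection computes the chosen
effective distance per ratio and returns the ratio with the highest Mantel
r against the genetic matrix.

Verified invariants: agreement with a dense Laplacian-pseudoinverse oracle
to 1e-8 (the oracle uses the hermitian eigendecomposition path — the
generic SVD route of `np.linalg.pinv` returns corrupted results for some
30-node Laplacians on this LAPACK build); exact series/parallel closed
forms; least-cost equality with exhaustive branch-and-bound path
enumeration on grids up to 5×5; Rayleigh monotonicity; linear scaling in
the costs; and resistance ≤ least-cost cost with equality on 1-D chains.

## Distance-matrix statistics

Matrices are unfolded to the lower triangle in row-major order (66 values
for 12 sites). Mantel tests permute rows and columns of the second matrix
simultaneously, one-tailed upper, +1 correction; an exact mode enumerates
all n! permutations for small n. MRM is OLS on the unfolded vectors with the
same permutation scheme applied to the response matrix only; the overall
test uses R², per-coefficient tests are two-tailed on |β| (the convention
chosen where one- vs two-tailed was unstated). With one predictor,
R² = (Mantel r)² to machine precision (tested). VIF_j = 1/(1−R²_j) from
regressing predictor j on the rest.

AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) with n the number of pairs and
k the intercept plus slopes; Akaike weights are normalized exp(−Δ/2); the
95% confidence set is filled in descending weight order until the
cumulative weight reaches 0.95. Using n = 66 non-independent pairs is the
procedure's known weakness, which is why the MLPE stage exists.

MLPE: y = Xβ + Zu + ε on unfolded distances, Z the 66×12 pair-to-population
incidence matrix (two unit entries per row), u ~ N(0, σ²_u I),
ε ~ N(0, σ²_ε I), predictors mean-centered (enforced). REML profiles the
variance ratio φ = σ²_u/σ²_ε by bounded scalar minimization on [0, 1000]
(xatol 1e-10), with an explicit boundary check at φ = 0; at φ = 0 the GLS
solution reproduces OLS to machine precision. Wald t tests use residual
degrees of freedom n − rank(X), and R²_β = qF/(qF + ν) from the Wald F of
the non-intercept effects — a simpler small-sample treatment than the
Kenward–Roger adjustment, flagged here as the package's choice. The
population-effect p-value is a likelihood-ratio test against φ = 0 with the
0.5·χ²₁ boundary mixture. The fit agrees with an independent
variance-components mixed-model implementation (statsmodels) on simulated
data (tested) and recovers (σ²_u, σ²_ε) within 50% median relative error at
n = 66.

## Synthetic data

The generator produces what the analysis assumes, at the study's scale:
12 demes, samples of 10–42 diploids, 10 loci, moderate differentiation.

**Landscape.** One grid (default 40×40 cells of 250 m) carries: an
elevation field (smoothed Gaussian noise plus a planar trend, scaled to
100–500 m), slope (gradient magnitude), forest cover (an
elevation-correlated autocorrelated field thresholded at the requested
fraction), a stream network (steepest-descent flow accumulation over
elevation, thresholded at its 92nd percentile — a dendritic spanning forest
over low ground), a human-influence field (Gaussian kernels around random
settlements scaled to 0–64) and minimum temperature (lapse-rate decrease
with elevation plus local noise). All layers are deterministic functions of
the scenario seed.

**Genotypes.** Forward Wright–Fisher on gene copies. An ancestral pool the
size of the whole metapopulation (12 × 100 diploids) is burned in for
10·N_e generations under stepwise mutation (±1 repeat, reflecting bounds
[5, 60]) so demes start from realistic standing variation; demes then evolve
for T generations (default 400; 600 in the stream scenario) of drift,
migration and mutation, and diploid samples are drawn without replacement.
Migration is the generative landscape signal: m_ij ∝ exp(−λ d_ij/median d)
with d the effective resistance on the generating cost surface, scaled so
mean per-deme immigration equals `migration_total` (default 0.05). Rows are
deliberately *not* normalized to equal totals — demes that are poorly
connected on the surface genuinely receive fewer immigrants and drift
apart faster, which is the isolation-by-resistance signal the analysis is
meant to detect; equalizing per-deme immigration was measured to destroy
most of it. The euclidean-only scenario decays migration with straight-line
distance (uniform-surface resistance saturates logarithmically in 2-D and
buries the gradient); the three-cluster scenario replaces decay with a
block migration matrix.

Defaults (μ = 1e-3 per copy per generation, N_e = 100, m̄ = 0.05, λ = 4–5)
were chosen so the default scenarios land on the study system's anchors —
global θ in 0.05–0.15, H_E roughly 0.45–0.85, global D_est near 0.1–0.3 —
and are fixed; the four named scenarios regenerate bit-identically from
(name, seed).

**What passing tests do not show.** The generator's demes are panmictic
Wright–Fisher islands with unlinked loci, no null alleles, no genotyping
error, no selection or sex-biased dispersal, and its landscape layers are
statistically but not geomorphologically realistic. Recovery results
therefore demonstrate that the pipeline detects the generating signal under
its own assumptions, not that any particular real landscape variable drives
gene flow. Correlated landscape features (streams, temperature and slope
all track elevation here, as in real terrain) mean the stream-recovery
benchmark succeeds in about 8 of 10 seeds rather than all — the residual
failures pick a correlated corridor variable, the same collinearity caveat
that applies to real least-cost analyses.

## Pipeline and problem sizes

The pipeline is a pure function of (inputs, config, master seed); per-stage
seeds expand from the master seed by a fixed counter scheme and every stage
logs its name, seed and wall time. Locus exclusion lists (e.g. dropping
loci with systematic heterozygote deficits) are config, not auto-detection.
Test and benchmark problem sizes are scaled to keep the whole suite fast:
permutation counts of 99–199 where the field default is 10 000 (the +1
correction keeps the attained level exact), clustering chains of a few
hundred sweeps on separable data, 500-replicate null calibrations, and the
fixed-seed recovery benchmark at 10 scenario replicates. All statistical
conclusions the tests assert are calibration bands, oracle agreements or
majority criteria robust at those sizes.
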