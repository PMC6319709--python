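# Methods

`qstkit` implements an adaptive-divergence analysis for a regionally
structured, predominantly selfing wetland plant sampled as open-pollinated
seed families and raised in a common garden under three nitrogen-addition
treatments (T0, T70, T150). This note records the models, the numerical
choices, and what the synthetic data can and cannot establish.

## Molecular statistics

**Gene diversity.** Per locus and population the unbiased estimator
`He = (2n / (2n - 1)) (1 - sum p_u^2)` with `n` genotyped diploids; the
population value is the mean over loci with data. A locus missing in every
individual of a population is excluded from that population's statistics;
half-missing genotypes are treated as fully missing.

**Differentiation.** The default estimator is the Weir–Cockerham theta:
per-locus, per-allele variance components a (among populations),
b (among individuals within populations) and c (within individuals), with the
multilocus value the ratio of summed components — never a mean of per-locus
ratios. Negative per-locus components stay in the sums; loci monomorphic
across the compared groups are dropped (they contribute only 0/0). A Nei
G_ST variant is available for sensitivity. Between-lineage differentiation
pools each lineage's individuals into one group by default; an AMOVA-style
hierarchical decomposition (groups / populations / allele copies) is
provided as `hierarchical_fst` because published between-group values do
not always state which convention was used. Small negative estimates are
reported as computed, and clipped to zero only where a downstream formula
requires a non-negative value (the neutral simulator).

**Ordination.** Individual distances use the squared codominant genotypic
scheme (0/1/2/3/4 per locus, equivalently half the squared Euclidean
distance between allele-count vectors), summed over shared loci. PCoA
applies Gower double-centering to -D²/2 and a full symmetric
eigendecomposition; negative eigenvalues are reported, not dropped, and axis
percentages are taken over the positive eigenvalue mass.

**Lineage assignment.** An individual (or a population, via its mean
Q-vector) is assigned to the cluster with the largest admixture proportion
when that proportion exceeds 0.7, otherwise labelled admixed. Q-vectors must
sum to 1 within 0.05, tolerating rounded published tables.

## Variance components and Q_ST

The core model is the Gaussian nested mixed model

    y = X b + u_pop + u_fam(pop) [+ u_fam x treat] + e

with independent random intercepts per term. Quantitative-trait
differentiation is `Q_ST = V_AP / (V_AP + 2 V_WP)` where `V_AP` is the
among-population and `V_WP` the seed-family (within-population) component.
When the family x treatment term is included (the default in the
across-treatment mode) its variance is *not* counted in `V_WP`; a switch
(`include_family_treatment`) exposes the alternative.

**Gibbs sampler.** Blocked conjugate updates: the fixed-effect block from
its conditional multivariate normal; each random-effect vector from
independent conditional normals; each variance from its conditional
inverse gamma. Priors are weakly informative inverse-gamma(0.001, 0.001) on
every variance — the conventional default of Bayesian mixed-model packages;
the analysis this emulates states no prior, so this is an explicit
assumption. Chain defaults are 13,000 iterations, 3,000 burn-in, thinning
10, retaining exactly 1000 draws — the conventional posterior sample size
for Q_ST work; every retained draw is mapped through the Q_ST ratio, so
draws lie in [0, 1] by construction, and the 95% interval is the
equal-tailed 2.5/97.5 percentile band of the draws (an HPD interval is not
used). Reduced chains (2,600 iterations / 600 burn-in, 200 draws) are used
in the test suite and acceptance script; with fully conjugate updates on
these designs mixing is fast and the doubled-burn-in checks showed no drift.

**REML path.** Restricted maximum likelihood via statsmodels `MixedLM`,
with the coarsest random term (lineage, else population) as the top
grouping and the remaining terms as variance components. It backs the
trait-response analyses (Wald tests, post-hoc contrasts with Holm
adjustment on adjusted means; marginal means weight other factors' levels
equally), cross-checks the sampler, and fits the 231 per-pair models behind
the pairwise Q_ST matrix, where per-pair MCMC would be disproportionate.
Non-convergence triggers optimizer fallbacks (BFGS, L-BFGS, Powell) and
raises with the trace if all fail; failed pairs yield missing matrix
entries with a warning.

**Modes.** Across-treatment (treatment fixed), per-treatment (subset, no
fixed factor), per-lineage (across-treatment model inside one lineage;
lineages with fewer than 4 populations are refused, mirroring the exclusion
of a 3-population lineage from lineage-specific estimates).

## Neutral null and the difference test

Under drift, the expected among-population additive variance is
`V_P^n = F_ST * 2 V_A / (1 - F_ST)`. Its finite-sample spread over `n_pop`
demes is emulated by multiplying with `r / (n_pop - 1)`,
`r ~ chi2(n_pop - 1)`. Per simulation, `V_A` is a posterior seed-family
variance draw (multiplier 1.0 by default — no selfing correction, matching
the analysis emulated here rather than quantitative-genetic theory, which
under full selfing would allow the among-family variance to exceed half of
`V_A`; the multiplier is exposed in `NeutralSimConfig`), and
`Q^n_ST = V_P^n / (V_P^n + 2 V_WP)` uses the observed (posterior draw)
within-population variance. The test statistic is the index-paired
difference between 1000 posterior Q_ST draws and 1000 simulated Q^n_ST
draws — the draws are independent, so index pairing is an arbitrary but
fixed convention — with a directional/stabilizing verdict when the 95%
equal-tailed interval of differences excludes zero. The F_ST entering each
test is recomputed on exactly the subset of populations analyzed, and
negative estimates are clipped to zero before simulation (the formula is
undefined below zero).

## Synthetic data

The generator defines the study conditions: 22 populations in three
lineages (8/11/3), 4–6 seed families per population (default 5), 4
offspring per family and treatment, three treatments with an optional
unbalance mask, target F_ST 0.66, 16 loci with 5 alleles each, selfing
rate 0.95 (a realistic value for a predominant selfer; the emulated study
reports no numeric rate), unit among-population and seed-family variances,
family x treatment variance 0.25, unit residual variance, and a grand mean
of 10 with treatment effects (0, 1, 2).

Genotypes follow an island model: per locus, base frequencies from a flat
Dirichlet; population frequencies from `Dirichlet(base (1 - F)/F)`, whose
expected Wright F_ST equals the target; genotypes drawn with autozygosity
probability `F_IS = s / (2 - s)`. This analytic link was chosen over
coalescent simulation for speed and transparency. Selfing enters only
through within-individual homozygosity, not identity disequilibrium —
sufficient for the statistics tested. The generator does not emulate
stepwise mutation, linkage, demographic history, or trait non-normality;
passing closed-loop tests therefore demonstrates estimator correctness
under the assumed model, not robustness to real-data violations.

The bundled fixture reproduces the published 22-population design verbatim
(ids, coordinates, per-treatment family/offspring counts, three-cluster
Q-vectors, gene diversities) and simulates genotypes, phenotypes and soil
around it deterministically.

## Environment association

Soil variables are z-scored (sample SD); PCA is the eigendecomposition of
the correlation matrix with a deterministic sign convention (largest-
magnitude loading positive). Constant columns are dropped with a warning.
Cline models regress a trait on a PC axis with treatment fixed and lineage,
population, family random (overall variant), or PC x lineage fixed within
one treatment (per-treatment variant); a population-mean seed-mass
covariate is optional. Environmental distances are Euclidean over the
standardized variables (pairwise-complete when values are missing);
geographic distances are haversine on a sphere of radius 6371.0088 km —
at regional scales the ellipsoidal correction is far below 1%. The printed
1.1 km distance between the closest population pair is not exactly
reproduced from 4-decimal coordinates (haversine gives 1.02 km); the
coordinates were evidently rounded and no correction is applied.

MMRR unfolds lower triangles, z-scores each unfolded vector (so
coefficients are comparable across predictors; standardization is of the
off-diagonal vector, not the whole matrix), fits OLS, and assesses each
coefficient against 9999 simultaneous row/column permutations of the
dependent matrix, two-tailed on t, with the observed statistic counted in
numerator and denominator: `p = (#{|t*| >= |t|} + 1) / (n_perm + 1)`.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| lineage Q threshold | 0.7 | assignment cut-off on admixture proportions |
| chain | 13000 / 3000 / 10 | iterations / burn-in / thinning (1000 draws) |
| n_sim | 1000 | neutral Q^n_ST draws per test |
| n_perm | 9999 | MMRR permutations |
| soil radius | 15 km | closed-ball aggregation of soil points |
| missing genotype codes | 0, -9 | both accepted on input |
| k_specific | 1.0 | root-porosity weight factor (species value unpublished) |
| earth radius | 6371.0088 km | haversine sphere |

## Problem sizes used by the test suite

Stochastic checks run at reduced sizes chosen to keep the suite fast while
leaving comfortable statistical margins: the neutral-null calibration uses
500 closed-loop replicates at 10 populations x 4 families x 4 offspring
with 200 retained draws; parameter recovery uses 200 replicates at the full
22-population design; the acceptance script uses 100/100/300 replicates for
theta recovery, Q_ST recovery and calibration respectively.

## Known limitations

- Gaussian responses only; no pedigree/animal models, no correlated-trait
  (multivariate) Q_ST.
- The pairwise Q_ST estimator is REML-based with treatment as a fixed
  effect; two-group REML occasionally fails to converge on near-boundary
  pairs, which propagate as missing entries.
- `V_A` = seed-family variance assumes outbred half/full-sib scaling; under
  predominant selfing this understates additive variance, biasing Q^n_ST
  conservative for directional verdicts. The `v_a_multiplier` knob exists
  precisely to probe this.
- STRUCTURE-style clustering and cluster-number selection are out of scope;
  the pipeline consumes a Q-matrix.
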