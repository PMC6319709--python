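# qstkit

Adaptive-divergence analysis for structured plant populations sampled as
seed families and raised in a common garden: molecular diversity and
differentiation from codominant (microsatellite) genotypes, Bayesian
estimation of quantitative-trait differentiation (Q_ST), a simulated
neutral null for Q_ST–F_ST comparison, and trait–environment cline and
matrix-regression analyses. A synthetic-data generator reproduces the
statistical structure of a 22-population, three-lineage, predominantly
selfing study system under three nitrogen-addition treatments, so every
stage is testable without external downloads.

## Who this is for

Evolutionary ecologists and population geneticists asking whether
quantitative-trait divergence among populations exceeds what drift alone
would produce, and whether trait variation tracks the environment of
origin — given (a) a codominant multilocus genotype table, (b) an
individual-level trait table from a nested seed-family design, (c) an
admixture Q-matrix, and (d) population soil/coordinate tables.

## The statistics at the core

For a trait measured on offspring of maternal seed families nested within
populations, the nested mixed model

    y = Xb + u_pop + u_fam(pop) + e,  u_pop ~ N(0, V_AP), u_fam ~ N(0, V_WP)

is fitted by a blocked Gibbs sampler (conjugate normal / inverse-gamma
updates), and each retained posterior draw is mapped through

    Q_ST = V_AP / (V_AP + 2 V_WP).

Neutral molecular differentiation is the Weir–Cockerham θ (ratio of summed
variance components across loci and alleles). The neutral expectation for
the trait is simulated as

    V_P^n = F_ST · 2 V_A / (1 − F_ST) · r / (n_pop − 1),  r ~ χ²(n_pop − 1)

with V_A drawn from the posterior of the seed-family variance, and
Q^n_ST = V_P^n / (V_P^n + 2 V_WP). The test statistic is the paired
difference between 1000 posterior Q_ST draws and 1000 simulated Q^n_ST
draws: a 95% credible interval entirely above (below) zero indicates
directional (stabilizing) selection. Environment association uses PCA of
standardized soil variables, REML mixed-model clines, and multiple matrix
regression with randomization (MMRR, 9999 permutations of the dependent
matrix).

See `docs/methods.md` for assumptions, priors, defaults and limitations.

## Worked example

A full closed loop on synthetic data generated under drift (neutral trait
divergence at the design's target F_ST of 0.66):

```python
import qstkit as qk
from qstkit.quantgen import ChainConfig
from qstkit.neutrality import compare_to_neutral

design = qk.SimDesign(seed=7)                 # 22 pops, 3 lineages, selfing 0.95
genotypes = qk.simulate_genotypes(design)
theta = qk.fst(genotypes)
print(f"global theta = {theta.value:.3f} (per-locus SD {theta.per_locus_sd:.3f})")

traits = qk.simulate_phenotypes(design, neutral=True)
qst = qk.QstModel(traits, "trait1").fit(seed=8, chain=ChainConfig(13000, 3000, 10))
print(qst.summary())

test = compare_to_neutral(qst, theta.value, design.n_pop, seed=9)
print(test.summary())
```

prints

```
global theta = 0.693 (per-locus SD 0.068)
Q_ST(trait1, across-treatment) = 0.555 (95% CrI 0.389-0.728, 1000 draws)
Q_ST - Q^n_ST (trait1, across-treatment): median -0.124, 95% CrI [-0.334, +0.110] -> neutral
```

The genotypes realize θ ≈ 0.69 around the 0.66 target; trait divergence is
substantial (posterior median Q_ST 0.56) but — because the phenotypes were
generated under drift at that same F_ST — the difference test correctly
returns a neutral verdict: the credible interval of Q_ST − Q^n_ST spans
zero.

The same analyses run from the shell:

```sh
qstkit simulate --out data/ --seed 7
qstkit popgen fst --genotypes data/genotypes.csv
qstkit qst --traits data/traits.csv --trait trait1 --seed 8
qstkit run --config pipeline.yaml      # full pipeline from a YAML config
```

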