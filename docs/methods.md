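# Methods

`rvpower` is a simulation-and-analysis toolkit for a focused methodological
question: when a *gene* (not a single variant) is the unit of discovery in a
rare-variant association study of a quantitative trait, how does the
classical per-SNV regression test — combined across the gene by a minP rule —
compare with multi-marker tests (burden, SKAT, SKAT-O) in type I error and
power?  This note records the models, the numerical choices, and what the
synthetic data can and cannot establish.

## Genotype model

Genotypes come from a single pool of `H = 10,000` binary haplotypes over a
200 kb region, simulated once per experiment with `msprime` under a neutral
coalescent with recombination.  The demographic model is a single population
that grew exponentially from an ancestral effective size `N_anc = 15,000` to
a present size `N_0 = 300,000` over the last 350 generations (sizes are on
the haploid-model scale: two lineages coalesce at rate `1/N(t)` per
generation).  Per-generation rates are `mu = 2.15e-8` mutations/bp
(infinite-sites, continuous coordinates) and `r = 1e-8` recombinations/bp.

These four numbers are a *calibration*, not an estimate: they were chosen so
that the emergent summaries of the sampled genes match deep-resequencing
panels of European ancestry used in rare-variant method evaluations —

* 3 kb genes paired into n = 1,000 diploids carry on average ~33
  non-monomorphic SNVs (observed 32–35 across pool seeds; range roughly
  15–55);
* ~41% of SNVs are singletons (MAC = 1) and ~12% doubletons in the 2,000
  sampled haplotypes;
* 75–82% of SNVs are rare (MAF ≤ 0.03).

The calibration is enforced by a regression test rather than hard-coded
data, so a change in `msprime`'s internals that shifted these summaries
would surface as a test failure.

A gene replicate is drawn by (1) placing a 3 kb window uniformly in the
region (0-based, half-open `[s, s+L)`), (2) drawing `2n` haplotypes from the
pool *without replacement* and summing consecutive pairs into 0/1/2
genotypes, (3) re-orienting every site so the counted allele is the minor
allele *in that sample* (`MAF = MAC / 2n`), and (4) dropping monomorphic
sites.  Windows without polymorphic sites — or, under an alternative
scenario, without a rare site to make causal — are resampled and counted, so
power denominators stay at exactly `m`.

Pools can be saved and reloaded as plain text (`save_haplotype_pool` /
`load_haplotype_pool`), which permits byte-identical reuse of an externally
exported haplotype panel in place of the simulated one.

## Trait model

For individuals `j` with genotypes `g_ij`:

    Y_j = 0.5 x1_j + 0.5 x2_j + sum_i beta_i g_ij + eps_j,
    x1 ~ Bin(0.5),  x2 ~ N(0,1),  eps ~ N(0,1).

Causal variants are drawn uniformly among the gene's rare SNVs
(MAF ≤ 0.03); the causal count is `max(1, round_half_up(fraction * n_rare))`
(the floor of one causal variant per gene is part of the design; the
rounding convention — half away from zero — is pinned by tests).  Effects
are `|beta_i| = c * |log10 MAF_i|`, so a singleton at MAF 0.0005 carries an
effect ~3.3c while a variant at MAF 0.03 carries ~1.5c.  The sign split
(100/0, 80/20 or 50/50 positive/negative) uses the same rounding rule on a
uniformly chosen subset.

The shipped scenario grid (`rvpower/data/scenarios.yaml`, loaded by
`scenario_grid()`) crosses causal fraction {5, 10, 20, 50}%, effect constant
c in {0.6, 0.3, 0.2} and the three sign splits into 36 alternative
scenarios, plus the null scenario 0.  Per-gene explained variance is
`sum_i 2 MAF_i (1 - MAF_i) beta_i^2 / Var(Y)` with `Var(Y)` taken as the
empirical variance of the replicate's trait — a defined number per replicate
without distributional assumptions; its median across replicates spans
~0.1% (5% causal, c = 0.2) to ~9% (50% causal, c = 0.6).

Misspecification arm: `eps` may instead follow t4, t8, or a standard
log-normal centred by `exp(1/2)` (centring keeps the null intercept zero;
the tests still assume normal errors, which is the point of the arm).
Binary arm: a logistic model on the same linear predictor; the intercept is
solved numerically for a configurable population prevalence (default 0.1)
and a balanced case-control sample is drawn by rejection sampling.  The
case-control sampler records which genotype rows it kept
(`PhenotypeSet.genotype_rows`), since resampling changes the genotype
matrix.

## The four tests

All tests condition on the two covariates and can run in two inclusion
modes applied identically: every SNV of the gene, or rare SNVs only.

**Single-marker test (SMT).**  Per SNV, OLS of `y` on `(1, x1, x2, g_i)`;
the Wald statistic `beta_hat/SE` is referred to `t_{n-4}` (unbiased residual
variance, divisor `n - 4`).  The fits are vectorised over SNVs via
Frisch–Waugh–Lovell residualisation, which reproduces the full-model
coefficient, standard error and degrees of freedom exactly (pinned against
a normal-equations oracle).  Gene-level decision: minP — the gene is
declared significant when the smallest multiplicity-adjusted per-SNV
p-value (Benjamini–Hochberg by default, Bonferroni as alternative) is at or
below the nominal level.  Genotype columns collinear with the design are
reported as missing fits and excluded from the minimum; duplicated columns
are deliberately *not* pruned — each SNV is tested as observed.

**Burden.**  OLS Wald t-test (df `n - 4`) of the unweighted minor-allele sum
`sum_i g_i`.

**SKAT.**  Score statistic `Q = r' G W^2 G' r / sigma_hat^2` with `r` the
covariate-only residuals, ML variance `sigma_hat^2 = SSE/n`, and
`W = diag(w_i)` with `w_i` the Beta(1, 25) density of `MAF_i` (the standard
"linear weighted" kernel; parameters configurable).  Under the null `Q` is
distributed as `sum_j lambda_j chi2_1` with `lambda_j` the eigenvalues of
`W G~' G~ W` (`G~` the covariate-residualised genotypes).  Because the
statistic and the kernel are scaled consistently, the variance-estimator
convention cancels from the p-value.

**SKAT-O.**  For a grid of mixing parameters
`rho in {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}`,
`Q_rho = (1-rho) Q_SKAT + rho Q_wburden` in the weighted-score form.  Each
`Q_rho` is referred to its own chi-square mixture; the minimum p over the
grid is then corrected for the search by the standard one-dimensional
integration: the common burden-direction component is isolated as a
`chi2_1` variable, the per-rho thresholds at the minimum p are mapped back
through moment-matched quantiles, and the remainder mixture's CDF
(variance-deflated for the dropped cross-term) is integrated against the
`chi2_1` density over (0, 40) with 64-point Gauss–Legendre after the
substitution `x = t^2` (which removes the density's inverse-square-root
endpoint singularity).  `rho = 1` is capped at 0.999 inside the construction
so every mixture keeps full rank; one-point grids {0} and {1} short-circuit
to the exact SKAT and weighted-burden score tests.  The final p-value is
also capped at `n_grid * min_rho p_rho`.

## Chi-square-mixture tail probabilities

`quadform.davies_pvalue` inverts the characteristic function of
`sum lambda_j chi2_1` (Imhof's integral) with a midpoint rule, following
Davies' analysis of the two error sources:

* *Aliasing*: the discretisation with step `Delta` wraps tail mass from
  `q ± 2*pi/Delta`; `Delta` is chosen from a closed-form Chernoff bound so
  that the wrapped mass is below `acc/4`.
* *Truncation*: the integral is cut at `U` and the cut tail is *estimated
  analytically* by one integration by parts
  (`g(U) cos(theta(U)) / theta'(U)`); `U` is then chosen so the second-order
  residual `~ g(U)(k/2+1)/(U theta'(U)^2)` is below `acc/4`.  The end
  correction is what keeps `U` small in the hard near-rank-one cases
  (a single dominant eigenvalue and a mid-distribution threshold).

The kernel is numba-compiled; a multi-threshold variant shares the
eigenvalue-dependent work across thresholds for the SKAT-O integration.
Validation: equality with chi-square closed forms to <5e-9 across
`k = 1..33` and p-values 0.5 down to 1e-6, agreement with an independent
Ruben-series oracle to 1e-7, and with 1e7-draw Monte-Carlo tails.

The Liu moment-matching approximation (modified form, matching skewness and
where possible kurtosis to a noncentral chi-square) serves three roles:
fallback when the inversion exceeds its node budget (recorded in the result
object), screening of the SKAT-O rho grid, and the quantile back-transform
inside SKAT-O (where the published construction itself uses the
moment-matched quantile).  In the simulation engine the inversion accuracy
is targeted *relative* to the p-value (0.5% of p, floored at 1e-8, capped
at 1e-3): decisions at any nominal level from 0.05 down to 2.5e-6 are
unaffected, while mid-distribution p-values avoid needlessly fine grids.
The screening refines per-rho p-values only when they could become the grid
minimum and are below 0.15; above that the moment approximation's ~1e-3
error cannot move any decision.

## Monte-Carlo experiments

`run_scenario` draws `m` independent replicates; replicate `i` uses the RNG
stream `SeedSequence([root_seed, i])`, so results are independent of
execution order and reproducible bit-for-bit (replicates could be
distributed over workers without changing results; the shipped driver is
serial since the per-replicate cost is milliseconds).  Gene-level power /
type I error is the rejection proportion with binomial standard error;
SNV-level power pools the causal SNVs of all replicates within MAF/MAC
strata (singletons, doubletons, (0.001, 0.005], (0.005, 0.01],
(0.01, 0.03]).  `summarize_experiment` renders wide tables per scenario ×
method × level × inclusion, with median (MAD) explained variance.

Default problem sizes are chosen for desk-scale runs with quantified MC
error: `m = 1e5` for null calibration (MC SE at alpha 0.05: 0.0007),
`m = 2,000–10,000` for power, configurable upward.  The m = 10^7-replicate
regime the gene-level deep-tail levels (1e-5, 2.5e-6) would require is out
of desk scope; at `m = 1e5` only levels down to ~1e-3 are meaningfully
estimable.

## Blood-pressure adjustment stage

Antihypertensive treatment makes observed SBP a lower bound on the
untreated value, so treated individuals are right-censored at their
observed SBP.  `fit_censored_regression` maximises the Tobit likelihood
(normal errors; censored records contribute `log P(T > observed)`) over
(intercept, age, sex, smoking, log sigma) by BFGS from the OLS start, with
a Nelder–Mead polish on non-convergence; standard errors come from the
inverse numerical Hessian (delta method for sigma).  With no censored
records the ML solution is the OLS fit, returned in closed form.

`adjust_phenotype` defines the analysis phenotype: `SBP_adj = observed −
fitted` for untreated records, and for treated records the conditional mean
shift `E[T | T > c] − mu = sigma * phi(z)/(1 − Phi(z))`, `z = (c − mu)/
sigma`, computed on the log scale so extreme censor points degrade into the
stable asymptotic regime instead of overflowing.

Gene regions are user-supplied coordinates flanked by ±5 kb (1-based
inclusive, floored at 1; overlapping regions allowed).  VCF handling:
multi-allelic records are skipped with a warning; SNVs with a missing-call
fraction *strictly greater* than 0.05 are excluded; kept genotypes are
oriented to the sample minor allele (frequency over called genotypes) and
residual missing calls are mean-imputed — both conventions are configurable
since the original analysis protocol leaves them open.  The gene-level
tests then run on `SBP_adj` with an intercept-only covariate design (the
phenotype is already covariate-adjusted).  Reading a gene from VCF and
testing it is bit-identical to testing the in-memory matrices (pinned by a
round-trip test).

`write_synthetic_cohort` fabricates a complete cohort (VCF + phenotype +
gene table, ~100 individuals, 9 genes) for end-to-end tests; it is a
synthetic stand-in for access-controlled sequencing studies and makes no
attempt to mimic any particular cohort's LD or phenotype distribution — its
censoring mechanism (treated observed = true − Uniform(5, 20)) is
deliberately *not* the Tobit model, so the adjustment stage is exercised
under realistic misspecification.

## What the synthetic data does and does not show

The generator reproduces the features that drive the SMT-vs-MMT comparison:
gene-sized LD blocks, a singleton-heavy frequency spectrum, MAF-linked
effect sizes, covariates, and medication censoring.  It does not model
genotyping or sequencing error (especially consequential for singletons),
population structure or relatedness, selection, non-additive effects,
covariate–genotype correlation, or gene–gene interaction.  Passing tests
therefore establish the statistical behaviour of the tests under a clean
additive model on realistic allele-frequency spectra — not robustness to
the data-quality problems of real sequencing studies.

## Known limitations

* SKAT-O's small anti-conservatism (~0.052 empirical at nominal 0.05) is a
  property of the published construction and reproduces here; it is not
  corrected for.
* The Tobit fit assumes normal errors; the adjustment is a conditional
  mean, not a draw, so the adjusted phenotype of treated individuals has
  shrunken variance.
* Deep-tail gene-level calibration (nominal 1e-5 and below) is outside the
  default replicate budgets.
* The binary-trait arm's prevalence and sampling design are reconstructions
  (documented defaults), as the exact choices are not fixed by the study
  design this package re-implements.  The association tests are applied to
  the 0/1 trait in their linear-model form (a linear probability model for
  the SMT/burden scores); dedicated logistic score versions are not
  implemented.
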