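# Methods

## The problem

Large retrospective cohorts recruit a small, self-selected fraction of their
target population. When the decision to participate depends on genotypes or
phenotypes, the participant sample is conditioned on a common effect of those
variables — a collider — and non-causal associations appear among
participants. When participation effects additionally differ between males
and females (*sex-differential* participation), autosomal variants become
associated with biological sex in the sample ("sex GWAS" signal), trait GWAS
pick up spurious hits at participation-associated variants, and Mendelian
randomization between causally unrelated traits drifts off the null.

This package simulates that mechanism end to end, quantifies the bias, and
verifies the practical correction: run the GWAS separately within each sex
and combine the two estimates by fixed-effects inverse-variance
meta-analysis.

## Generative model

**Population.** `n` individuals; `m` unlinked autosomal variants with
minor-allele frequencies `p_j ∈ (0, 0.5]`, dosages `g_ij ~ Binomial(2, p_j)`
(Hardy–Weinberg); sex `s_i ~ Bernoulli(male_fraction)` coded 0 = female,
1 = male. There is no LD: the bias mechanism studied here is marginal and
per-variant, so linkage is orthogonal to it.

**Binary traits.** Liability-threshold model on centered dosages:
`L_i = Σ_j b_j (g_ij − 2p_j) + e_i`, `e_i ~ N(0, 1 − h²)`, trait = 1 iff
`L_i > Φ⁻¹(1 − K)` for prevalence `K`. Per-allele effects are drawn i.i.d.
normal per standardized genotype on the causal set and rescaled **exactly**
(not just in expectation) so `Σ_j 2 p_j (1 − p_j) b_j² = h²`; this makes the
heritability invariant testable to machine precision.

**Participation.** The core object is a logit selection model,

    P(participate | g, x, s) = expit(α_s + Σ_j b_{s,j}(g_ij − 2p_j) + Σ_t γ_{s,t} x_it),

equivalently a liability threshold with standard-logistic noise (variance
π²/3, π ≈ 3.14159). Liability-scale heritability of participation is
therefore defined on the logistic scale, `h²_s = Var(η_s)/(Var(η_s) + π²/3)`,
and effect vectors are rescaled exactly to
`Var(η_s) = h²_s/(1 − h²_s) · π²/3`. (Traits use the probit/Gaussian
convention because that is the standard liability-threshold phenotype model;
only participation is logit.) *Sex-independent* forces identical effect
vectors in both sexes; *sex-differential* allows any between-sex effect
correlation, down to −1 (mirrored effects).

**Intercept calibration.** Target participation rates π_s are inputs, so the
intercepts α_s are solved by monotone bracketing root-finding (Brent) on the
simulated linear predictors until `mean(expit(α_s + η_s)) = π_s` (absolute
tolerance 1e-4, well below Monte-Carlo error at these sample sizes; the
root itself is found to 1e-12). Monte-Carlo calibration rather than a
Gaussian-integral approximation keeps the calibration exact for any effect
distribution. When the model is exactly sex-symmetric (sex-independent
effects, equal targets) a single intercept is solved on the pooled sample
and shared, which preserves the exact null below.

## Association engine

Per-variant tests are maximum-likelihood logistic regressions of the outcome
on allele dosage (plus shared covariates), fit by IRLS with step tolerance
1e-8 and at most 50 iterations; non-convergence, |beta| > 30 (separation
guard), monomorphic variants and sparse genotype/outcome margins (< 5
observations) are flagged, never silently dropped, and flagged variants are
excluded from inflation summaries. Because dosage takes 3 values and the
only covariate used by the pipelines (sex) is binary, the engine collapses
the data onto the ≤ 6 design cells and runs the IRLS on grouped counts —
the cell counts are sufficient statistics, so this is the identical MLE,
verified against `statsmodels.Logit` to ~1e-15 in the test suite. A
linear (OLS) engine is available for continuous outcomes and as a
linear-probability fallback.

The **sex GWAS** regresses sex on dosage among participants with no
covariates; its mean Wald chi-squared over variants, against the null
expectation of 1, is the inflation readout. The **trait GWAS** runs either
pooled ("combined") or within each sex ("stratified"); stratified results
are combined per variant by fixed-effects inverse-variance meta-analysis
(`w_s = 1/se_s²`), which also emits Cochran's Q.

**The sex covariate question.** `run_trait_gwas(mode="combined")` adjusts
for sex by default, matching common GWAS practice. The figure-style bias
experiments, however, run the combined arm *unadjusted*: conditioning on sex
inside the regression is itself a (partial) stratification — in the
rare-participation limit the selection weight factorizes within sex, so a
sex-adjusted pooled fit is as immune as the stratified analysis and shows no
contrast with it (we verified this numerically; both sit within Monte-Carlo
error of the meta estimator). The bias of interest flows through the
genotype→sex and sex→trait associations induced among participants, a path
that is open only when the pooled fit does not condition on sex.

## Theory: rare-participation limit and the enumeration oracle

Write the selection weight at rare participation as
`expit(z) ≈ e^z`. Then among participants the log-odds of male at genotype g
is linear in g with slope exactly `b_male − b_female`: participation effects
common to both sexes cancel, and only the between-sex difference drives the
sex GWAS. At any participation rate the post-selection association can be
computed without sampling error by enumerating the six (genotype × sex)
cells with masses `HWE(g) · P(s) · P(participate | g, s)` and fitting a
weighted logistic regression of sex on dosage to the exact masses (Newton,
step tolerance 1e-13). The oracle also returns the per-participant Wald
non-centrality `slope²/Var₁(slope)` computed from the per-participant Fisher
information, so the predicted mean chi-squared for N participants is
`1 + N · ncp`. An optional per-sex Gaussian "background" standard deviation
integrates the participation probability over the linear-predictor
contribution of all other variants and traits (Gauss–Hermite, 64 nodes), so
the oracle predicts marginal per-variant effects inside polygenic
simulations as well.

Two scales for the Fig-style effect-difference slope are reported and not
conflated: on the log-odds scale the regression of estimated sex-GWAS
effects on `b_male − b_female` has slope 1 in the rare limit; on the
linear-probability scale the estimated effects regress on the marginal
(probability-scale) participation-effect differences with a slope of order
1/(4·rate) at equal calibrated participation rates. The package emits both slopes plus the
realized between-sex rate difference and asserts only the log-odds-scale
prediction; which probability-scale normalization the original figure used
is not recoverable from the available description.

## Study conditions (experiment defaults)

The source experiments do not publish their grid values; the conditions
below were fixed once, sized for single-workstation runs, and are the
package defaults.

| Experiment | Conditions |
|---|---|
| Exact-null / rate grid | n = 50,000; 400 variants, MAF ~ U(0.15, 0.5); participation h² = 0.2 per sex; π ∈ {0.01, 0.05, 0.2, 1}; 5 replicates |
| Oracle equivalence | single variants, n = 200,000; MAF 0.3; 3 rates × 3 effect pairs |
| Rare-limit slope | 100 variants simulated independently, n = 2,000,000 each; MAF 0.3; π = 0.001; per-sex effects ~ U(−0.3, 0.3) |
| Correction (stratify+meta) | n = 200,000; π = 0.01; 50 trait-null variants, MAF ~ U(0.2, 0.5); participation h² = 0.2 per sex with between-sex effect correlation −1; trait K = 0.3, γ = ±0.7 mirrored across sexes; 50 replicates |
| MR robustness | n = 100,000; π = 0.01; two traits, h² = 0.3, K = 0.3, 30 disjoint causal variants each (oracle instruments); trait→participation γ = ±0.7, mirrored and opposite between the traits; 40 replicates |
| Power (representative) | π = 1; n = 6,000; 50 causal variants; trait h² = 0.2, K = 0.5; α = 5e-4; 500 replicates |

The correction and MR scenarios are deliberately *maximally*
sex-differential (between-sex effect correlation −1, mirrored trait
effects); they are stress tests of the correction, not estimates of any real
cohort's architecture. α = 5e-4 stands in for genome-wide significance,
which is unreachable at these sample sizes.

Seeding: every experiment takes one master seed; per-cell generators are
spawned as `SeedSequence(master_seed, spawn_key=cell_index)`, each record
carries its derived seed, and reruns with the same configuration are
bit-identical.

## Numerical and design choices

- Genotypes are centered at `2p_j` throughout, so intercepts map directly to
  rates and the theory formulas stay clean.
- Oracle-instrument MR: the exposure's true causal variants are used as
  instruments, isolating participation bias from winner's-curse effects;
  p-value-based selection is available but not the default.
- MR-IVW uses first-order weights 1/se_outcome² and ignores exposure-side
  uncertainty (the standard IVW estimator); meta-analysis accepts any number
  of strata, not just two.
- Power-difference interval: the per-test decision discordance between the
  pooled fit and estimated-weight IVW meta is ~2·10⁻⁴ and one-directional
  (the joint fit is very slightly more efficient in finite samples), so a
  replicate-paired Wald interval on the mean difference degenerates. The
  reported interval is the two-proportion binomial 95% CI over all
  replicate × variant decisions, which is conservative with respect to
  pairing; paired per-replicate differences are still emitted.
- Degenerate inputs have deterministic, flagged outcomes: monomorphic or
  sparse variants, perfect linear fits (zero residual), separated logistic
  fits, single-sex participant sets, empty rate grids and uncalibrated
  models all either flag or raise with a diagnostic.

## What the simulations do and do not show

The generator emulates the mechanism of sex-differential selection under a
logit participation model with independent variants and binary traits. It
does not emulate LD, continuous participation-driving variables (age,
income), assortative or household recruitment, relatedness, X-chromosome
dosage, or non-logit selection (a probit switch would change the
rare-limit algebra). Passing tests therefore demonstrate that the
stratify-then-meta-analyze correction removes the bias *this mechanism*
generates, at the rates and architectures above — including its predicted
failure mode: at high participation rates the rare-limit factorization
breaks down and within-stratum bias is no longer negligible, which the
enumeration oracle quantifies exactly.

## Known limitations

- The correction's residual (within-stratum) bias grows with π and with the
  trait→participation effect sizes; the package measures it rather than
  bounding it analytically.
- Inflation summaries assume unlinked null variants when interpreting the
  mean chi-squared against 1.
- The grouped fast path requires dosage coding {0,1,2} and binary
  covariates; other designs fall back to the slower individual-level IRLS.
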