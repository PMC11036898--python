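# Methods

This note documents the statistical procedures the package implements,
the assumptions behind them, the parameter defaults and why they were
chosen, and what the synthetic-data validation does and does not
establish.

## Data model and preprocessing

The central object is a sample × ASV table of non-negative integer
read counts with per-sample metadata (phenotype group EIM/C, disease
subtype CD/UC, surgery flag, negative-control flag, free-form
covariates). Three filtering rules are applied in a fixed order:

1. **Low-frequency filter** (default 1e-5, i.e. 0.001%): an ASV whose
   total count divided by the grand total is *strictly below* the
   threshold is removed. The threshold is applied to the pooled
   relative abundance rather than per sample; pooled frequency is the
   common reading for removing globally rare features and the rule's
   wording carries no per-sample qualifier.
2. **Negative-control decontamination** (defaults 15%/15%): an ASV
   present (count > 0) in strictly more than 15% of negative controls
   and strictly fewer than 15% of biological samples is removed
   outright; for every surviving ASV the mean count across controls is
   subtracted from each biological sample's count, clamped at zero,
   then rounded half away from zero. Rounding keeps the integer-count
   contract required by the count models downstream; whether the
   original analysis rounded, floored or kept fractions is not
   documented anywhere, so this is a package decision.
3. **Prevalence filter** (default 10%), applied only before
   differential abundance and network inference: ASVs present in
   strictly fewer than 10% of samples are removed.

All prevalence comparisons use strict inequalities, and "present"
means count > 0 throughout. Filters are idempotent and never alter
retained entries (property-tested).

## Diversity and PERMANOVA

Shannon entropy uses the natural log, so Pielou's evenness
J = H / ln S is exact; J is undefined (reported missing) for
single-ASV samples. Unweighted UniFrac is the fraction of branch
length leading to ASVs present in exactly one of two communities;
weighted UniFrac is Σ_b l_b |p_a(b) − p_b(b)| over branches, where
p_x(b) is the fraction of community x descending through branch b,
normalised by Σ_b l_b (p_a(b) + p_b(b)) by default so the distance is
bounded in [0, 1] and invariant to rescaling either community. Both
are computed by a single post-order traversal accumulating per-branch
descendant mass; tests compare them against a brute-force enumeration
of branch descendant sets and against scikit-bio.

PERMANOVA partitions the Gower-centred inner-product matrix
G = −½·C·D²·C with sequential (Type-I) sums of squares: terms enter in
the order given, SS(term) = tr(H_k G) − tr(H_{k−1} G) for nested hat
matrices, residual SS = tr(G) − tr(H_full G), pseudo-F and
R² = SS/tr(G) follow, and p-values permute raw sample identities with
the (1 + #{F ≥ F_obs}) / (1 + B) estimator (never zero). This mirrors
the behaviour of vegan's `adonis2` defaults. An exact mode enumerates
all n! permutations for small n and then reports the enumeration
p-value with the identity included, which coincides with enumeration
over distinct group relabelings.

## Multi-model differential abundance

ASV count distributions vary wildly across taxa — some are
equidispersed, most are overdispersed, many have excess zeros — so a
single model family fits badly. Each ASV is therefore fit with four
candidates **on the same raw response**, making AIC values comparable
(comparing AIC across transformed responses would be invalid):

* gaussian identity-link linear model (no library-size adjustment);
* Poisson log-link GLM with log library size as offset;
* negative binomial (NB2) log-link GLM with offset; dispersion α by
  profiled maximum likelihood (1-D bounded search on log α nested in
  IRLS for the mean, outer convergence 1e-8). The dispersion MLE may
  sit on the α → 0 boundary, where the NB collapses to the Poisson;
  the implementation detects this and reports the boundary supremum,
  so NB log-likelihood ≥ Poisson log-likelihood always holds;
* zero-inflated negative binomial: NB count part with offset plus an
  intercept-only logit zero part, fit by expectation-maximization
  (E-step: posterior structural-zero probabilities for observed
  zeros; M-step: weighted NB fit and π update) to a log-likelihood
  tolerance of 1e-8 or 500 iterations. The intercept-only zero part is
  the minimal ZINB; anything richer is unidentifiable at these sample
  sizes.

AIC = −2ℓ + 2k counts every estimated quantity: k = p+1 (gaussian,
incl. variance), p (poisson), p+1 (negbin, incl. dispersion), p+2
(zinb, incl. dispersion and zero-inflation intercept). The converged
fit with minimal AIC is selected; ties go to fewer parameters, then a
fixed order (poisson, negbin, zinb, gaussian). ASVs where no fit
converges are reported in a skip log, not fatal.

**Inference.** The group effect is tested with a two-sided Wald test.
The covariance estimator is a deliberate design choice: information-
based (model) standard errors are exact when the chosen family is the
truth, but real ASV counts (and the log-normal generator used for
validation) have heavier tails than the NB, and model SEs then
understate sampling variability — measured type-I error was ~13% at
nominal 5% with n = 120. The reported p-values therefore use an HC3
(leverage-adjusted) sandwich covariance with a t reference whose
degrees of freedom are a moment-corrected Satterthwaite estimate,
df = min(3 (Σᵢuᵢ)²/Σᵢuᵢ², n−p) with uᵢ the squared per-observation
influence on the coefficient. The factor 3 removes the threefold
downward bias of the plug-in ratio under Gaussian influences, so on
well-specified data df ≈ n−p and the test reduces to the usual robust
Wald t; under heavy tails the df shrink and the reference widens.
Measured size at n = 60+60: 4.8% under the log-normal generator, 4.5%
on true NB data. Model-based SEs remain available on every fit and
are the ones verified against statsmodels.

Effect summaries follow the field's conventions: log₂ FC is the group
coefficient divided by ln 2 for log-link models and
log₂((mean_EIM + 0.5)/(mean_C + 0.5)) for the gaussian fit; the mean
difference is on raw counts. p-values are Benjamini–Hochberg adjusted
across ASVs (step-up, verified against a brute-force evaluation of the
definition and against statsmodels), and the final table keeps ASVs
with q < 0.05 and |log₂ FC| strictly > 1.

## SparCC and module association

Sequencing counts are compositional: correlations between relative
abundances are biased by the shared denominator. SparCC estimates the
correlations of the unobserved basis abundances from the variation
matrix T (T_ij = var log(fᵢ/fⱼ)) under the sparsity assumption that
most pairs are uncorrelated, giving the linear system
t = [(D−2)I + 11ᵀ] ω² for the basis variances and
ρ_ij = (ωᵢ² + ωⱼ² − T_ij)/(2ωᵢωⱼ), clamped to [−1, 1]. Pairs violating
the assumption are handled by iterative exclusion: up to
`max_exclusions` (default 10) times, the strongest not-yet-excluded
pair with |ρ| ≥ `exclusion_threshold` (default 0.1) is dropped from
the system (its T contribution removed, the system matrix entries
decremented) and the basis re-solved. Negative solved variances are
clamped to 1e-10 with a warning flag. Fractions use the deterministic
Dirichlet posterior mean (count + 1)/(depth + D) for reproducibility;
a seeded single-draw variant is exposed as an option.

Modules are connected components (size ≥ 2) of the graph with an edge
where ρ ≥ 0.5, *signed* — strong negative correlations do not join a
module, matching the stated rule "correlation coefficient ≥ 0.5"; an
absolute-value mode is a flag. Module abundance is the sum of member
relative abundances per sample (the simplest summary consistent with
"a module depleted in cases"); alternatives (mean, CLR) were
considered and rejected as harder to interpret at module sizes of 2.
Association with the binary phenotype uses logistic regression (own
IRLS, gradient tolerance 1e-10, separation detected and flagged) of
EIM status on the standardised log₁₀ module abundance (pseudocount =
half the smallest nonzero abundance of that module). Standardising
makes slopes comparable across modules as log-odds per SD; whether the
original analysis used raw, log or standardised abundance is not
recorded anywhere, so this is a package decision.

## Cohort statistics

The enrollment filter removes participants whose EIM status was never
confirmed by a specialist; on the bundled fixture this reproduces
156 → 131 with 86 confirmed EIM (60 CD / 26 UC) and 45 controls
(21 CD / 24 UC). Fisher's exact test uses the two-sided
"probability mass ≤ observed" rule (verified against exhaustive
hypergeometric enumeration); the chi-square is Pearson's without
continuity correction (a Yates flag exists). Both delegate to scipy.

## Synthetic-data generator

The generator emulates the statistical regime the analysis assumes,
with every planted feature recorded for recovery testing:

* **Basis abundances**: per-ASV baseline log-means ~ N(0, 1.5²)
  (about three orders of magnitude between common and rare taxa);
  within-sample multivariate normal log-basis with SD 1.0 and a
  block-diagonal correlation matrix realising the module
  specification via a Cholesky factor — the log-scale construction
  matches SparCC's log-normal basis model, which is what makes
  recovery tests meaningful.
* **Group effects**: planted log₂-fold effects shift the log-mean of
  chosen ASVs in the case group; optional group-specific structural
  zeros are applied to the basis *before* multinomial sampling, so
  zero inflation exists beyond sampling zeros (the regime that
  separates ZINB from NB). Effects may not be planted inside
  correlation modules — that would confound module recovery.
* **Counts**: multinomial at a negative-binomial library size (mean
  30,000, dispersion 5, floor 1,000 reads), so row sums equal library
  sizes exactly and compositional coupling between ASVs is real.
* **Contaminants**: contaminant ASVs carry no community basis; they
  appear in negative controls as Poisson draws at the stated control
  mean and leak into biological samples only through Bernoulli
  carryover.
* **Cohort fixture**: 156 enrollment records reproducing the study's
  exact marginals, including per-subtype sex and surgery counts.

Default simulated cohort sizes mirror the study (86 + 45 samples, 8
negative controls); validation simulations use the sizes stated with
each test (60+60 for DA calibration, 100–500 samples for SparCC
recovery, 65+65 for module association).

What the generator does **not** emulate: taxonomy-specific biology,
phylogenetic signal in abundances (the random tree is independent of
the correlation structure), denoising artifacts, chimeras, or batch
effects. Passing recovery tests therefore shows the estimators are
correct under the assumed regime, not that the pipeline is robust to
every pathology of real amplicon data. The log-normal tails are,
deliberately, heavier than the NB family — that mismatch is what the
robust Wald inference is validated against.

## Numerical choices and degenerate inputs

* GLM linear predictors are clipped at ±30 to prevent overflow; IRLS
  tolerance 1e-10, NB outer loop 1e-8, ZINB EM 1e-8/500 iterations;
  dispersion searched on log α ∈ [−12, 8].
* All-zero responses are rejected as degenerate; fits that throw or
  fail to converge are flagged and excluded from AIC selection; an ASV
  with no converged fit is skipped and logged.
* Ties in AIC are resolved by parameter count then a fixed model
  order, making results order-independent.
* Subtraction residues in decontamination round half away from zero.
* Distance matrices are validated symmetric with zero diagonal;
  PERMANOVA flags negative-eigenvalue artifacts (possible for
  semi-metric distances) rather than silently clipping.
* A single integer seed drives every stochastic component; derived
  streams are namespaced so stages are independently reproducible.

## Known limitations

* The ZINB zero part is intercept-only; covariate-dependent zero
  inflation is out of scope.
* SparCC p-values for individual correlations (bootstrap) are not
  implemented; the module threshold is applied to point estimates.
* PERMANOVA assumes exchangeable samples under the null; no strata or
  repeated-measures support.
* The gaussian candidate models raw counts (by design, for AIC
  comparability); it is rarely selected for realistic count data and
  exists to catch ASVs whose distribution none of the count families
  fit.
* Module association treats modules independently; no multiplicity
  adjustment is applied across modules, matching the source workflow.
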