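# Methods

This note documents the statistical models `apomir` implements, the
defaults it chooses where the design was genuinely open, and what its
synthetic-data tests do and do not establish about real data.

## Study design and data model

The pipeline targets a paired design: each subject contributes one
carcinoma and one adjacent-normal sample, linked to subject-level
covariates (age, sex, tumor site, AJCC stage, MSS/MSI phenotype) and
survival follow-up (months from diagnosis, vital status, and whether
colorectal cancer was a primary or secondary cause of death). Matrices
use `<subject>_T` / `<subject>_N` sample ids as the pairing key. Missing
expression cells are rejected outright — genes with widely missing
expression are expected to be excluded upstream — and the only metadata
field allowed to be missing is the tumor phenotype.

## Normalization

**RPMPCG.** A gene's expression level is its count divided by the
sample's total count over protein-coding genes, times 10⁶. The transform
is exactly scale-equivariant per sample, and the per-sample log totals
double as the offsets of the count model, so normalization and testing
share one denominator.

**Upper-quartile scaling (miRNA).** Each sample is multiplied by
(median across samples of the 75th percentile) / (its own 75th
percentile). Percentiles interpolate linearly between order statistics
(the common "type 7" rule; a parameter, not a constant, so another
convention can be swapped in). The map is idempotent and removes any
per-sample multiplicative distortion exactly, since such a distortion
scales the sample's P75 by the same factor.

**Differential expression per subject.** Downstream stages consume one
column per subject: tumor − normal by default. The difference keeps
zeros legal and linear models well-posed; the per-subject ratio
(fold change) is also available, with an optional pseudocount (default
off — a zero normal value is an error rather than a silent imputation)
and is used for descriptive per-subject FC reporting only.

## Paired negative-binomial differential expression

Per gene: `y_it ~ NB(μ_it, α)` with `log μ_it = a_i + β·1[t=tumor] + o_it`,
NB2 variance `μ + αμ²`, per-subject fixed intercepts `a_i`, and offset
`o_it` = log protein-coding total. β is the log fold change on the RPMPCG
scale. Design choices:

* **Subject effect as fixed intercepts.** With exactly two observations
  per subject the conditional (fixed-effect) fit is stable and tests the
  same within-pair contrast a random-intercept model would; no
  random-effect approximation is provided.
* **Solver.** The IRLS normal equations for this design are an arrowhead
  matrix (diagonal subject block plus one coupling column), solved
  exactly in O(n) per iteration via the Schur complement. The fit is
  numerically identical to a dense NB GLM on the dummy-coded design; the
  test suite asserts agreement with statsmodels to ~1e-5.
* **Dispersion.** Per-gene, by maximizing the Cox–Reid adjusted profile
  likelihood (the profile likelihood penalized by half the log-determinant
  of the weighted information), which counters the downward bias induced
  by one nuisance intercept per subject. Because α sits on a boundary, a
  positive estimate is kept only when it improves the adjusted likelihood
  by more than 2.0 over the Poisson limit (the boundary-corrected
  chi-square threshold); otherwise the fit collapses to Poisson. α is
  floored at 1e-8 and capped at 100. A fixed dispersion can be supplied
  instead of estimating.
* **Test.** Likelihood-ratio test of β at the estimated dispersion
  (default); Wald is available. Simulations at n = 200 pairs, dispersion
  0.3 put the empirical size at ~0.05 ([0.03, 0.07] band over 1500 null
  genes) and recover a planted log-FC of ln 2 within ±0.15 in ≥95% of
  replicates.
* **Reporting.** Fold change = tumor-mean / normal-mean of RPMPCG,
  unrounded; dysregulation = adjusted p < 0.05 (BH) and FC outside
  [0.67, 1.50]. Classification always uses the unrounded mean ratio — a
  ratio of 0.6656 counts as < 0.67 even though it prints as 0.67. Genes
  with all-zero counts are excluded as untestable rather than fitted.

MSS/MSI subgroup analyses rerun the identical pipeline on the phenotype
subset (offsets and BH family recomputed within the subset).

## Bootstrap-F association screen

Genes and miRNAs whose FC falls outside [0.67, 1.50] enter the screen.
For each pair, OLS of the gene differential on (miRNA differential, age,
sex), with the extra-sum-of-squares F for the miRNA term against the
covariates-only null. Constant covariates are absorbed by the intercept
(relevant for single-sex or age-homogeneous subsets); genuinely collinear
columns are an error naming the columns.

The null distribution is built by residual resampling from the *null*
model: resample its residuals with replacement, add to its fitted values,
refit both models, record F\*. `p = (1 + #{F* ≥ F_obs}) / (n_boot + 1)`
(add-one convention; p ≥ 1/(n_boot+1), never 0). Refits are vectorized
through fixed orthonormal bases of the two design spaces — mathematically
identical to refitting per resample. With Gaussian errors the bootstrap p
converges to the classical F-test p (checked at 20,000 resamples,
|Δ| < 0.02). One BH family covers all pairs tested in a run; per-pair
resampling streams are derived by hashing the pair ids with the root
seed, so results are independent of enumeration order.

## Seed matching

Seeds are taken at miRNA positions 2–7 (6-mer), 2–8 (7-mer, the 7mer-m8
site), and 1–8 (8-mer); candidate sites are their DNA reverse complements
(U→T) matched exactly on the UTR plus strand, 1-based closed coordinates.
Wobble pairing is not modeled and `N` never matches. The three sites
nest — an 8-mer hit at offset p implies a 7-mer hit at p and a 6-mer hit
at p+1 — and the scanner reports only the longest match per locus;
overlapping distinct loci are all reported. When UTRs from multiple
genome assemblies are provided, a pair matches if it matches in either
file, with the source recorded per match. A significant association with
at least one seed match and a negative slope is a candidate direct
interaction; other significant associations are candidate indirect.

## Permutation Cox survival analysis

One record per subject: time = months to death or last contact, event =
death with CRC as primary or secondary cause (other deaths and losses to
follow-up are censored). The Cox model regresses the hazard on (miRNA
differential, age, sex, stage), stage coded 1–4 as a single ordered
numeric covariate — full dummy coding is fragile in small site-specific
cohorts and remains a config choice away. Ties use Efron's correction.

The fitter is a Newton solver on the partial likelihood written over
cumulative risk-set sums (singleton event times fully vectorized, tied
groups looped); it matches lifelines' `CoxPHFitter` to ~1e-7 on betas,
standard errors and log-likelihoods in the test suite. It exists because
the permutation test refits the model thousands of times: p-values come
from permuting the exposure across subjects (covariates and outcomes
fixed), refitting, and comparing likelihood-ratio statistics, add-one
convention as above. Hazard ratios are reported per interquartile
exposure difference, `HR = exp(β(Q3−Q1))`, with
`CI = exp((β ± 1.96·se)(Q3−Q1))`; Q1/Q3 are computed on the analysis
cohort with the same percentile rule as normalization. HR is invariant
to affine rescaling of the exposure.

Across miRNAs both BH-adjusted p-values and Storey q-values are reported.
pi0 is estimated by smoothing `#{p > λ} / (m(1−λ))` over
λ = 0.05…0.95 with a cubic polynomial and evaluating at λ = 0.95, capped
at 1. When the estimate is ≤ 0 — the data suggest no true nulls —
q-values are reported as undefined (NaN) with a warning rather than
forced to zero.

## Synthetic data

The generator produces inputs with exactly the structure the analysis
assumes, under cohort conditions matching the emulated study population:
217 subjects, 77.9% colon, 54.4% male, 86.6% MSS, age 64.8 (SD 10.1),
stage mix 27/29/34/11%, and a 57.4% censored fraction.

* **Counts**: NB draws around `s_it·exp(a_g + u_ig + fc_g·tumor)` with
  lognormal library sizes (σ = 0.25 around 10⁶) and subject effects
  u_ig ~ N(0, 0.3) on the log scale; dispersion defaults to 0.3 and 0
  gives the Poisson limit. Pathway genes carry 2% of each library; the
  remaining protein-coding mass is one aggregated Poisson background row,
  so RPMPCG magnitudes and offsets behave like a genome-wide matrix
  without simulating one. Dispersion, subject variance and the mass
  fraction are free parameters — no published estimates exist for them.
* **miRNA intensities**: lognormal tumor/normal intensities around
  per-miRNA baselines with planted log fold changes, then per-sample
  lognormal scale distortions (σ = 0.2) that the upper-quartile
  normalization is expected to remove. Planted gene~miRNA effects rebuild
  the gene's differential from the linear model itself (Σ β·miRNA-diff +
  age/sex effects + noise scaled to the sd of the miRNA differential), so
  planted slopes are recoverable at a unit-free signal-to-noise;
  unplanted genes keep their count-derived differentials and serve as
  true nulls.
* **UTRs**: random background DNA with reverse-complement seed sites
  written in at recorded positions; backgrounds are redrawn to dodge
  accidental site occurrences (any that remain are recorded, not
  forbidden), and flanking bases are fixed so a planted 6/7-mer cannot be
  silently extended into a longer nested site.
* **Survival**: exponential event times under a proportional-hazards
  linear predictor on centered (age, sex, stage, exposure), with a single
  administrative censoring time solved by bisection so the expected
  censored fraction hits the target; `crc_death` is true exactly for
  simulated events.

Every generator is a pure function of its config including the seed, and
everything planted is recorded exactly once in the truth object.

**What passing tests show — and don't.** The simulations establish
internal validity: the estimators are calibrated and recover what was
planted under the generator's assumptions (NB2 counts, linear
associations, proportional hazards, exponential baselines, exact seed
complementarity). Real FFPE RNA-seq and array data violate these in ways
the generator deliberately does not model: no FFPE degradation or GC
effects, no probe-level artifacts, no within-pair correlation beyond a
shared intercept, no measurement error in covariates, and no wobble or
non-canonical miRNA sites. Results on real data inherit those caveats.

## Problem sizes and numerics

Monte-Carlo suite sizes were chosen to keep each check's binomial error
well inside its tolerance band: 500–600 null genes / replicates for
type-I rates (se ≈ 0.01 at the 0.05 level), 100–200 replicates for
recovery rates, 499–999 resamples for permutation and bootstrap nulls in
tests (10,000 remains the analysis default). IRLS and Newton iterations
converge on relative log-likelihood change < 1e-10 / 1e-9 with step
halving; linear predictors are clipped at ±200 (Cox) and ±500 (NB)
before exponentiation; bootstrap F statistics with zero numerator are
defined as 0. Degenerate inputs fail loudly: all-zero genes are
untestable, constant exposures give p = 1 (no information), empty
cohorts or filters raise errors naming the offending records.

## Known limitations

* The NB subgroup and survival machinery take whatever cohort they are
  given; multi-cohort designs (e.g. a larger survival cohort than the
  paired-expression cohort) are handled by running each cohort
  separately, not modeled jointly.
* The exposure entering the Cox model is the tumor-minus-normal
  differential, an analysis choice; tumor-only expression can be passed
  as the exposure matrix if preferred.
* The association screen fits one miRNA at a time; no multi-miRNA or
  mediation models.
* Seed matching is purely sequence-based: no thermodynamics, site
  accessibility, or conservation scoring.
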