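# Methods

## Problem and pipeline

The package implements the statistical pipeline of a prenatal-exposure
neuroimaging study design: does gestational exposure to traffic-related air
pollution (NO₂, PM₁₀, PM₂.₅) relate to neonatal brain morphology measured as
head-size-normalised regional volumes? Because the imaging cohort it
emulates is access-controlled, the pipeline is exercised end to end on a
synthetic cohort generator whose statistical structure is calibrated to the
published descriptive statistics, and whose exposure→brain association is
*planted* with exactly known strength, so every stage can be validated
against ground truth.

The stages, in order:

1. **Exclusion cascade** — sequential rules (maternal smoking, GA at birth
   ≤ 36 or ≥ 44 weeks, focal lesion, dropped twin, residence outside the
   exposure-model domain), each counting only subjects still remaining.
2. **Volumetrics** — relative volume = regional volume / ICV (denominator
   switchable to TBV, see below).
3. **Exposure windowing** — weekly concentrations from conception (week 0)
   to birth; whole-pregnancy mean is the unweighted weekly mean; trimesters
   cut after gestational weeks 13 and 26, the third running to birth.
   Trimester means are seasonally adjusted (below).
4. **Single-pollutant regression** — for each of the 8 regions × 3
   pollutants, OLS of relative volume on the windowed exposure adjusting
   for PMA at scan, GA at birth, sex, and IMD quintile; 95% t-based CIs;
   Benjamini–Hochberg FDR across the 24-test family of each window.
5. **Adjusted CCA** — pollutants residualized for IMD, relative volumes for
   PMA/GA/sex, both blocks column-standardized; classical CCA via SVD of
   the Cholesky-whitened cross-covariance, giving min(3, 8) = 3 modes;
   per-mode permutation validation; Spearman loading tables with FDR.

## Canonical correlation analysis

For blocks X (n×3) and Y (n×8) with sample covariances S_xx, S_yy and
cross-covariance S_xy, the solver computes the SVD of
L_x⁻¹ S_xy L_y⁻ᵀ, where S = L Lᵀ are Cholesky factors. The singular values
are the canonical correlations ρ₁ ≥ ρ₂ ≥ ρ₃ ≥ 0; weights are
a = L_x⁻ᵀ U, b = L_y⁻ᵀ V, so the canonical variates U_k = X a_k, V_k = Y b_k
have unit sample variance and are within-block uncorrelated. Sign
indeterminacy is resolved by forcing the largest-magnitude exposure-side
weight positive per mode. Singular within-block covariance raises an error;
regularized CCA is deliberately out of scope.

## Permutation validation

Shuffling the subject correspondence between the blocks breaks any true
association while preserving each block's internal covariance. Permuting
both blocks independently is distributionally identical to permuting one
relative to the other, so one fresh permutation of X's rows is drawn per
iteration (B = 1000 by default, minimum 100). For each permutation the CCA
is refitted and the Spearman correlation of each variate pair recorded.
Mode k is significant when its observed Spearman correlation exceeds the
95th percentile of its own null; the empirical p-value is
(1 + #{null ≥ observed}) / (B + 1), never exactly zero; passing modes are
BH-FDR adjusted.

**Known limitation (anti-conservative later modes).** Comparing observed
mode k against the k-th statistic of fully permuted data is only exact for
k = 1. When a strong true first mode exists, the observed second mode
behaves like the *first* mode of the residual system while its null was
built from data with no modes at all; at planted ρ = 0.5, n = 469 the
spurious mode-2/3 pass rate is roughly a third rather than 5%. The default
follows the per-mode procedure as published; `statistic="max"` switches to
a max-over-modes null (family-wise control) which removes the inflation at
the cost of power for genuinely multiple modes. Mode-1 inference — the
quantity the validation exists for — is exact either way: under the null
its pass rate is 5% by construction (verified empirically at 200 replicate
datasets).

## Loadings

Loadings are Spearman rank correlations (average ranks on ties) of each
*adjusted* variable with its own block's variate — the quantities that
actually entered the CCA — with two-sided p-values from the large-sample t
approximation and BH-FDR within each block's variable family (8 regions;
3 pollutants). R² = (Spearman R)² is reported alongside. With strongly
inter-correlated pollutants, loadings (C·w up to scale) differ markedly
from weights (w); reported mode patterns are loading patterns.

## Seasonal adjustment

Short exposure windows sample the annual pollution cycle unevenly, so
trimester means are adjusted by anomaly removal: the network-wide reference
series is reduced to a cyclic 52-bin week-of-year climatology (mean of all
subject-week observations per bin), and

    adjusted = raw − (reference mean over the window's bins − annual mean).

For a cyclic climatology the "52 weeks centred on the window" mean *is* the
annual mean, so the adjustment is defined for every window without edge
gaps; a missing bin raises a coverage error. Whole-pregnancy means are not
adjusted. On a cohort whose only exposure variation is a shared seasonal
signal, the adjustment removes > 99% of between-subject trimester variance.

## Synthetic cohort generator

The generator emulates, per subject: demographics (term GA ≈ N(40.1, 1.3²)
truncated to the observed range, preterm GA for the GA-excluded subjects,
log-normal scan delay, 44% male, deprivation quintiles with frequencies
(.10, .15, .20, .25, .30)); five disjoint exclusion-flag sets with
configurable counts (defaults 16/94/29/46/128 of 782); log-normal pollutant
and volume marginals whose medians and log-spreads (log(high/low)/6) match
the published medians and ranges; covariate effects of PMA/GA/sex on log
ICV and log regional fractions; a deprivation–exposure correlation
(default rank correlation −0.3, more deprived → more polluted); and weekly
exposure series = subject target + winter-high cosine anomaly + weekly
noise, with the anomaly and noise centred within the subject's gestation
window so the whole-pregnancy mean equals the latent target exactly.

**Planted mode.** Latents u, v share a common standard-normal factor with
corr(u, v) = ρ. In a whitened space the exposure block is
X̃ = u w̃ₓᵀ + E(I − w̃ₓw̃ₓᵀ) (noise projected off the signal direction, so
cov(X̃) = I), and similarly for Ỹ; colouring by C^{1/2} restores the
configured pollutant correlations. All cross-covariance is then the rank-1
matrix ρ·w̃ₓw̃_yᵀ, so the population first canonical correlation equals ρ
exactly and the population canonical direction equals the planted weight
vector — CCA is invariant to the colouring. Default exposure weights are
solved from the target loading pattern (−0.2, 0.2, 0.06) as C⁻¹·pattern;
brain-side weights are ventricle/cerebellum-dominant.

**What the generator does not emulate.** No spatial dispersion modelling or
postcode structure (a single latent spatial offset per subject); no
within-subject temporal autocorrelation beyond the shared seasonal cycle
(the weekly-noise scale is a free knob, not an estimate); exclusion flags
never overlap (the cascade handles overlap, the generator doesn't produce
it); volume marginals reproduce the published table's ICV-relative medians
verbatim even though those medians sum to ≈1.19 of ICV — an inconsistency
present in the source table itself (the values are plausibly TBV-relative);
the exp/log-normal transforms make covariate removal by linear
residualization approximate rather than exact (effects are a few percent
and absorbed by the tolerance of the recovery checks). Passing tests
therefore demonstrate the *pipeline's* correctness and calibration, not
fidelity of any particular real-world effect size.

## Numerical and design choices

- **Relative volumes** use the region/ICV ratio, not regression adjustment:
  only the ratio produces dimensionless medians of the published magnitude.
  The denominator is configurable (`icv` | `tbv`) because of the table
  inconsistency noted above.
- **Trimester boundaries** at gestational weeks 13 and 26 (t1 = weeks 0–13,
  t2 = 14–26, t3 = 27–birth), the common clinical convention; the
  duration-weighted trimester means recompose exactly to the
  whole-pregnancy mean.
- **Conception date** = birth date − GA; calendar weeks are 7-day bins of
  day-of-year folded to 52 bins.
- **IMD quintile** enters the regression as a single numeric covariate by
  default (4-dummy categorical coding available); sex is a 0/1 indicator.
  Sex cannot enter the CCA as a variable; sex-stratified subgroup runs are
  provided instead, and constant covariates within a subgroup are dropped
  from the residualization design.
- **Residualization** is column-wise OLS with intercept followed by
  standardization to unit sample variance (ddof = 1); residuals orthogonal
  to every covariate to < 1e-10; a residual column with zero variance
  (perfect confounding) is an error rather than silently standardized.
- **De-biasing recovered canonical correlations**: the fitted first
  canonical correlation exceeds the population value through overfitting
  (≈ 0.14 under the null at n = 469, p = 3, q = 8). Point recovery is
  therefore assessed on the quadrature-corrected value
  √(max(r̄² − r̄₀², 0)), with r̄₀ the mean null-data mode-1 correlation;
  linear subtraction of the null mean would over-correct (the bias adds
  roughly in quadrature, not linearly).
- **Descriptive tables** report medians and ranges (the variables are
  non-normal by construction); Shapiro–Wilk statistics are logged per
  variable but drive no branching.
- **Loading p-values** use the t approximation rather than exact Spearman
  permutation — the default documented choice; at n = 469 the two are
  indistinguishable at reported precision.
- Tie-breaks: Spearman uses average ranks; the BH step-up is the standard
  monotone-enforced adjustment (via statsmodels).

## Problem sizes used by the test and acceptance suites

Calibration and recovery properties are Monte-Carlo estimates at the study
scale (n = 782 enrolled → 469 analysed): 200 replicate datasets × 200
permutations for null calibration of the pass rule; 100 replicates at
planted ρ = 0.5 for power and recovered-correlation checks; 100 replicates
for regression-slope recovery and 40–60 null replicates for FDR behaviour;
20 seeded toy instances for the brute-force CCA oracle. These sizes put
Monte-Carlo noise comfortably inside the asserted tolerances while keeping
the whole suite a few minutes of single-core compute.

## Known limitations

- Per-mode permutation nulls are anti-conservative for modes ≥ 2 in the
  presence of a strong first mode (see above); interpret multi-mode
  significance with the max-statistic variant.
- The seasonal climatology is estimated from the cohort itself; with very
  small cohorts (tens of subjects) week-of-year bins may be unobserved and
  adjustment refuses to guess (coverage error).
- Planted regression slopes are additive on the relative-volume scale while
  the volume marginals are log-normal; the OLS estimand remains the planted
  slope, but the error distribution is mildly heteroscedastic.
- No regularized, sparse or kernel CCA; no cross-validated mode selection;
  no mixed-effects or robust-variance regression variants.
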