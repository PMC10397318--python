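# Methods

`cardiomr` implements the summary-statistics workflow of a large
resting-heart-rate (RHR) genetics study as a reusable, testable pipeline:
fixed-effects GWAS meta-analysis with its filtering and pruning rules,
instrument preparation for two-sample Mendelian randomization (MR), a suite
of univariable, multivariable and non-linear MR estimators with the
heterogeneity framework that selects the reporting model, meta-subtraction,
and conditional tissue-enrichment statistics.  Every stage can be exercised
on synthetic two-cohort data with known ground truth.

## Meta-analysis of summary statistics

Per-variant effects from $k$ studies are pooled by inverse-variance
weighting (the METAL fixed-effects scheme): $w_i = 1/\mathrm{se}_i^2$,
$\hat\beta = \sum w_i\beta_i / \sum w_i$, $\mathrm{se} = 1/\sqrt{\sum w_i}$,
with the pooled P from the pooled Z (not Fisher combination).  Before
pooling, standard errors are inflated by the square root of the supplied
genomic-control/LD-score-regression intercept; the package accepts any
inflation factor and never estimates one.  Alleles are aligned across
studies by label, by strand complement, or — for palindromic A/T and G/C
variants — by allele frequency, and only when both frequencies are
informative ($|\mathrm{EAF}-0.5| > 0.08$); ambiguous palindromes are dropped
with a reason.  Quality filtering retains variants with imputation INFO
$\ge 0.3$ and effective sample size
$N_\mathrm{eff} = N\cdot\mathrm{Info}\cdot 2\,\mathrm{MAF}(1-\mathrm{MAF})
\ge 25$.

Independent variants are chosen greedily by ascending P among genome-wide
significant variants ($P < 10^{-8}$), rejecting any candidate with
$r^2 \ge 0.005$ to an already-selected variant within 5 Mb (ties broken by
chromosome, then position, for determinism).  Loci are closed ±1 Mb
intervals around independent variants, merged when overlapping, keeping the
most significant variant as the locus top.  A sentinel replicates when it is
genome-wide significant in the meta-analysis, supported at $P<0.01$ in each
cohort alone, and direction-concordant; it is novel when more than 1 Mb
from every known locus boundary.

Meta-subtraction inverts the pooling algebra to recover the residual cohort
from a meta-analysis and one constituent: $w_r = w_m - w_c$,
$\beta_r = (w_m\beta_m - w_c\beta_c)/w_r$, $\mathrm{se}_r = 1/\sqrt{w_r}$.
Variants where the cohort carries at least the meta weight are dropped (the
inputs then contradict the subset assumption).  The round trip
`meta_subtract(ivw_meta(A, B), A) = B` is exact to numerical precision and
is asserted in the tests.

## Instrument preparation

Harmonization aligns outcome effects to the exposure effect allele, using
complements for strand flips and the frequency rule for palindromes, which
are dropped when the minor-allele frequency exceeds 0.42 on either side.
When a variant is missing from the outcome and an LD table lists a proxy
with $r^2 > 0.8$, the proxy substitutes (flagged).  On exit the exposure
effect and SE are divided by 5, so every causal estimate reads "per 5 bpm
of genetically predicted exposure".

Instrument strength uses $R^2 = t^2/(t^2 + n - 2)$ with $t = \beta/\mathrm{se}$
(this $t$-statistic form uses only fields the pipeline carries and is
algebraically consistent with $F = R^2(n-2)/(1-R^2) = t^2$, which the tests
assert).  Instruments with $F < 10$ are flagged weak but never excluded —
excluding them would compound winner's curse.  For binary outcomes the
observed-scale variance explained implied by the log-odds effect is
converted to the liability scale with the threshold-model correction
$R^2_\mathrm{liab} = R^2_\mathrm{obs}\,
\frac{K(1-K)}{\varphi(\Phi^{-1}(K))^2}\,\frac{K(1-K)}{P(1-P)}$
(population prevalence $K$, sample case fraction $P$); the transformation is
first-order accurate for the small per-variant effects of the GWAS regime
and is checked against a numerical integration of the threshold model.

Steiger filtering removes variants whose exposure correlation $\sqrt{R^2}$
is significantly smaller than their outcome correlation, by a one-sided
Fisher-z comparison with variance $1/(n-3)$ per cohort.  A variant whose
outcome $R^2$ is too small to estimate is kept: a true exposure→outcome
direction is then assumed.

## Univariable MR

All estimators consume the harmonized set $\{(\hat\beta_{Xj},
\hat\beta_{Yj}, \mathrm{se}_{Yj})\}$:

* **Wald ratio** $\hat\beta_{Yj}/\hat\beta_{Xj}$ with first-order delta SE.
* **IVW** — weighted regression through the origin, weights
  $1/\mathrm{se}_{Yj}^2$.  The multiplicative random-effects (MRE) variant,
  the reporting default, scales the SE by $\max(1, \sqrt{Q/(k-1)})$: the
  conventional definition, floored at the fixed-effects SE so heterogeneity
  can never make the estimate look more precise.
* **MR-Egger** — adds an intercept (the directional-pleiotropy estimate)
  after orienting every pair to positive exposure effect, since Egger
  regression is orientation-dependent.  $I^2_{GX} = (Q_{GX} - (k-1))/Q_{GX}$
  summarizes instrument measurement error; values above 95% indicate low
  regression-dilution risk for the Egger slope.
* **Weighted median** of the per-variant ratios with weights
  $1/\mathrm{se}^2_\mathrm{wald}$, interpolated between order statistics at
  cumulative weight 0.5; SE by seeded parametric bootstrap.
* **MR-Lasso** — per-variant intercepts under an L1 penalty; the penalty is
  relaxed along a geometric path and the tuning value is the largest penalty
  at which the retained (zero-intercept) set's Cochran Q stays below the
  $\chi^2$ critical value at df = retained − 1, $\alpha=0.05$.  The reported
  estimate is plain IVW on the retained set, so a homogeneous input
  reproduces IVW exactly.
* **Contamination mixture** — profile likelihood over a 1000-point grid
  spanning median(ratio) ± 5·MAD (normal-consistent MAD); each variant
  contributes the larger of a valid ($N(\theta, \mathrm{se}^2)$) and invalid
  ($N(0, \psi^2 + \mathrm{se}^2)$) log-density, with $\psi$ defaulting to
  the SD of the ratios.  The 95% confidence set
  $\{\theta: 2(\ell_{max}-\ell(\theta)) \le \chi^2_1(0.95)\}$ may be a union
  of disjoint intervals; all components are reported.

The **Rücker framework** computes the IVW heterogeneity $Q$, the Egger
heterogeneity $Q'$, their difference (a 1-df test of the intercept under
fixed-effects weighting), $I^2 = (Q-(k-1))/Q$ truncated at 0, and the Egger
intercept with its MRE-scaled P.  Reporting moves from IVW to Egger only
when both $P(Q-Q') < 0.05$ and the intercept P $< 0.05$; otherwise IVW (with
MRE scaling when $P(Q) < 0.05$) is reported.  Simulation tests verify the
decision fires in ≥90% of replicates under strong directional pleiotropy
(mean direct effect 0.05 across 50 instruments) and in ≤10% under balanced
pleiotropy of the same scale.

The Wald discovery scan flags variants whose per-variant causal estimates
reach $P < 0.05/493$ in two outcome cohorts with concordant direction while
the variant itself is not genome-wide significant ($P < 5\times10^{-8}$) in
either outcome GWAS — candidate outcome loci found through the exposure.

## Multivariable MR

Outcome effects are regressed jointly on the $k\times p$ exposure-effect
matrix, weighted by the inverse outcome variance only (exposure-side
uncertainty is not propagated into the weights, matching the method's
standard construction).  Egger adds an intercept after orienting to the
first exposure; Lasso applies the univariable tuning rule with per-variant
intercepts; the weighted median solves the estimating equations by
coordinate-wise weighted medians of partial ratios with bootstrap SEs.
Instrument strength per exposure is the conditional statistic $Q_{xj}$: the
inverse-variance-weighted residual heterogeneity of exposure $j$'s effects
after regression on the other exposures' effects, compared to the
$\chi^2_{k-1}$ critical value at 0.05 (at or below → weak flag).  Pleiotropy
is flagged when the MV-IVW weighted residual sum of squares $Q_a$ exceeds
the $\chi^2_{k-2}$ critical value.  Attenuation of a total effect by a
secondary exposure is $100(1 - \hat\beta_\mathrm{direct}/
\hat\beta_\mathrm{total})$ on the log-odds/log-hazard scale, with a CI from
parametric simulation of the two estimates assuming independence — the
ratio-of-log-effects convention, adopted because the attenuation is a
statement about regression-scale effects.

## Non-linear MR

A weighted genetic risk score (GRS) $\sum_j w_j g_{ij}$ is divided by 5 so a
unit score is 5 bpm of genetically predicted exposure.  The exposure is
residualized on the score (and covariates); stratifying on this residual
rather than the raw exposure avoids collider bias because the residual is
not downstream of the instruments — the tests verify the score distribution
stays homogeneous across strata.  The residual is cut into 30 equal-count
quantile strata (rank-based, stable ties).  In each stratum the
GRS→exposure coefficient (linear) and GRS→outcome coefficient (linear,
logistic, or Cox) give the localized average causal effect
LACE = $\hat\beta_\mathrm{out}/\hat\beta_\mathrm{exp}$ with first-order
delta SE using the outcome SE only (exposure-coefficient noise is
second-order for strong scores).

The LACE are meta-regressed (weights $1/\mathrm{se}^2$, known variances) on
the **derivative** of fractional-polynomial shapes of degree 1 and 2 over
powers $\{-2,-1,0,0.5,1,2,3\}$ (power 0 = log; repeated powers use the
standard log-augmented basis), evaluated at the stratum mean exposure minus
an offset of 45 bpm — the offset keeps the transformed exposure positive
and close to zero where the family is most flexible; post-offset values
must stay positive or the fit refuses.  The best model per degree minimizes
the weighted RSS; degree 2 is chosen only when it beats degree 1 in a 2-df
LRT at 0.05.  The causal curve is the integral of the fitted derivative
anchored to zero at the 70 bpm reference, with a pointwise delta-method 95%
band; exponentiation to OR/HR happens only at presentation.

Three non-linearity tests are reported: a trend test (meta-regression slope
of LACE on stratum mean exposure, inverse-variance weighted), Cochran's Q
about the weighted LACE mean, and the fractional-polynomial test — the LRT
of the selected model against the linear (constant-LACE) model, referred to
$\chi^2$ with df equal to the selected degree.  The df convention is the
package's own: each degree contributes one power/coefficient pair beyond
the linear trend.  The one-parameter degree-1 shapes are not mutually
nested, so under a linear truth the selected degree-1 model is almost
always the linear one itself and rejections flow through degree-2
selection; calibration tests confirm the construction is near-nominal
(type-I error within [0.02, 0.08] at $\alpha = 0.05$), where the
function-selection df counting (3 for degree 2) was measurably
over-conservative in this two-stage setting.  The same trend/Q pair applied
to the GRS→exposure coefficients across strata checks instrument
homogeneity.

## Conditional tissue enrichment

Given tissue Z-scores and their correlation matrix, the top tissue $t$ is
conditioned out via $z_s' = (z_s - \rho_{ts} z_t)/\sqrt{1-\rho_{ts}^2}$ and
removed; the step repeats on the current signed maximum while it is at
least 2.585 (the lowest Z with FDR < 0.05 in the upstream enrichment
engine; the FDR mapping is documented, not recomputed).  Ties break by
label order.  After each step the remaining correlations are replaced by
partial correlations given the conditioned tissue (default), because
re-applying the update with stale correlations double-counts shared signal;
the stale-correlation behaviour is available behind a flag for comparison.
Tissues perfectly correlated with the conditioned one are removed with a
reason.

## Synthetic data

The generator emulates the study design: two non-overlapping cohorts drawn
from independent random streams of one seed (separate sub-streams per stage
— genotypes, noise, outcome, censoring — so changing one stage never
cascades), sharing a genetic architecture of `n_variants` Hardy–Weinberg
binomial variants with MAF uniform on a configurable range.  Optional LD
uses a blockwise latent Gaussian copula thresholded to allele indicators —
simple, with controllable within-block correlation for pruning tests, but
not a realistic human LD map.  Per-allele effects (bpm) are scaled so the
genetic variance share of the exposure equals `exposure_h2`; the exposure
is Gaussian around 69.3 bpm with SD 11 bpm, matching the study population.
An optional standard-normal confounder feeds both exposure and outcome; the
variance budget $h^2\sigma^2 + \gamma_c^2 \le \sigma^2$ is enforced.

Defaults are the study conditions: 150 instruments, 50k individuals per
cohort, and `exposure_h2 = 0.30`.  The variance share controls regression
dilution directly: the IVW attenuation factor equals
$I^2_{GX} = \sum\beta_X^2 / (\sum\beta_X^2 + \sum \mathrm{se}_X^2)$.
Because summary statistics come from *marginal* per-variant regressions,
each exposure SE carries the full phenotypic variance (the other variants'
genetic contribution stays in the residual), so at these sample sizes
$1 - I^2_{GX} \approx m\,\overline{1/2pq}\;\overline{2pq}/(n\,h^2) \approx
0.0036/h^2$; 30% keeps dilution near 1% of the effect ($I^2_{GX}\approx
0.99$, mean per-variant F ≈ 100), the regime the recovery and coverage
validation presumes.  This deliberately
exceeds the variant-set R² of real heart-rate GWAS (~5% across ~500
variants): the generator emulates a dilution-free instrument panel, not the
polygenic background, and the coverage results do not speak to designs with
substantially weaker instruments.  The default causal effect is 0.04 per
bpm (0.2 per 5 bpm).

Invalid instruments receive direct outcome effects: balanced pleiotropy
draws $N(0,\mathrm{scale}^2)$; directional draws half-normal magnitudes
aligned with the exposure-increasing allele, so the pleiotropy remains
directional after Egger orientation.  Outcomes are continuous (Gaussian
noise, configurable SD), binary (logistic with intercept set from the
target prevalence), or time-to-event (Weibull proportional hazards with
inverse-transform sampling and administrative censoring tuned to the target
censoring fraction).  Non-linear causal curves (quadratic, threshold) are
evaluated on the centred exposure.  Phenotypic outliers beyond 4 SD are
excluded before association, mirroring GWAS practice (configurable off),
and a medication option adds a constant (+15 by default, +10 intended for
diastolic-like traits) to a treated fraction of a blood-pressure-like
outcome.  Cohorts reduce to summary statistics by marginal per-variant
regression — vectorized closed-form OLS for continuous traits, per-variant
logistic or Cox fits otherwise.

What the generator does **not** emulate: realistic LD structure,
imputation-error patterns (INFO is always 1), relatedness, population
stratification, assortative mating, or selection into the sample.  Passing
tests therefore demonstrate the estimators' statistical behaviour under the
model assumptions, not robustness to those real-data complications.
BMI-like heritable covariates are not simulated; the regression interfaces
accept arbitrary covariate lists so real covariate sets can be supplied.

## Validation studies and problem sizes

`cardiomr.studies` packages the replicated experiments the test-suite
asserts on: parameter recovery (200 replicates of the two-sample design —
150 instruments, 50k/50k, truth 0.2 per 5 bpm, outcome noise SD 2 so the
realized IVW standard error sits near 4% of the effect, comparable to
rather than far tighter than consortium MR precision; IVW-MRE mean bias
< 0.01 and 95% CI coverage in [0.92, 0.98]),
robustness (60 replicates with 30% directional-invalid instruments at
cohorts of 20k with 100 instruments — sized so every instrument stays
individually strong while each replicate runs in well under a second;
weighted median, MR-Lasso and the contamination mixture must each show less
than half the IVW bias), Rücker decision rates (200 replicates per
pleiotropy mode at the summary level), and non-linear MR calibration
(500 null / 200 power replicates at n = 60k, 25 instruments, 30 strata;
the quadratic power scenario uses curvature of $5\times10^{-4}$ per bpm²,
about five trend-SE at the realized precision).  The acceptance script
reports the same quantities at 300/150 non-linear replicates.

## Numerical choices and degenerate inputs

Normal quantiles go through `scipy`'s inverse error function, never
tables.  The weighted median interpolates order statistics at cumulative
half-weight.  MR-Lasso's coordinate iteration stops at $10^{-12}$ absolute
change, over a 100-point geometric penalty path spanning four decades.
Cochran statistics are truncated at zero before $\chi^2$ referencing.
Degenerate inputs fail loudly: constant traits, monomorphic variants,
rank-deficient designs, all-equal exposure effects in Egger, empty
harmonized sets, subtraction of a non-subset cohort.  A noise-free
simulated trait floors the regression SE at $10^{-12}$ so the record stays
representable.

## Known limitations

Proxy lookup requires an explicit LD table; there is no reference panel.
Multi-allelic variants and indel normalization are out of scope, as are
correlated-instrument IVW, MR-PRESSO, mode-based estimation and
colocalization.  The contamination-mixture $\psi$ and grid defaults are
heuristics, configurable by callers.  The attenuation CI assumes the total
and direct estimates are independent, which overstates its width when both
derive from overlapping instrument sets.  Chow tests use the classical
homoscedastic form (synthetic cohorts are unrelated; no cluster-robust
variant).
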