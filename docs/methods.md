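# Methods

This package implements a two-phase, epigenome-wide search for high-order
gene–smoking interactions on overall survival in early-stage non-small
cell lung cancer (NSCLC), together with the downstream analyses that such
a finding feeds: an integrated risk score with quartile subgroup
comparisons, discrimination analysis of nested prognostic models, and a
methylation–expression cis-regulation follow-up. Everything runs end to
end on synthetic multi-center cohorts, so the statistical machinery can
be exercised and audited without access to the original patient data.

## The model

The core model is a histology-stratified Cox proportional-hazards model.
For patient *i* in histology stratum *s* (LUAD or LUSC),

    h_i(t) = h_0s(t) · exp( Σ_j α_j · covariate_ij + Σ_S β_S · Π_{v∈S} x_iv )

where the covariates are age, sex, smoking status (never/ever/current),
clinical stage (I/II) and study center (reference-coded indicators), and
the second sum runs over the factorial interaction hierarchy of the k
interacting variables: pack-years of smoking (the environmental
exposure) and k−1 CpG methylation probes. Methylation enters on the
0–100 percent scale everywhere, so each β is a log hazard ratio per one
percentage point of methylation; hazard ratios print in the familiar
0.999x range.

Two term schemes are supported. `full_factorial` uses all 2^k − 1
products (15 terms at k = 4), which keeps the hierarchy complete.
`as_printed` reproduces the 14-term integrated-score formula as
published, which omits the exposure × probe2 × probe3 triple. The
default is `full_factorial`; the discrepancy between the two is
surfaced, not silently resolved, and either can be selected.

### Fitting

The stratified partial likelihood is maximized by Newton–Raphson with
step-halving, Efron tie handling by default (Breslow optional), and
convergence at gradient max-norm < 1e-8. Design columns are internally
centered and scaled to unit variance — the partial likelihood is
invariant to location shifts, and scaling a column by c divides its
coefficient by c exactly — which keeps the observed information well
conditioned even though raw-scale four-way products span ~1e6 and are
correlated above 0.97 with their lower-order parents. The covariance is
the inverse observed information mapped back to the original scale.
Singular designs (no within-stratum contrast, or collinear columns) are
detected up front by a QR factorization of the stratum-centered design
and reported with the offending column names. Monotone-likelihood
escapes are flagged when any per-unit log hazard ratio exceeds 20.

The fitter is validated against two independent oracles: direct
Nelder–Mead maximization of the literally coded partial likelihood on
small fixtures, and the `lifelines`/R `survival::coxph` implementations
(agreement to ~1e-7 in coefficients, including Efron tie handling to
1e-12 against R).

## The two-phase scan

The scan follows a hill-climbing (greedy order-escalation) strategy.
Given the already validated set of k−2 probes, every remaining
QC-passing probe X is slotted into the order-k model, and the Wald test
of the single highest-order coefficient is recorded. Per scan,
Benjamini–Hochberg q-values are computed over converged candidate fits
(non-converged candidates are excluded from the multiplicity correction
and counted in the table metadata). A candidate is confirmed when

1. FDR-q ≤ 0.05 in the discovery cohort,
2. P ≤ 0.05 in the independent validation cohort, and
3. the effect direction agrees between phases.

Confirmed probes are refit on the pooled cohort with the phase folded
into the center covariate block. When several probes pass, the one with
the smallest discovery p is appended (the tie-break matters only in
simulation; the motivating study had a single passer). The escalation
stops at the first order with no passer.

The tested "interaction effect" is the single top coefficient's Wald
statistic, matching the single-HR reporting convention of the field; a
likelihood-ratio variant was examined during development and behaves
identically at these sample sizes (see *Small-sample calibration*).

## Quality control

Probe-level rules, applied with first-failing-rule attribution in a
fixed order: (a) detection p > 0.05 in strictly more than 5% of samples;
(b) coefficient of variation (sd/mean on the beta scale, sample sd)
below 5%; (c) constant methylation state, operationalized as all betas
≥ 0.9 or all ≤ 0.1 (configurable — the criterion has no standard numeric
definition); (d) SNP-flagged probes; (e) cross-reactive probes (flag or
user blacklist); (f) failure of any data-driven rule (a–c) within any
single study center. Samples are removed for > 5% undetectable probes or
a missing pack-year value. Both ">5%" thresholds are strict
inequalities; the boundary convention is tested explicitly.

`normalize_batches` is a deliberate location–scale stand-in: per batch
and probe, mean and sd are mapped onto the pooled reference and the
result is clipped to [0, 1]. Array-specific pipelines (quantile
normalization, type I/II probe-chemistry correction, empirical-Bayes
batch adjustment) are out of scope here, and no claim is made that the
stand-in reproduces them.

## TRIUNE, subgroups, and the effect surface

The integrated score (TRIUNE) is exactly the fitted model's linear
predictor: the weighted sum of all covariates, main effects and
interaction products, with weights from the four-way Cox fit. There is
no intercept or baseline-hazard term, so the score is only defined up to
location for comparisons — quartile grouping, Kaplan–Meier curves and
group hazard ratios are all location-invariant.

Quartile cutoffs are the empirical 25/50/75 percentiles; values equal to
a cutoff go to the lower group, making the grouping deterministic under
ties and exactly equal-sized when n is divisible by 4 with distinct
scores. Group hazard ratios (Groups 2–4 vs 1) are marginal by default,
with a covariate-adjusted variant behind a flag. Kaplan–Meier curves use
`lifelines`; the median is the smallest time with S(t) ≤ 0.5, and its
confidence interval comes from the log-log confidence band
(Brookmeyer–Crowley style). The clinical comparator score is the linear
predictor of the covariates-only Cox model, grouped by its own
quartiles.

Scoring the estimation sample with in-sample weights reproduces the
published analysis and its optimism; the scoring functions accept a fit
from any cohort, so honest out-of-sample scoring is one argument away.

The forest analysis reports the hazard ratio of the score per 1 SD
within levels of each clinical factor (per-unit log hazard of a linear
predictor is scale-dependent and uninterpretable across refittings);
strata under 10 samples or 3 events are skipped with a warning.

The conditional effect surface evaluates the model-implied log hazard
ratio of the scanned probe X per 1% as a function of exposure and the
first partner probe, with the second partner fixed at a subgroup value
(e.g. the median of its low/high halves): the sum of every X-bearing
term's coefficient times the product of its other variables. This is the
literal closed form implied by the factorial model, evaluated on a grid
and exported as a tidy table.

## Prediction evaluation

Time-dependent discrimination uses the cumulative/dynamic AUC with
inverse-probability-of-censoring weights (IPCW): at horizon τ, cases are
events by τ weighted by 1/G(T−), controls are patients at risk past τ
weighted by 1/G(τ), with G the Kaplan–Meier estimate of the censoring
distribution (pooled, not stratified — the common default of
time-dependent ROC software). With no censoring before the horizon the
estimator reduces exactly to the Mann–Whitney AUC of the binary
event-by-horizon label; it also agrees with scikit-survival's
`cumulative_dynamic_auc` to machine precision on censored data. The AUC
variance is the projection (influence-function) variance of the weighted
two-sample U-statistic with weights treated as fixed; the extra
variability from estimating G is ignored, a documented simplification.

Comparing two models' AUCs on the same samples is exactly DeLong's
correlated-ROC test whenever the horizon reduction is uncensored, and
otherwise a Wald test on the AUC difference using the paired influence
variance; the output labels which branch was used. The relative AUC
increase is 100·(AUC_big − AUC_small)/AUC_small.

Harrell's C treats a pair as orderable when the shorter observed time is
an event (time ties are orderable only when exactly one member is an
event); concordance gets full credit, score ties half. Pairs of events
at identical times are not orderable under this convention.

The nested comparison fits (a) covariates only, (b) covariates plus all
elements of the three-way interaction, (c) covariates plus all elements
of the four-way interaction, scores in-sample, and evaluates AUC at 3
and 5 years plus C per model.

## Expression link

Methylation–expression association uses ordinary least squares of
(standardized) expression on the methylation beta value plus the same
clinical covariates; the reported estimate is the methylation slope, the
p-value its t-test, and the partial correlation is derived from the t
statistic. Only probes involved in the integrated score are tested
against all genes, with BH q-values over the tested pairs. A probe is a
cis-regulation (eQTM) candidate for a gene when it lies within 1 kb of
the gene-body interval (1-based inclusive coordinates, distance 0 inside
the body, strand ignored — the window anchor is not standardized, and
gene-body anchoring is the simplest defensible choice) and the
association has P ≤ 0.05; both boundaries are inclusive. The gene-level
four-way re-test reuses the factorial Cox machinery with standardized
expression in place of percent methylation.

## Synthetic cohorts

The generator emulates the structure of the motivating study
populations, and its defaults are the study conditions:

- **Discovery**: four centers × 131 patients (n = 524), 81% LUAD,
  censoring target 0.479, administrative horizon 15 y, baseline hazards
  0.13/y (LUAD) and 0.17/y (LUSC) giving ~5 y median survival.
- **Validation**: one center (n = 468), 48.5% LUAD, no never-smokers,
  censoring target 0.7607, horizon 6 y, higher baseline hazards —
  the short-follow-up, heavily censored regime of the public validation
  cohort.
- **Covariates**: age ~ N(66.6, 9.7²) clipped to [30, 95]; 55.4% male;
  smoking never/ever/current = 0.08/0.61/0.31; stage II 30%; pack-years
  gamma-distributed with mean 43.36 and SD 31.10 among smokers and
  exactly 0 for never-smokers.
- **Methylation**: per-probe Beta(a, b) with the mean drawn from a
  hypo/hemi/hyper regime mixture over [0.2, 0.8] and concentration in
  [15, 50]; planted probes are pinned to mean 0.5, concentration 30, so
  their CV comfortably clears the 5% QC rule. Detection p-values are
  Uniform(0, 0.01) except a configured fraction forced above 0.05.
- **Survival**: event times are inverse-transform exponential draws with
  rate λ0(histology)·exp(lp). Censoring is the minimum of the
  administrative horizon and an independent exponential whose rate is
  calibrated by root-finding against the realized event times so the
  expected censoring fraction hits the target; the calibration is
  deterministic given the seed, and realized fractions land within
  ±0.05 of target for n ≥ 400.
- **Covariate effects** (log-hazard): age 0.02/y (centered at the age
  mean), male 0.15, ever 0.10, current 0.25, stage II 0.45. The
  motivating study reports no covariate effect sizes, so these are
  field-plausible placeholders, not estimates of any real cohort.
- **Planted interactions** are specified per factorial term
  (`"E:G1:G2:X"` etc.) and, by default, applied to centered variables
  (exposure minus its mean, percent methylation minus 50). The expansion
  of a centered product is an exact linear combination of the raw
  factorial terms with the *same* top-order coefficient, so the planted
  value remains the estimand of the fitted raw-scale model while the
  linear predictor stays bounded (|lp| > 50 raises an error advising
  rescaling). The default planted four-way coefficient, −1.6e-5 per
  (pack-year × %³), was calibrated once so the two-phase design detects
  the planted probe with ≈80% probability at n = 1000 discovery / 500
  validation among 2000 probes.
- **Expression**: each cis gene is r·z(beta) + √(1−r²)·noise,
  standardized per gene; extra independent genes pad the matrix. Gene
  intervals for cis genes are placed 200 bp from their probe.
- One integer seed drives everything through named sub-streams;
  identical configs give byte-identical bundles.

What the generator does **not** emulate: array chemistry (type I/II
probes, color channels), realistic batch effects beyond a per-center
location option, correlated CpG neighborhoods, genomic covariance
between probes, or non-proportional hazards. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
stated generating model, not robustness to real-array artifacts.

## Small-sample calibration of the top-order Wald test

A finding of this implementation worth stating plainly: under the global
null, the Wald test of the highest-order coefficient in the 15-term
factorial model rejects at ~0.075 instead of 0.05 at n ≈ 300–1000, and
only reaches nominal level around n ≈ 4000. The inflation is not a
defect of this fitter — R's `survival::coxph` reproduces it on identical
data, and the likelihood-ratio test behaves the same — but a consequence
of the tiny effective information left for the top term after partialling
out 14 near-collinear lower-order products. Two consequences are
measured honestly by the acceptance checks: the two-phase null
false-positive rate comes out near 0.006 rather than the idealized
0.05 × 0.05 = 0.0025, and the BH q ≤ 0.05 selection over-fires under the
global null at these cohort sizes. Users planning a study at desk scale
should treat the nominal two-phase false-positive arithmetic as a lower
bound.

## Problem sizes used by the test suite

The default suite scales simulations to keep a full run short: the
two-phase null check uses 30 cohort pairs (500 probes, n = 300 per
phase); planted-signal recovery uses 15 fixed seeds with 400 probes
(n = 1000/500); null calibration uses 1000 replicate fits (n = 300) and
40 replicate scans of 300 probes; estimator oracles use 1000 random
fixtures each. `scripts/acceptance.py` runs the two-phase null
simulation at 200 pairs.

## Known limitations

- Complete-case handling only; no imputation of covariates.
- No proportional-hazards diagnostics, time-varying effects, or
  penalized/robust variance options.
- The IPCW AUC variance ignores the estimation of the censoring
  distribution.
- In-sample evaluation reproduces the published workflow; optimism is
  not corrected.
- The batch stand-in is location–scale only.
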