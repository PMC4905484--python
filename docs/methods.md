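# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that would otherwise be
invisible in the code.

## Quantification model

Raw qPCR data are cycle thresholds Ct(assay, well) in cycles; one cycle
≈ a two-fold difference in template abundance, and lower Ct means more
abundant. Wells reported as `Undetermined`, empty, or at/above the
detection ceiling are stored *at* the ceiling (default 40 cycles,
configurable) with an undetected flag. This mirrors instrument-export
practice and keeps ceiling values available as presence/absence
information for screening, while disqualifying any assay with an
undetected well from reference candidacy — a normalizer that drops out
in some samples is useless.

Relative expression is the −ΔΔCt level: ΔCt subtracts the reference
assay's Ct within each well, ΔΔCt subtracts the per-assay mean ΔCt of
the baseline (control) group, and the stored level is −ΔΔCt, so
positive values are up vs controls on a log2-like scale. The
fold-change view 2^(−ΔΔCt) is exposed but all downstream statistics use
−ΔΔCt: the rank tests are invariant to the choice, and the logistic and
Cox coefficients are more interpretable per log2 unit than per fold.
Technical duplicate wells are averaged on the Ct scale *before* ΔCt
(the mean cycle threshold of the replicate measurements enters the
analysis); averaging after ΔCt would give the same answer only because
ΔCt is linear, and the before-ΔCt convention is the one fixed and
tested here.

Two invariants pin the arithmetic down: adding a constant to every Ct
of one well (a pure loading/yield effect) leaves all relative levels
unchanged, and one extra cycle in a target assay lowers its relative
level by exactly 1.

## Reference selection

Per array card, candidates must have mean Ct ≤ `max_mean_ct` (default
35 cycles — "high yield" has no canonical number; 35 keeps assays
comfortably clear of the 40-cycle ceiling) and no undetected wells.
The `k` = 6 lowest-SD candidates per card form the shortlist; ties
break lexicographically by assay name (as do all ties downstream).
Each shortlisted assay is then tested for group neutrality: two-sided
Mann–Whitney for control vs all patients, and Kruskal–Wallis across all
groups present. Rank tests were chosen because the discovery design has
only 10 samples per group and plasma Ct distributions are not reliably
normal. A candidate qualifies only if **both** p-values exceed α
(default 0.05); the chosen reference is the qualifying assay of
smallest SD. If no shortlisted assay qualifies the stage fails loudly,
listing every candidate's p-values.

A deliberate consequence of testing neutrality at α = 0.05: a truly
neutral assay still fails one of the two correlated tests in roughly
8–10% of cohorts. That is why the generator plants *several* stable
assays per card (see below) — with one stable assay per card, selection
would fall through to an ordinary assay in ~1 cohort in 10 by
construction, no matter how good the implementation.

Pairwise-stability algorithms (geNorm, NormFinder) are intentionally
out of scope; the three criteria above are the pipeline's definition of
a usable reference.

## Screening

Seven two-group contrasts cover the clinically meaningful questions:
presence of disease, early-stage detection, late-stage separation,
metastasis, and the stage II vs III boundary that drives adjuvant
chemotherapy decisions. The default test is the two-sided Mann–Whitney:
exact enumeration when the combined n ≤ 20 and the pooled values are
tie-free, otherwise the normal approximation with tie correction and
continuity correction. Student's t (equal-variance, two-sided) is
available by configuration and every output row records which test
produced it. The effect measure is the difference of group medians of
the relative level — direction is what matters clinically; magnitudes
on the −ΔΔCt scale are reported but not thresholded.

No multiple-testing correction is applied by default: each assay is
screened at the nominal two-sided α = 0.05, accepting ~5% false
positives per comparison across the array as the price of sensitivity
in a discovery phase whose output is re-tested in validation.
Benjamini–Hochberg per comparison is one flag away, and the selected
set under BH is provably a subset of the uncorrected one at equal α.
A "trend" band (α ≤ p < `alpha_trend`, default 0.06) flags borderline
assays without selecting them; promotion of a trend assay into
validation is an explicit analyst decision, never automatic.

The heat-map export z-scores each assay row to mean 0 and **population**
(ddof = 0) SD 1 across samples; zero-variance rows are an error rather
than silently dropped. No clustering is applied — samples stay in stage
order.

## Evaluation

Candidates are evaluated per clinical contrast (patients vs controls,
III–IV vs I–II, IV vs I–III) as univariate logistic models on the
−ΔΔCt scale, fitted by maximum likelihood (statsmodels Newton).
Quasi-perfect separation is detected (diverging coefficients or fitted
probabilities equal to the labels) and raised as an explicit error.
The per-contrast winner maximizes AUC by default (AIC optional); using
the fitted probability as the score makes the model's AUC equal the raw
marker's AUC up to coefficient sign, so the leaderboard is effectively
ranking markers by discrimination with the orientation learned from
data rather than assumed.

AUC is the rank statistic (concordance probability, ties ½), identical
to the trapezoidal area under the empirical ROC curve. Its standard
error is Hanley–McNeil with Q1 = A/(2−A), Q2 = 2A²/(1+A) and the 95% CI
is A ± 1.96·SE clipped to [0, 1]. Hanley–McNeil was fixed as the
default because it needs only (A, n⁺, n⁻); note its moments are exact
under the bi-exponential ROC model and conservative (SE too large by up
to ~20%) for well-separated Gaussian scores. The operating cutoff
maximizes Youden's J = sensitivity + specificity − 1 over midpoints
between adjacent distinct scores with the decision rule
"score ≥ cutoff ⟹ positive"; J-ties break toward higher sensitivity,
then the lower cutoff (a screening context prefers sensitivity). A
closest-to-(0,1) criterion is available by configuration. Describing
the cutoff as "maximizing the AUC" is a category error a single point
cannot commit; Youden's J is the standard reading and the one
implemented.

## Survival

For each marker, patients are split at the **mean** of their relative
levels: strictly above → high, at or below → low. The boundary
convention matters only for discrete data but is fixed and tested.
Degenerate splits warn and are refused by the two-group analyses
downstream. Arms are compared with the product-limit (Kaplan–Meier)
estimator and the two-group log-rank test (hypergeometric moments
summed over distinct event times, chi-square with 1 df); an optional
permutation p-value re-randomizes arm labels for small samples.

The multivariable Cox model codes each contrast's first-listed level
as 1: stage III–IV, CEA > 5 µg/L (exactly 5 → 0), age ≥ 55, female,
chemotherapy yes, marker high. Markers enter the model when their
univariate log-rank p is below `cox_marker_alpha` (default 0.05).
Patients missing survival or any covariate are dropped from survival
analyses only — never from marker evaluation — and reported. Ties are
handled with Efron's approximation (the lifelines implementation);
survival times in the synthetic cohorts are continuous, where Efron,
Breslow and the exact likelihood coincide, and a Breslow
partial-log-likelihood reference implementation is exposed for
verification. Survival time is taken as given in months (diagnosis to
death or last follow-up); the pipeline never recomputes dates. No
time-dependent covariates, competing risks, or proportionality
diagnostics — the proportional-hazards assumption is a documented
caveat, not a tested one.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with every
planted effect listed in a machine-readable truth table:

* **Panel**: 754 assays over cards A/B (377 each); baseline mean Ct ~
  U(22, 38) cycles, per-assay biological SD ~ U(0.3, 1.5) cycles —
  order-of-magnitude choices for plasma qPCR surfaced entirely in the
  config, not estimates of any particular dataset. 30 assays sit above
  the ceiling in every sample (flat Ct 40), exercising the
  zero-variance filter the way dropout assays do on real cards.
* **Markers**: group-wise shifts planted on the Ct scale so they
  propagate through normalization exactly as real signal would.
  Defaults: detection −1.5 cycles in all stages; early-stage −1.2 in
  I–II; late-stage −1.8 in III–IV; metastasis −2.5 in IV only;
  stage-II-vs-III −1.5 in II. The early/late asymmetry (−1.2 vs −1.8)
  is deliberate: with equal shifts the two markers are *exactly*
  equally informative for the III–IV vs I–II contrast and "the best
  marker" would be undefined; the asymmetry gives every evaluation
  contrast a unique planted winner. Marker biological SD is 0.8
  cycles.
* **Stable assays**: three per card with SD 0.12–0.20 cycles, no group
  shift, high yield — endogenous-control analogues. Three per card
  (not one) because neutrality testing at α = 0.05 rejects a truly
  neutral assay in ~10% of cohorts (see above); recovery is scored as
  "the chosen reference is one of the planted stable assays".
* **Validation**: 47 controls + 187 patients (38/50/50/49 by stage)
  with the exact sex (22/99 male), surgery (156 yes), chemotherapy
  (144 yes / 42 no / 1 missing) and missing-survival (13) composition
  of the emulated population; duplicate wells with 0.15-cycle
  technical SD; a spike-in assay (SD 0.08) as normalizer.
* **Survival**: exponential baseline hazard (default 0.008/month) with
  log-linear terms: +1.1 for stage III–IV and +0.9 per prognostic
  marker's high arm, where the arm is defined on the *latent*
  abundance (shift + biological noise) so the measured wells and the
  hazard see the same signal. Censoring is administrative, uniform on
  (0, 56) months → median follow-up ~28 months. A Weibull shape
  parameter generalizes the exponential if needed. CEA is log-normal
  with a stage shift and is consumed only as a Cox covariate.
* **Determinism**: one seed drives named counter-based substreams
  (assay panel, each cohort's Ct draws, clinical draws, survival), so
  outputs are bitwise reproducible and adding draws to one stage never
  perturbs another.

What the generator does **not** emulate: hemolysis and other
pre-analytic artifacts, batch/plate effects, inter-assay efficiency
differences, correlated miRNA co-regulation, and non-proportional
hazards. Passing tests therefore demonstrate that the pipeline
recovers planted signal of realistic size under clean qPCR noise —
not that it is robust to the artifacts above.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full default design
(754 assays, 50 + 234 samples) end to end — a single run takes about a
second — and use sweeps of 10–100 seeds or 200 simulation replicates
where a property is a rate (reference recovery, winner recovery, CI
coverage); these sizes give comfortable margins on every threshold
while keeping the whole suite under a minute of compute. Sample SDs use
ddof = 1 except the heat-map z-score (population, ddof = 0); all ties
break lexicographically after the stated sort key; p-values are clipped
to [0, 1]; the normal 95% quantile is 1.959963984540054. Exit codes of
the CLI: 0 success, 2 input/validation error, 3 statistical-stage
error.
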