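# Methods

This note documents the models, algorithms and numerical choices behind
`ihcsig`, and what the synthetic-data generators do and do not emulate.

## The signature and its dichotomization

The CD8×PD-L1 signature of a patient is the plain product
`s = d_CD8 · d_PD-L1` of the CD8+ and PD-L1+ cell densities (cells/mm²)
measured inside the annotated tumor region, in cells²/mm⁴ at full floating
precision. All four measures (signature, the two component densities, and
the manual PD-L1 tumor-cell percentage) are dichotomized with the inclusive
rule **value ≥ cutoff ⇒ positive**. The manual score's conventional label is
"TC ≥ 25%", so ≥ is adopted uniformly; at an exact tie a single patient's
label can depend on this convention, which is why it is fixed and documented
rather than left to chance. Reference cutoffs carried as defaults are
297 cells/mm² (CD8), 644 cells/mm² (PD-L1), 1.54×10⁵ cells²/mm⁴ (signature)
and 25% (manual TC). Note that the signature cutoff is *not* the product of
the component cutoffs (297 × 644 = 191 268 > 1.54×10⁵): it is learned on its
own score column.

## Cutoff learning by constrained PPV maximization

Candidates are the sorted unique observed scores. PPV, prevalence and the
log-rank statistics are step functions that only change at observed values,
so this grid is exhaustive; nothing between two observed scores can alter
any evaluation. For each candidate `c`:

* prevalence = `#(s ≥ c) / n`;
* PPV = responders among positives / positives, with an exact
  Clopper–Pearson interval at the configured confidence (default 95%);
* two-group log-rank p-values for OS and for PFS.

A candidate is **feasible** when prevalence ∈ [0.30, 0.70] and both p-values
are ≤ 0.05 (all four thresholds configurable; the two log-rank constraints
are applied simultaneously as a conjunction). The selected cutoff maximizes
PPV over feasible candidates; ties are broken by the smaller OS p-value,
then the smaller cutoff. This tie-break is this package's rule — any
deterministic rule would do, but one must be fixed for reproducibility.
When one side of the dichotomy is empty, or the groups contain no events,
the log-rank test is undefined and the candidate is recorded infeasible with
the reason, never dropped: `CutoffSearchResult.all_evaluations` always has
one entry per candidate. The signature, CD8 and PD-L1 cutoffs are optimized
independently on their own score columns; the search never couples them.

## Survival machinery

* **Kaplan–Meier** curves use the product-limit estimator with Greenwood
  variance and log-log (exponential-Greenwood) 95% bands, via lifelines.
  The median is the first time the curve falls to ≤ 0.5 (`math.inf` encodes
  "not reached", rendered `NR` in reports); its CI inverts the pointwise
  band (Brookmeyer–Crowley with the log-log transform).
* **Log-rank** is the standard two-group chi-square with 1 df (asymptotic
  p-value, no permutation fallback); it requires at least one event overall.
* **Cox proportional hazards** is fit in-package by maximizing the partial
  likelihood with damped Newton iterations. Risk-set sums are suffix
  cumulative sums over the time-sorted subjects; Efron's tie correction is
  the default, Breslow is available. Convergence is declared when the
  gradient norm falls below `1e-8 · max(1, |log PL|)` (the likelihood-scaled
  analogue of an absolute 1e-8 tolerance, which double precision cannot
  reach on large cohorts) or the Newton step vanishes; steps are halved (up
  to 30 times) whenever they would decrease the likelihood. A coefficient
  drifting past |β| > 15 (hazard ratio ≈ 3×10⁶) marks monotone likelihood —
  perfect separation — and the fit is returned flagged `converged=False`
  rather than raising. Standard errors are Wald (inverse observed
  information). Constant columns are rejected, and the number of events
  must be at least the number of covariates. The solver agrees with
  lifelines' `CoxPHFitter` to ≲1e-5 on coefficients and standard errors
  (cross-checked in the test suite, tied and untied data).
* **Nested-model comparison** of proportional-hazards fits is the partial-
  likelihood ratio chi-square, `2(logPL_full − logPL_reduced)` with df equal
  to the covariate-count difference — this is what an "ANOVA" between nested
  Cox models computes. Identical models compare with df 0 and p = 1.
* **Significance banding** follows the four-symbol legend with inclusive
  upper boundaries: `-` > 0.05, `+` ≤ 0.05, `++` ≤ 0.005, `+++` ≤ 0.0005.

The multiparametric Cox table adds each dichotomized measure separately to
seven fixed clinical covariates (histology, smoking status, age, gender,
liver metastasis, tumor stage, previous lines of therapy — eight covariates
total). Categoricals are one-hot encoded against the lexicographically first
level as reference; age and prior lines enter continuously/ordinally. The
overall-model band comes from the nested test against the fixed-only model.

## Cohort transfer by prevalence matching

The reference positive prevalence q is carried at full precision (e.g.
59/163 ≈ 0.362, displayed as 36%). The target cohort is ranked by score and
the top `n_pos = ⌊q·n + 0.5⌋` patients are labeled positive (round-half-up,
so 0.36 · 199 = 71.64 → 72; `floor`/`ceil` are available options). The
derived cutoff is the smallest positive score; when nothing is positive it
is a sentinel just above the maximum score. Ties straddling the boundary are
resolved by stable input order with a warning — with continuous densities
exact ties essentially never occur, but the behavior must be deterministic.
Matching q back onto the reference scores reproduces the reference positive
count within one patient (rounding can shift it by at most one).

## Stratified train/test split

Patients are grouped into joint strata of the balance variables (defaults:
manual PD-L1 status, response, previous lines, stage, gender; continuous
variables with more than six distinct values are binned into two quantile
bins for stratification only). Each stratum receives
⌊size · f⌋ training slots plus largest-remainder top-ups until the exact
overall train size ⌊n·f + 0.5⌋ is met; within a stratum, membership is a
seeded shuffle. Stratum order is itself seeded so remainder ties break
randomly but reproducibly; single-patient strata are thereby assigned by the
seeded draw and logged. With n = 163 and f = 84/163 the split is exactly
84/79, and per-variable category proportions in train vs test agree within
10 percentage points on the synthetic cohorts (audited in tests).

## Image quantification

* **Optical density**: `OD = −log10(max(I, ε)/I₀)` per channel, clipped at
  0, with background intensity I₀ = 255 and floor ε = 1/255 so zero pixels
  stay finite. The floor (rather than an additive ε) keeps mid-range values
  exact: intensity 25.5 maps to OD 1 with no bias. 8-bit quantization limits
  the OD→intensity→OD round trip to an error of ~0.217/I; below intensity
  ≈ 11 (OD ≳ 1.4) densitometry is inherently coarse.
* **Stain unmixing**: each pixel's OD vector is expressed in a 3×3 stain
  basis (rows: hematoxylin, DAB, residual) by a linear solve; negative
  concentrations are clipped to 0. The default basis uses the classical
  hematoxylin (0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776) OD
  directions with the complement residual
  `r_i = sqrt(max(0, 1 − h_i² − d_i²))`, normalized — non-negative by
  construction and well conditioned. A matrix with condition number above
  1e8 is rejected with the condition number in the message. Custom bases can
  be supplied as a 3×3 CSV.
* **Detection**: the chromogen concentration map is thresholded (default
  0.3 OD), 8-connected components are labeled, and components with pixel
  area in [20, 2000] are kept; each contributes its centroid. Touching cells
  are *not* split (no watershed) — a deliberate simplification that keeps
  the operator deterministic and oracle-testable; the synthetic generator
  guarantees separation, and on real tissue this undercounts dense nests.
* **Density**: cells whose centroid lies inside the annotation mask are
  counted (an unambiguous rule for boundary-straddling objects) and divided
  by the mask area, `#true pixels · (µm/px / 1000)²` mm². An empty mask is a
  degenerate-region error.

## Synthetic data: what it emulates, and what it does not

**Cohorts.** Densities are bivariate log-normal — non-negative and
right-skewed with a single correlation knob. The default log-scale
parameters (μ_CD8 = 5.39, μ_PD-L1 = 5.97, σ = 1.0 each, ρ = 0.33) were
solved once so that the reference cutoffs sit at realistic positive
prevalences: P(d_CD8 ≥ 297) ≈ 0.38, P(d_PD-L1 ≥ 644) ≈ 0.31, and
P(s ≥ 1.54×10⁵) ≈ 0.36. Response is Bernoulli with logistic probability in
the *standardized* log signature (intercept −1.66, slope 1.1), giving an
overall response rate near 0.19 and a PPV contrast of roughly 0.4 vs 0.09
between signature-positive and -negative patients. OS and PFS are
exponential proportional hazards: the linear predictor is
`β_sig · 1[log s > population median] + β_LM · LM` with defaults
β_sig = −1.0 (a positive-group median about 2.7× the negative's) and
β_LM = 0.7; baseline hazards are ln2/8 per month for OS and ln2/2.5 for PFS,
and PFS is capped at OS (progression-or-death). Censoring is an independent
exponential clock (0.04/month, ≈ 60% OS events at study scale). The hazard
acts on the *binary above-median indicator*, not the continuous score, so
that a Cox fit of that indicator recovers β_sig exactly — the generator's
parameters are thereby directly testable. Covariates are independent
categoricals with configurable prevalences, age ~ N(64, 9²) clipped to
[30, 90], and the manual TC% is a noisy monotone logistic transform of the
PD-L1 density (≈ 58% of patients at TC ≥ 25%). The non-ICT cohort preset
lowers the density scale, sets β_sig = 0 (the signature is predictive, not
prognostic), and stretches baseline survival to a ~50-month median.

**Images.** Brown DAB-like disks of fixed radius on a uniform bluish
hematoxylin wash, composited in OD space and converted to 8-bit RGB with
additive Gaussian noise (default 1.5 intensity units — typical scanner
noise, and small enough that unmixed chromogen noise stays well below the
0.3 detection threshold). Disk centers are rejection-sampled to be disjoint
and strictly inside the mask; ground truth records every centroid.

**Not emulated** (so a green suite does not certify them): real nuclear
texture and stain heterogeneity, touching/overlapping cells, dual-stain
(purple/brown) assays beyond two stain vectors, whole-slide formats,
dependence of densities on clinical covariates, a CD8-specific prognostic
effect separate from the signature, non-proportional hazards, and platform/
batch variation between cohorts. Passing tests demonstrate correctness of
the estimators and the pipeline logic under the stated statistical model,
not performance on clinical material.

## Problem sizes and determinism

Every stochastic operation takes an explicit integer seed; no global RNG
state is used, and identical seeds yield byte-identical cohorts, images and
pipeline outputs. The test suite exercises parameter recovery at n = 2000
(KM median, Cox log-HR), type-I error of the log-rank test over 2000 null
simulations of 40 + 40 patients, uniformity of the nested-test p-value over
1000 replicates at n = 100, brute-force equivalence of the cutoff search on
20 cohorts of 30–100 patients, and a 3×3 (cell count × noise) image grid —
sizes chosen to bound Monte-Carlo error well inside the asserted tolerances
while keeping the default run a few minutes. The acceptance script uses the
study's own sizes (163 split 84/79; 199 for transfer).

## Known limitations

* The detection stage is intentionally simple; it is a stand-in for
  segmentation tuned by pathologists and should be re-tuned (threshold,
  area gates, stain vectors) before use on scanned tissue.
* Log-rank and Wald p-values are asymptotic; at very small group sizes the
  cutoff-search constraints inherit that approximation.
* The cutoff search optimizes an in-sample PPV; it provides feasibility
  diagnostics but no internal cross-validation, so the learned cutoff must
  be validated on held-out data (as the pipeline's train/test design does).
* Exponential baselines make median survival analytic but force constant
  hazards; calibration checks that depend on hazard shape should not be
  generalized beyond that family.
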