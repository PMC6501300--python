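# ihcsig

Predictive-biomarker analysis for anti-PD-L1 immunotherapy in NSCLC built on
a **CD8×PD-L1 density signature**: the product of the CD8+ tumor-infiltrating
lymphocyte density and the PD-L1+ cell density (cells²/mm⁴) measured by
automated image analysis inside a pathologist-annotated tumor region. It is
aimed at computational pathology and biostatistics practitioners who want a
tested, reusable implementation of the full analysis chain:

1. **Quantification** (`ihcsig.quant`) — Beer–Lambert optical-density
   conversion, hematoxylin/DAB color deconvolution, thresholded
   connected-component cell detection, and area normalization to cells/mm².
2. **Signature scoring** (`ihcsig.scoring`) — the product score
   `s = d_CD8 · d_PD-L1` and inclusive dichotomization (`value ≥ cutoff` is
   positive) for the signature, its two components, and the manual PD-L1
   tumor-cell percentage.
3. **Cutoff learning** (`ihcsig.cutoff`) — the cutoff `c*` maximizes the
   positive predictive value

   `PPV(c) = #(responders with s ≥ c) / #(s ≥ c)`

   (equivalently, the objective response rate among signature-positives)
   over all observed scores, subject to two-group log-rank `p ≤ 0.05` for
   both OS and PFS and a positive prevalence between 30% and 70%. PPV
   confidence intervals are exact (Clopper–Pearson).
4. **Survival evaluation** (`ihcsig.survival`) — Kaplan–Meier curves and
   medians with log-log CIs, the log-rank test, a multivariate Cox
   proportional-hazards fit (Efron or Breslow ties), the partial-likelihood
   ratio test between nested models, and four-symbol significance banding
   (`-` > 0.05, `+` ≤ 0.05, `++` ≤ 0.005, `+++` ≤ 0.0005).
5. **Cohort transfer** (`ihcsig.transfer`) — positivity is transferred to an
   independent cohort by prevalence matching: rank the target scores and
   label the top-q fraction positive, q being the reference cohort's
   positive prevalence.
6. **Synthetic data** (`ihcsig.simulate`) — seeded generators for cohorts
   (correlated log-normal densities, logistic response, exponential
   proportional-hazards OS/PFS with censoring, clinical covariates) and for
   chromogenic-IHC-like images with ground-truth cell positions, so every
   stage is testable without any external data.

The decision-shaped pieces are scikit-learn-style estimators
(`CutoffOptimizer`, `PrevalenceMatcher`, `SignatureScorer`) with
`fit`/`predict`/`transform` and `get_params`/`set_params`; everything is also
reachable through plain functions and the `ihcsig` command-line interface
(`simulate-cohort`, `simulate-image`, `quantify`, `split`, `optimize`,
`report`, `cox-table`, `transfer`, `run`).

## Worked example

```python
import numpy as np
from ihcsig import (CohortConfig, CutoffOptimizer, PrevalenceMatcher,
                    generate_cohort, logrank)
from ihcsig.pipeline import stratified_split
from ihcsig.scoring import add_measure_labels

cohort = add_measure_labels(generate_cohort(CohortConfig(n_patients=163, seed=0)))
train, test = stratified_split(
    cohort, 84 / 163,
    ("pdl1_tc_label", "response", "prior_lines", "tumor_stage", "gender"), seed=0,
)

opt = CutoffOptimizer().fit(train)          # PPV-maximizing cutoff on train
best = opt.result_.best
print(f"learned signature cutoff: {opt.cutoff_:.3g} cells^2/mm^4")
print(f"training prevalence {best.prevalence:.2f}, PPV {best.ppv:.2f} "
      f"(95% CI {best.ppv_ci[0]:.2f}-{best.ppv_ci[1]:.2f})")

pos = opt.predict(test).astype(bool)        # frozen cutoff applied to test
p = logrank(test["os_time"][pos], test["os_event"][pos],
            test["os_time"][~pos], test["os_event"][~pos]).p_value
print(f"test-set OS log-rank p = {p:.4f}")

non_ict = add_measure_labels(generate_cohort(CohortConfig(n_patients=199, seed=99)))
matcher = PrevalenceMatcher().fit(cohort["signature_label"].to_numpy())
res = matcher.match(non_ict["signature_score"].to_numpy())
print(f"transferred to n=199 cohort: {res.n_positive} positives "
      f"(matched prevalence {res.matched_prevalence:.2f}), "
      f"derived cutoff {res.derived_cutoff:.3g}")
```

Output:

```
learned signature cutoff: 1.06e+05 cells^2/mm^4
training prevalence 0.45, PPV 0.37 (95% CI 0.22-0.54)
test-set OS log-rank p = 0.0032
transferred to n=199 cohort: 73 positives (matched prevalence 0.37), derived cutoff 1.54e+05
```

Read: on this synthetic 163-patient cohort the search selects the observed
score 1.06×10⁵ cells²/mm⁴ as the training cutoff; 45% of training patients
are signature-positive and 37% of those respond. Applied unchanged to the
held-out test split, the signature separates overall survival
(log-rank p = 0.0032). Matching the 37% positive prevalence onto an
independent 199-patient cohort labels its top 73 scores positive and implies
a cohort-specific cutoff of 1.54×10⁵.

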