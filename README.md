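# labelamp

Quality control (QC) of structural MRI — deciding whether a T1-weighted
scan is usable — is still largely an expert visual judgment, and it does
not scale to cohorts of thousands of scans. `labelamp` implements a
label-amplification pipeline for this problem: a small set of
confidently expert-labeled scans is *amplified* through a crowd of
imperfect raters, a supervised model learns how much to trust each
rater, the resulting continuous labels train an image-based quality
scorer, and the package quantifies how the choice of QC threshold
changes a downstream developmental effect-size estimate. Every stage is
runnable on synthetic data generated by the package itself, so the full
system is testable without any data download.

It is written for neuroimaging methodologists and for anyone studying
crowd-sourced annotation: all stages are importable library functions
with a thin `labelamp` command-line wrapper.

## The model

**Raters.** Each crowd rater follows a two-coin model with sensitivity
*a* (P(pass | truly pass)) and specificity *b* (P(fail | truly fail));
for a slice of latent quality *q* ∈ [0, 1] the pass probability is

    P(pass) = q·a + (1 − q)·(1 − b)

Priors over (*a*, *b*) skew sensitivity high and give specificity a
low-reliability tail — crowds systematically pass bad images — and
per-rater activity is log-normal (a few raters do most of the work).

**Gold standard.** Experts rate whole volumes pass/fail with confidence
1–5, recoded to a signed −5…5 scale. A volume enters the gold set only
when every expert who rated it was confident (|score| ≥ 4) and all
agree. Inter-expert reliability is the overlap-weighted mean ROC AUC of
each expert's signed scores against a reference expert's decisions.

**Weighted aggregation.** The design matrix has one row per slice and
one column per rater; entry (s, r) is rater r's mean rating of slice s,
*missing* (not 0) if r never saw s. A gradient-boosted tree classifier
(600 trees; depth ∈ {2, 6} and learning rate ∈ {0.01, 0.1} chosen by
stratified 10-fold CV) is fit on gold slices; its probability output on
every slice is the amplified label in [0, 1]. The per-rater importance
F — how many tree splits use that rater's column — measures how much
the model trusts each rater.

**Image scorer.** A frozen convolutional backbone (default: a seeded
random filter bank; a pretrained 16-layer ImageNet backbone is
pluggable) turns each 256×256×3 slice into features; a dense head
(256 ReLU → 50% dropout → 1 sigmoid) is trained as a *regression* on the
amplified labels under mean squared error for 50 epochs, keeping the
best-validation-loss checkpoint, with subject-grouped 80/10/10 splits
and multi-seed evaluation.

**Effect size.** Subject QC score = mean of its slice scores. Ordinary
least squares of gray-matter volume on age is fit with and without the
inclusion rule qc_score > threshold; the reference effect is the
two-point readout of a published growth curve,
(710 − 580)/(5 − 35) = −4.3 cm³/year.

## Worked example

```python
import pandas as pd
from labelamp import run_end_to_end, reference_slope, fit_volume_age
from labelamp.effect_size import simulate_development_cohort

res = run_end_to_end(seed=0)          # phantoms -> crowd -> amplify -> scorer
print(f"weighted aggregator AUC: {res.weighted_test_auc:.3f}")
print(f"equal-weight AUC:        {res.equal_weight_test_auc:.3f}")
print(res.scorer_eval.summary())

cohort = simulate_development_cohort(seed=0)   # corrupted pediatric cohort
print(fit_volume_age(cohort).summary())
print(fit_volume_age(cohort, threshold=0.7).summary())
print("reference slope:", reference_slope(710, 580, 5, 35), "cm3/year")
```

Output:

```
weighted aggregator AUC: 0.886
equal-weight AUC:        0.987
Multi-seed scorer evaluation (test split vs binarized gold)
  seed 9: AUC = 0.9500
  seed 10: AUC = 0.9900
  seed 11: AUC = 1.0000
  mean AUC = 0.9800  (SD = 0.0216)
OLS gm_volume ~ age
  QC threshold:  none
  n included:    629
  slope:         -2.78 cm3/year (SE 0.48)
  intercept:     710.3 cm3
  residual SD:   54.6 cm3
OLS gm_volume ~ age
  QC threshold:  0.7
  n included:    368
  slope:         -3.64 cm3/year (SE 0.39)
  intercept:     718.8 cm3
  residual SD:   34.6 cm3
reference slope: -4.3 cm3/year
```

The scorer, trained only on crowd-amplified labels, reproduces the
true pass/fail labels of held-out subjects (AUC 0.98). With this
default crowd — heterogeneous but with no outright adversarial
raters — the equal-weight average is already an excellent aggregator
and the weighted model has only ~110 gold slices to learn from, so it
does not win here; its advantage appears when the crowd contains
unreliable raters and the gold set is larger (the acceptance script
measures exactly that condition: weighted ≥ equal in 10/10 replicates
at 1,000 gold slices with a 25% unreliable crowd). In the cohort
analysis, scans corrupted by artifacts carry volumes unrelated to age,
flattening the fitted slope (−2.78) relative to the generator's truth
(−4.3); excluding subjects with QC score ≤ 0.7 moves the estimate back
toward it (−3.64) — the QC threshold changes the scientific
conclusion.

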