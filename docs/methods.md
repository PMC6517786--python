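# Methods

This note documents the models, the synthetic data generators, the
numerical choices, and the limitations of `labelamp`. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from external data.

## Phantoms and the artifact model

The phantom generator produces a head-like object on an exactly zero
background: nested shells with T1-like contrast (bright white-matter
core 1.0, gray-matter shell 0.6, dark CSF rim 0.2), with in-plane
semi-axes close to the array half-extent and a *flat-topped* axial
profile (full cross-section over ~85% of the axial semi-extent,
ellipsoidal taper beyond). The flat top is deliberate: the slice
selection rule takes five axial slices 40 apart starting at the first
slice with more than 10,000 non-zero pixels, so the default
128×128×220 phantom needs a run of at least 161 qualifying slices, which
a plain ellipsoid of that size cannot provide. Gaussian intensity noise
(default SD 0.03 of the white-matter intensity) is added inside the
head support only, keeping the background exactly zero so pixel-count
slice selection behaves as on skull-stripped or well-shimmed data.

Motion is modeled in k-space: a fraction of phase-encode lines (up to
half, scaling linearly with severity, sparing the central 10% of lines
that carry gross contrast) receive random phase offsets whose magnitude
also scales with severity; the magnitude of the inverse transform shows
the replicated, shifted anatomy ("ghosting") that dominates real QC
failures. For a fixed seed the corrupted line set is nested across
severities, so distortion is monotone in severity realisation by
realisation, not just in expectation. Severity 0 is an exact
round-trip. No pulse-sequence, B0/B1, or defacing modeling is
attempted.

Latent quality is q = 1 − severity; the binary truth thresholds q at
0.5 (configurable). Cohort severities are drawn from a bimodal Beta
mixture (low mode Beta(1.5, 8); high mode Beta(8, 1.5) with default
weight 0.3–0.35 depending on the stage) because ratings of real scans
pile up at "clearly fine" and "clearly unusable"; the middle is rare.
No empirical severity distribution exists for real cohorts, so this
mixture is a modeling choice, and results conditional on it.

## Crowd simulation

Raters are two-coin annotators; for latent quality q the pass
probability interpolates linearly between the coins,
P(pass) = q·sens + (1 − q)·(1 − spec). This is the simplest response
model consistent with the two-coin endpoints; real raters may be
nonlinear in perceived quality. Default priors: sensitivity
~ Beta(12, 2) (mean ≈ 0.86); specificity ~ Beta(8, 3) with a 15%
low-reliability tail Beta(2, 5) — together encoding the pass bias
crowds show on this task; activity ~ log-normal(0, 1). The tail weight
was calibrated once so that a filtered crowd's *equal-weight* AUC on a
balanced gold set lands near 0.95, the operating point reported for
real filtered crowds on this task; campaigns default to ~22 rating
events per slice before filtering (matching a reported ~80k events
over ~3.6k slices). An `unreliable_fraction` of raters are outright
random/adversarial (both coins uniform on [0.2, 0.6]); it defaults to
0 and the ordering experiments set it to 25–30%.

Serving starts uniform-random and switches to fewest-first (uniform
among minimum-count slices) after one pass over the slice set; the
switch point is configurable since no principled value exists. The
gamification rule awards one point per rating unless the slice already
has more than 5 ratings, their mean is outside (0.3, 0.7), and the
rating disagrees with that majority; the incoming rating is excluded
from the history. Rater filtering ranks raters by the number of
*distinct* gold slices rated (repeat views counted once; configurable)
and keeps the top floor(quantile·n) with lexicographic tie-breaking, so
261 raters at quantile 0.25 retain exactly 65.

## Gold standard

Expert decisions are recoded to sign(decision)·confidence ∈ −5…5. An
image qualifies for the gold set iff every expert who rated it gave
|score| ≥ 4 and all signs agree — unanimity over the experts *present*,
the weakest rule consistent with panels where not everyone rates
everything; a stricter all-experts-must-rate variant is a flag.
Reliability uses the signed score as the continuous ROC axis against
the reference expert's binary decision, weighting each pair by overlap
count; pairs whose overlap has a single reference class are skipped and
reported.

## ROC/AUC

Implemented from first principles because every stage depends on it:
the trapezoidal area under the empirical ROC (thresholds at distinct
scores, ties collapsed to one operating point) and, independently, the
Mann–Whitney pair count (ties half credit) computed from mid-ranks.
The two agree to 1e−12 on arbitrary inputs and are cross-checked
against scikit-learn in the tests. Orientation: label 1 = pass, higher
score = more passable. Single-class inputs raise rather than return a
default.

## Weighted aggregation

Raters are features; slices are observations; entries are per-pair mean
ratings with genuine missingness (never imputed — the trees route
missing values natively, and a test proves a NaN entry can predict
differently from 0). The classifier is XGBoost with 600 estimators,
grid-searched over depth {2, 6} × learning rate {0.01, 0.1} by
stratified 10-fold CV maximizing AUC (the API defaults; the simulation
experiments use 150–200 trees and 5-fold CV at their smaller problem
sizes). Importance F is the split count per rater column summed over
the ensemble, read directly from the booster. The equal-weight baseline
averages per-rater slice means (one vote per rater per slice,
consistent with the design-matrix entry definition; event-level
averaging is available as an option). Gold slices split 2/3 train,
1/3 test, stratified; the training-size sweep holds that test split
fixed while subsampling the training pool.

On simulated crowds with ≥ 20–25% unreliable raters and a
1,000-slice gold set, the weighted aggregator's held-out AUC exceeds
the equal-weight baseline's in ≥ 9/10 replicates (the advantage needs
a few hundred training slices to materialize — with fewer the
equal-weight mean is a surprisingly strong baseline), and F
rank-correlates positively with true balanced accuracy among
equal-activity raters — the weighting recovers rater reliability
rather than just activity. Both properties are asserted in the
acceptance suite at the problem sizes below.

## Image scorer

Inputs are bilinearly resized to 256×256, peak-normalized, and
triplicated to three channels. The default backbone is a fixed, seeded
random filter bank: the image is mean-pooled 4×, convolved with 12
zero-mean random 5×5 kernels, and the positive and negative rectified
responses are average-pooled over a 6×6 grid, alongside raw grid means
(900 features). Random convolutional features are a standard cheap
fixed representation; crucially, ghosting spreads signal energy into
the image background, which grid-pooled features see directly. A
pretrained 16-layer ImageNet backbone can be substituted where a deep
learning framework is installed; no backbone is ever fine-tuned.

The head (dense 256 ReLU → dropout 0.5 → 1 sigmoid) is trained by
minimizing MSE with Adam (lr 1e−3, batch 32 — unstated in the original
recipe, so defaults are exposed in config and recorded in the scorer
artifact), features standardized on the training split, inverted
dropout, 50 epochs, restoring the minimum-validation-loss checkpoint.
Targets are the continuous amplified labels (a regression, including
ambiguous mid-range slices); evaluation binarizes only confident
labels. In the synthetic pipeline "confident" means severity at least
0.15 away from the 0.5 label boundary — the analogue of evaluating
only against gold ratings given with high confidence; slices nearer
the boundary are genuinely ambiguous (their own expert label would be
contested) and are trained on but not scored against. Splits are
grouped by subject at 80/10/10 by slice count; the pipeline re-draws
the (seeded) split if the test partition lacks one of the two
confident classes, which otherwise happens by chance in small cohorts.
Multi-seed evaluation re-trains the head with different
initialization/shuffling seeds and reports per-seed AUC, mean and SD.

## Effect-size analysis

OLS of volume on age (optionally + age², optionally per sex) is solved
by least squares on the design matrix (coefficient SEs from
(XᵀX)⁻¹s²), cross-checked against statsmodels in the tests; the module
stays self-contained and exact to 1e−9 on noise-free polynomial data.
Thresholding is strict (qc_score > t). The reference effect size is the
two-point readout (710 − 580)/(5 − 35) = −4.3 cm³/year, displayed at
one decimal.

The synthetic cohort (default n = 629, ages uniform 5–21) has clean
volumes 730 − 4.3·age + N(0, 35²) cm³. A corrupt fraction (default
0.3) of subjects are bad scans, and the default corruption mode is
**signal loss**: their measured volume is drawn around the
age-independent population mean with SD 80 cm³ — segmentation on an
unusable scan returns a number unrelated to the subject's anatomy.
Including such scans attenuates the fitted slope by roughly the corrupt
fraction (≈ −3.0 vs truth −4.3 at the defaults), which is the regime
observed in practice: a clear, bias-dominated flattening rather than
mere noise. A pure variance mechanism (`corruption_mode="additive"`,
zero-mean high-variance error) is also provided; it inflates the slope
SE without biasing it, and is what the SE-inflation test uses.
QC scores are Beta(9, 2) for clean and Beta(2, 8) for corrupted
subjects; the overlap of these modes is the imperfect link between the
scorer and true corruption. With these defaults, thresholding at 0.7
moves the slope estimate toward the truth in ~96% of replicates
(asserted as ≥ 9/10 over fixed seeds).

## Problem sizes

The API defaults mirror the full-scale recipe (5×40 slice rule, 600
trees, 10-fold CV, 50 epochs, 10 scorer seeds). The simulation
experiments in the tests and acceptance script run at desk scale, a
deliberate choice to keep replicate counts high: the
weighting-vs-averaging experiment uses 65 raters over a 1,000-slice
gold set with 18 ratings per slice and 200 trees / 5-fold CV;
importance-recovery uses 40 equal-activity raters over 300 slices;
the end-to-end pipeline uses phantom cohorts of 48 subjects
(240 slices) with ~22 ratings per slice and 3 scorer seeds; 10
replicates for every ordering/recovery property.

## Known limitations

- The phantom is geometric, not anatomical; no real tissue texture,
  no intensity inhomogeneity, no defacing artifacts. Passing tests
  show the *pipeline logic* recovers planted signal, not that the
  scorer transfers to real scans.
- The linear-in-q response model and Beta priors are assumptions; real
  rater behavior (fatigue, learning, slice-position effects) is richer.
- The random-filter backbone is far weaker than a pretrained deep
  network; it suffices here because the planted artifact has a strong
  low-frequency signature. Real QC at scale should plug in a
  pretrained backbone.
- Amplified labels inherit whatever bias survives the weighting; an
  adversarial majority coordinated on specific slices would defeat it.
- The effect-size endpoints reported on real cohorts elsewhere are not
  reproducible from synthetic data; only the direction and rough
  magnitude of threshold-induced recovery are meaningful here.
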