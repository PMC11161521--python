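# Methods

## Problem and model

Japanese pear varieties are largely self-incompatible, so growers pollinate by
hand with pollen collected from flowering branches. How much pollen a branch
can yield depends on the morphological stage of each flower: an immature bud
("Early"), the balloon-shaped bud just before opening ("Best", the stage of
maximal collectable pollen), the open bloom with red anthers ("Late"), the
post-bloom flower with dark anthers whose pollen has already burst
("Too late", zero collectable pollen), and side/back views where "Late" and
"Too late" cannot be told apart ("Other").

`pearpollen` estimates the collectable pollen mass of a branch from a
per-stage flower count:

    total (mg) = Σ_s  n_s · p_s

where `n_s` is the number of flowers counted in stage `s` and `p_s` is the
per-flower pollen mass for that stage from a per-variety reference table
(mg/flower, measured on 100 flowers × 3 replications per stage for the
packaged varieties Chojuro, Shinko and Nepal). Two stages are special:

* **Too late** always contributes 0 — the invariant is enforced when a table
  is loaded.
* **Other** has no static entry. Since an "Other" flower is either "Late" or
  "Too late", it is priced at the count-weighted mean of those two stages'
  unit masses *in the same image*:
  `p_other = n_late/(n_late + n_too_late) · p_late` (the Too-late term is 0).
  If an image contains Other flowers but no Late/Too-late flowers at all, the
  ratio is undefined; the estimator falls back to `p_late/2` and sets an
  `other_fallback` flag rather than guessing silently. This degenerate rule
  is a package choice; the defining sources are silent on the case.

Each table also carries an "effective" column: the raw mass multiplied by the
stage's fruiting rate (probability that pollination with that stage's pollen
sets fruit). `mode="effective"` prices counts with that column instead;
effective ≤ raw holds cell-wise by validation.

The published per-stage standard deviations are stored nowhere in the
computation path: their printed magnitudes (~1e-5) are inconsistent with the
mg-scale means and their units are unstated, so they are treated as opaque.

## From detections to counts

Counts normally come from an object detector run on branch photographs. The
package consumes YOLO-format text records (one row per box:
`class_id cx cy w h [confidence]`, geometry normalized to [0, 1]) and applies
the standard post-processing itself:

1. **confidence filter** — drop rows below `confidence_threshold`
   (default 0.25);
2. **per-class NMS** — greedy selection in descending confidence; a box is
   suppressed when its IoU with an already-kept box *of the same class* is
   ≥ `iou_threshold` (default 0.5). Cross-class overlaps are kept, ties in
   confidence break by input order, so the result is deterministic.

The comparator is ≥ (survivors are pairwise < threshold); the defaults are
declared package defaults — the reference workflow does not state its
thresholds. Class indices are Early=0 … Other=4 in the listing order of the
stages; boxes are converted to half-open pixel corner coordinates (top-left
origin) on read, scaled by the configured image size (default 640 px).

## Occlusion correction

A camera sees one side of a branch; flowers hidden behind wood never enter
the image, so count-based estimates are biased low. Assuming flowers hidden
over a 45°–90° angular range, roughly 12.5–25% of flowers are invisible, and
the aggregate estimate is multiplied by a factor in [1.125, 1.25]
(default 1.1875, the band midpoint, when correction is requested without an
explicit factor). Only the total is rescaled — per-stage contributions
describe what was actually seen. Factors < 1 are rejected: occlusion only
hides flowers.

On the *error percentage* the correction is applied additively
(`error + 100·(factor − 1)`), which is the arithmetic that maps a mean error
of −27.89% to −2.89% / −15.39% at the band endpoints. Note the two routes are
not algebraically equivalent: the multiplicative mass correction is zeroed
exactly by `factor = actual/detected`, the additive percentage-point form by
`factor = 2 − detected/actual`. Both are exposed
(`apply_occlusion_correction` on estimates, `corrected_error_pct` on errors)
and the tests pin each form's own closed form.

## Evaluation statistics

* **Estimation error** (signed %): `−(1 − detected/actual) × 100` on flower
  counts (canonical form). A pollen-mass variant
  `−(1 − est_mg/actual_mg) × 100` is a separate function because the two only
  agree when detected and actual stage *proportions* coincide; callers see
  which form they used rather than having the discrepancy hidden.
* **Accuracy rate** (%): correctly-labelled detections over matched
  detections. Flowers the detector missed entirely (background) are excluded
  from the denominator, matching how the reference workflow scored it.
* **Stage percentages**: per-stage share of the total count, reported to
  1 decimal (half-away-from-zero rounding); the error row is the difference
  of the two rounded columns.
* **Confusion matrix with background**: truth boxes and detections are
  matched greedily, one-to-one, label-agnostically, in descending IoU order
  at IoU ≥ 0.5 (ties break by input order). Matched pairs tally
  (true stage → predicted stage); unmatched truth falls in a background
  column (undetected flowers), unmatched detections in a background row
  (spurious detections). Rows are normalizable to proportions.
* **mAP50**: per class, detections are ranked by confidence and matched to
  the free same-class truth box of highest IoU within the same image (TP at
  IoU ≥ 0.5); AP integrates the precision envelope over recall (all-point
  interpolation; a 101-point variant is available behind
  `interpolation="101point"` since detector toolchains differ). mAP averages
  over the classes present in truth and is invariant to rank-preserving
  confidence rescaling.

Report rounding throughout: masses 3 decimals, percentages 1 decimal,
accuracy rates 3 decimals. Internal arithmetic is full precision.

## Synthetic scenes and detector noise

The generator replaces the camera and the trained network at desk scale.

`SceneParams` defaults describe one flowering branch: `n_flowers=62` (the
visually counted total of the reference branch set), stage distribution
(0.30, 0.21, 0.40, 0.04, 0.05) — the measured branch proportions for
Early/Best/Late/Too-late, plus a 5% Other share so the ratio rule and the
Other confusion row are exercised (human ground truth never contains Other,
but detector output and annotation practice do) — occlusion fraction 0.1875
(midpoint of the 12.5–25% band), 640 px images, box sizes 24–64 px.
Boxes are rejection-sampled under a pairwise IoU cap of 0.3 (flowers cluster
but are not coincident); occlusion is an independent Bernoulli flag per
flower, not a geometric branch model. Occluded flowers never reach the
detector.

`DetectorNoiseParams` defaults encode the published detector operating point
as *marginal* per-stage rates: correct-label 0.80 (Early), 0.69 (Best, with
0.18 confused to Early), 0.86 (Late), 0.54 (Other), with the remaining mass
assigned to missed detections, since the reference analysis attributes the
shortfall to flowers not being detected rather than to misclassification.
No rate is published for Too late; the default uses 0.80 correct / 0.20
missed, comparable to Early. Internally the model is a per-stage miss
probability plus a row-stochastic confusion matrix conditional on detection,
so e.g. Best→Early is 0.87 × (0.18/0.87) = 0.18 marginally. Box corners get
Gaussian jitter (σ = 2 px); confidences are uniform on [0.5, 1.0] for
correct labels and [0.25, 0.75] for confused ones — arbitrary but fixed.
Spurious (false-positive) detections default to rate 0 and can be enabled.

All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
equal seeds give identical scenes and detections.

**What passing simulations show — and what they don't.** The simulator
validates the *arithmetic pipeline*: that occluding a fraction q of flowers
drives the mean count error to −100q, that the reciprocal factor 1/(1−q)
cancels it, and that pooled IoU-matched confusion recovers the generating
rates. It does not model appearance, lighting, camera pose, correlated
occlusion along branches, or detector failure modes beyond an i.i.d.
per-stage confusion/miss model, so it says nothing about how well any real
detector classifies real flowers.

## Problem sizes in the test and acceptance runs

The worked-example checks are exact arithmetic on one branch (42 detected /
62 actual flowers) and run in milliseconds. Monte-Carlo checks use 60 scenes
of 62 flowers for the occlusion-error relationship (tolerance: 3 binomial
standard errors of the pooled mean) and 200 scenes for confusion-rate
recovery (3 binomial SEs per cell, floored at 0.015 absolute to absorb rare
jitter-induced mismatches). The exhaustive NMS oracle enumerates subsets of
≤ 6 boxes.

## Known limitations

* The Other-stage price uses the *post-NMS detected* Late/Too-late ratio of
  the same image set; when those counts are zero the `p_late/2` fallback is a
  convention, not a measurement.
* Reference tables are transcription-validated but variety-specific; applying
  a packaged table to another variety silently mis-prices counts.
* The occlusion correction is a scalar on the aggregate; per-stage corrected
  contributions are deliberately not produced.
* Count-form and pollen-form error percentages diverge when stage
  composition differs between detected and actual flowers; both are exposed.
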