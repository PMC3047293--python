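# Methods

This note records the modelling choices behind `sfindex`, the defaults and
why they were chosen, and what the synthetic cohorts do and do not emulate.

## The model

An eye is a pair of same-day measurements: a Humphrey 24-2 visual field
(Total Deviation per scored location, dB, plus MD/PSD) and an HRT disc scan
(measured and Moorfields-predicted neuroretinal rim area per sector, mm²).
Total Deviation is used rather than Pattern Deviation: TD already embeds
age correction, and the index's anatomical weighting itself discounts
diffuse loss that has no structural counterpart, so PD's diffuse-loss
correction would be redundant and would mask true diffuse disease.
Likewise the Moorfields-predicted rim area is taken as an input because it
embeds the disc-area and age normalisation; this package deliberately does
not reimplement that regression.

For each field location `j` and disc sector `s`:

* `P_field(j)` = 1 − CPF_j(TD_j), the empirical probability that the
  location's TD is abnormal relative to a reference cohort;
* `P_sector(s)` = 1 − CPF_s(measured_s − predicted_s);
* `P_anatomy(j, s)` = mass of a wrapped normal distribution of the
  location's disc insertion angle inside sector `s`'s arc;
* `SFI(j) = P_field(j) · Σ_s P_sector(s) · P_anatomy(j, s)`.

The index treats the three probabilities as independent given the anatomy,
which is the model's central assumption: a field defect and a rim defect
corroborate each other exactly to the extent that a nerve fiber bundle
could connect them.

### Empirical CPFs

The reference distributions are purely empirical — no parametric family is
imposed — because glaucoma-suspect TD distributions are skewed and
heavy-tailed. Evaluation uses Hazen plotting positions `(i − 0.5)/n` with
linear interpolation between order statistics. Interpolation (rather than
a step ECDF) was chosen to honour the continuous-probability intent of the
construction; the difference is O(1/n) at n = 500. Outputs are clamped to
`[1/(2n), 1 − 1/(2n)]` — the Hazen positions of the extreme order
statistics — so no probability is ever exactly 0 or 1. The clamp matters
downstream: the hemifield point score `1/(10(1 − SFI))` diverges as the
index approaches 1.

Reference models are fitted per laterality, with no mirroring of left-eye
data onto right-eye templates, to preserve any systematic laterality
differences (e.g. testing order). Fitting requires at least 20 eyes per
location/sector (configurable); the intended scale is ~500 eyes per
laterality.

### The anatomy map

The packaged map assigns each of the 52 right-eye locations a mean
insertion angle on the disc circumference, in an anatomical convention
shared by both eyes: 0° = temporal pole, 90° = superior, 180° = nasal,
270° = inferior. The mean-angle table is hand-constructed configuration
data following the retinotopy established by red-free-photograph mapping
of nerve fiber layer defects: superior field → inferior disc and vice
versa; central points just off the horizontal feed the papillomacular
bundle near the temporal pole; the nasal periphery feeds wide arcuate
bundles entering near the vertical poles; temporal field points insert
nasally. Inferior-field angles are the reflection `a → 360° − a` of their
superior partners (raphe symmetry), and the left-eye map is the x-mirror
of the right-eye map — under the anatomical angle convention the
sector-linkage vector of a mirrored point is identical sector-for-sector.

The per-point angular *variances* measured by the map's originators were
never published, so a uniform default SD of 15° is applied to every point.
The pair (mean 279.64°, SD 15°) at location (3°, 15°) reproduces the one
published calibration example — a 74%/26% split between the inferotemporal
and inferonasal sectors — and that example is used as a sanity check
(tested with ±0.02 tolerance), not an exact assertion. The full table
(means and SDs) is overridable from YAML.

Sector arcs default to the standard HRT sectors — temporal [315°, 45°),
superotemporal [45°, 90°), superonasal [90°, 135°), nasal [135°, 225°),
inferonasal [225°, 270°), inferotemporal [270°, 315°) — and are
configurable. Wrapped-normal masses are computed by summing the plain
normal CDF over ±2 extra circle periods (truncation error < 1e-12 for
SD ≤ 60°). Sectors holding less than 1e-6 anatomical mass are skipped in
the fusion sum; they contribute only zero terms.

### The hemifield test

The ten clusters are packaged configuration data shaped after the
published hemifield-test layout (region 1 = the 3-point nasal step,
regions 2–4 arcuate, region 5 central/temporal; sizes 3, 5, 6, 6, 6).
Unlike the device's test, the packaged clusters partition *all* 52 scored
locations, so the diffuse-loss score sum reflects the whole field (an
all-floor field scores exactly 52 × 0.1). The cluster table is
overridable.

Per-point scores cap at 100, binding from an index of 99.9% upward; the
cap is applied exactly at that stated threshold rather than through the
raw reciprocal to avoid float-representation wobble at the boundary.

The six summary statistics are referred to reference ECDFs with
`[1/(n+1), n/(n+1)]` bounding so no abnormality probability reaches 1,
keeping ROC thresholds well-defined. Paired differences are scored
two-sided (`2·max(F, 1−F) − 1`), since either hemifield may be the damaged
one; the score sum is one-sided (large = abnormal). The sidedness is
configurable (`two_sided=False` uses the upper tail of each difference);
two-sided is the default because a one-sided rule would miss
inferior-hemifield disease by construction.

## Evaluation

* AUC is computed by the rank (Mann–Whitney) formulation with half-credit
  ties, which equals the trapezoidal area of the tie-collapsed curve; the
  tests verify this against exhaustive pairwise concordance.
* AUC standard errors use the Hanley–McNeil moments
  `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`.
* Paired AUC comparison needs the correlation between the two AUC
  estimates. It is looked up from a table indexed by the average
  class-conditional Spearman correlation of the two scores and the average
  AUC. The packaged table was generated once by bivariate-binormal
  Monte-Carlo simulation (4000 replicates of n = 100 + 100 per cell over a
  10 × 9 grid; `scripts/generate_hm_table.py`) — the same construction
  that underlies the published table — and is bilinearly interpolated.
  Entries carry Monte-Carlo noise of about ±0.02, negligible relative to
  the sampling error of the statistic itself. The unpaired variant sets
  the correlation to 0.
* Sensitivity/specificity confidence intervals are exact Clopper–Pearson,
  substituted for the interval method the original analysis cited (whose
  individual intervals are not available for verification); outputs are
  labelled with the method used.
* The optimal operating point minimises Euclidean distance to
  (sensitivity, specificity) = (1, 1); exact ties resolve to the lower
  threshold.

## The synthetic cohorts

The generator's defaults are the study conditions:

| parameter | default | unit | rationale |
|---|---|---|---|
| `mean_td` | −0.46 | dB | suspect-group mean MD of the clinical cohorts |
| `sigma_global` | 1.69 | dB | with `sigma_local`, gives MD SD ≈ 1.7 |
| `sigma_local` | 1.8 | dB | suspect-group mean PSD |
| `sigma_rim` | 0.08 | mm² | plausible sector rim-difference noise |
| `defect_probability` | 1.0 | — | every glaucomatous eye carries damage |
| arc centers | 292.5° (w 0.55), 67.5° (w 0.45) | deg | inferotemporal/superotemporal predilection |
| `arc_width_mean` | 70 | deg | about 1–2 sectors of involvement |
| `depth_shape` | 0.8 | — | right-skewed severity (many mild, few severe) |
| `depth_mean` | 27.5 | dB | calibrated, see below |
| `rim_loss_coef` | 0.01 | mm²/dB | total rim loss 0.2–0.3 mm² for deep defects |

Reference and suspect eyes share one distribution (the clinical reference
group *was* a suspect subsample): TD_j = g + ε_j with
g ~ N(−0.46, 1.69²) shared across the eye and ε_j ~ N(0, 1.8²) pointwise,
floored at −35 dB; sector rim differences are N(0, 0.08²). In expectation
this reproduces the suspect group's reported MD mean/SD (−0.46, 1.7) and
PSD (1.8) exactly, since MD is computed as the unweighted TD mean and PSD
as the TD standard deviation — a documented simplification of the device's
proprietary variance-weighted indices that affects only simulation labels,
never the index itself.

Glaucomatous eyes additionally receive at most one focal defect: an
angular arc on the disc; every field point is depressed by
`depth × (insertion mass inside the arc)` and every sector loses
`rim_loss_coef × depth × (fraction of the arc in the sector)`. Damage is
therefore anatomically concordant by construction; `discordant_mode`
relocates the rim loss 180° away, preserving both marginal severities
while severing the link — the contrast used to test that the index
rewards anatomical concordance. `depth_mean = 27.5` dB was solved once by
simulation so that the expected cohort mean MD equals −6.3 dB (the
glaucoma group's reported mean) under the default arc geometry and floor.

What the generator does **not** emulate: multi-focal and purely diffuse
loss (so the simulated glaucoma MD spread, SD ≈ 4.9 dB, is narrower than
the clinical 8.3 dB, and simulated PSD runs higher than the clinical 4.9
dB mean — purely focal damage is more spatially heterogeneous than real
mixed damage); test-retest variability and its eccentricity dependence;
fixation losses and lens artefacts; correlated measurement noise between
neighbouring points; HRT segmentation error structure; longitudinal
change. Passing pipeline tests on these cohorts demonstrates internal
consistency of the method and its discriminative behaviour under the
stated generative assumptions, not clinical performance; the clinical
AUCs of the original cohorts cannot be reproduced without patient data.

## Problem sizes

The packaged tests fit reference models on 500 simulated eyes (the scale
of the original reference population per laterality), evaluate
discrimination on 300 eyes per group, the linkage contrast on 200 paired
eyes, and the calibration checks on the original group sizes (499
suspects, 895 glaucoma). Monte-Carlo oracles use 10⁶ draws.

## Degenerate inputs and tie-breaks

* Records with missing or non-finite TD points are rejected, not imputed.
* Exact MD ties in worse-eye selection keep the right eye.
* Duplicate (subject, laterality) pairs are an error.
* Degenerate AUCs of exactly 0 or 1 return a standard error of 0 with a
  warning.
* CPF evaluation at a value outside the reference range returns the clamp,
  never 0 or 1.

## Known limitations

* The anatomy map's means and SDs are approximate reconstructions; users
  with access to measured insertion-angle data should override the table.
* The hemifield cluster table follows the published layout in shape but
  extends it to cover all 52 points; device GHT categories are accepted
  as optional inputs for comparison, never recomputed.
* Only one focal defect per simulated eye (v1).
* The paired-AUC correlation table is itself a simulation product;
  for definitive inference on real data a resampling method would be
  preferable.
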