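# Methods

## Model and procedure

`cbctresp` quantifies early tumor response between two CBCT time points
(first and last treatment fraction) on a single axial slice per fraction.
The procedure is:

1. **Slice selection.** The analysis slice is the one with the largest
   tumor cross-section: among the contiguous slices on which the
   8-connected region through the seed at the iso value is non-empty, the
   slice with the maximal region pixel count is chosen (ties toward the
   lower index). Whether "central part of the tumor" should be anatomical
   or maximal-cross-section is genuinely open; maximal cross-section is the
   reproducible operationalization used here.

2. **Iso-pixel contour.** The tumor is the 8-connected component of pixels
   at or above a single HU threshold containing the seed, with interior
   holes filled. Pixels equal to the threshold are included (`>=`), which
   makes the mask deterministic under ties. A component touching the image
   border has no closed contour and is rejected. The traced boundary is a
   Moore-neighbor walk over the mask's outer boundary pixels.

3. **Iso-value policy.** The threshold is the midpoint between the mean HU
   of the 3×3 seed neighborhood and the background mean. It is computed
   once, on the first-fraction image, and reused verbatim on the last
   fraction, so area change is measured against a fixed HU level rather
   than a per-fraction adaptive one. Because the background mean itself
   requires a contour, the first fraction is processed in two passes: a
   crude background estimate (the slice median, dominated by lung in a lung
   window) gives a provisional contour, whose annular ROI supplies the
   final background mean and threshold.

4. **Background ROI.** An annulus of pixels whose Euclidean distance to the
   tumor mask lies in `(inner, outer]` pixels, defaults 2 and 10. The inner
   gap avoids partial-volume pixels on the contour; the outer limit keeps
   the sample local. An optional exclusion mask removes adjacent bright
   anatomy (chest wall, large vessels). The annulus must fit inside the
   image and be non-empty after exclusion.

5. **Per-fraction quantities.** Tumor mean/SD (`T`, `σ_T`) and background
   mean/SD (`B`, `σ_B`) are means and *population* standard deviations
   (`ddof=0`) over the masks; `CNR = |T − B|/√(σ_T² + σ_B²)`;
   `A` = pixel count × pixel pitch² (mm²); `μ_max` maps the maximal tumor
   HU through `μ = (1 + HU/1000)·μ_water`. An optional 3×3 median filter
   restricted to the mask (`smooth=True`, default off) suppresses
   single-pixel spikes before the maximum; the default matches a
   planning-system voxel maximum.

6. **Ratios and call.** `R_A`, `R_CNR`, `R_μ` are last/first ratios and
   `R` their product, so growth, rising contrast or rising density each
   push `R` above 1. `R ≤ R_C` is controlled, `R > R_C` progression, with
   `R_C = 1.1` as the calibrated default.

7. **Calibration.** Candidate cutoffs are midpoints between consecutive
   distinct cohort scores plus sentinels outside the range. At each cutoff,
   classification uses the same `≤` rule as the response call (positive
   class = controlled), so the reported cutoff is directly usable.
   AUC is the trapezoidal area under (1 − specificity, sensitivity); by
   construction it equals the Mann–Whitney pairwise statistic (controlled
   case scoring below a progression case = correctly ordered pair, ties ½),
   which the tests assert to 1e−9. The operating cutoff maximizes Youden's
   `J = sens + spec − 1` (ties toward the smaller cutoff). The AUC CI is a
   stratified percentile bootstrap (resampling within class, default 2000
   replicates, seeded); the interval is widened minimally if needed so it
   always brackets the point estimate.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `inner_margin_px`, `outer_margin_px` | px | 2, 10 | background annulus geometry; the source procedure leaves the ROI unspecified, an annulus is the least arbitrary "surrounding area" |
| `mu_water` | cm⁻¹ | 0.195 | water attenuation at a typical CT effective energy; cancels in `R_μ` and every classification, affects only absolute μ reporting |
| `cutoff` (`R_C`) | – | 1.1 | the cohort-calibrated decision threshold |
| `smooth` | – | off | median filter before peak μ; off matches a raw voxel maximum |
| bootstrap `reps`, `level` | – | 2000, 0.95 | CI precision/coverage |

HU calibration of the scanner is taken at face value from metadata; no
scanner-specific correction is attempted. Within-patient ratios absorb a
pure gain error exactly (`R_CNR`, `R_μ`) and an offset partially (`R_μ` is
*not* offset-invariant); this is documented rather than corrected.

## Ratio orientation

The ratios are implemented as LAST over FIRST, so that growth yields values
above 1 and a cutoff of 1.1 reads "a 10% increase calls progression". This
is the only orientation consistent with the calibrated cutoff and with the
interpretation of `R_A = 1.15` as a 15% area increase.

## The phantom generator

Each phantom pair is an elliptical soft-tissue tumor (default 50 HU, with a
small concentric dense core at +30 HU) in aerated lung (−800 HU) on a
128×128 grid at 0.9 mm pitch, with additive white Gaussian noise in HU
(default SD 20). Between fractions the generator applies multiplicative
ground-truth changes: semi-axes scale by `√area_factor`, tumor-to-lung
contrast by `contrast_factor` (noise SD fixed, so the CNR ratio tracks the
factor analytically), and the core height by `peak_factor` (so the peak-μ
ratio has the closed form `(1 + HU_L/1000)/(1 + HU_F/1000)`). Noise seeds
are `seed` and `seed + 1` for the two fractions: independent noise, full
determinism. Cohorts default to 124 controlled : 10 progression, mirroring
the prevalence the method was calibrated on, with per-class uniform factor
ranges.

What the phantom does **not** emulate: CBCT streak/scatter artifacts,
respiratory motion blur, anatomical background structure (vessels, chest
wall), irregular tumor shapes, and scanner HU drift. Passing phantom tests
therefore shows the pipeline is correct and self-consistent — that it
recovers known geometric/contrast/density changes — not that the metric
separates real responders from progressors; that evidence comes from the
clinical cohort the method was calibrated on, which is not redistributable.

## Numerical choices

- Connectivity: 8 for region labeling; boundary pixels traced with
  8-neighborhood Moore steps. Holes filled before any area or statistics.
- Population SD (`ddof=0`) for `σ_T`, `σ_B`; masks need ≥2 pixels.
- Undefined confusion fractions (zero denominator) are reported as absent
  (`None`), never as 0.
- ROC sentinels: `0.5·min(score)` and `1.5·max(score)` (scores are
  positive), guaranteeing the sweep reaches both trivial classifiers.
- Degenerate inputs rejected rather than guessed: non-positive contrast at
  the seed, components touching the border, empty annuli, single-class
  cohorts, fewer than two distinct scores, HU below −1000.
- Test problem sizes: 128×128 phantoms, cohorts of ~10–22, 100×8-record
  AUC-oracle cohorts, 2000-cohort null simulation — sizes chosen so the
  full suite runs in a few seconds while keeping every check exhaustive or
  statistically powered (3-SE bands).

## Known limitations

- Single-slice analysis; no volumetric aggregation or registration between
  fractions.
- The peak μ is taken over the analysis slice, not the whole volume (the
  source procedure is ambiguous on this point).
- Area is reported in mm²; when pixel spacing is constant across fractions
  the ratios are unaffected by the unit choice.
- The iso-value selection rule and background ROI geometry are the
  package's own operationalizations of an under-specified manual procedure
  (ImageJ contouring); both are configurable.
- The bootstrap CI is percentile-based; no analytic (DeLong) interval.
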