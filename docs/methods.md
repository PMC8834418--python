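# Methods

This note documents the models, numerical choices and limitations behind
`wellphen`, in the order the pipeline runs.

## Flat-field correction

Microwell frames are modeled as a smooth illumination field (vignette)
with small dark objects (rims, clusters) on top.  The field is estimated
by a wide Gaussian blur and removed subtractively:

    corrected = image − blur_σ(image) + mean(blur_σ(image))

Adding back the mean keeps absolute gray levels meaningful, which matters
because `nGV` is a ratio of gray values.  A divisive variant
(`image / blur × mean`) is available for data that follow a multiplicative
shading model.

* `sigma_px` defaults to `width / 8` — several well diameters, so
  well-scale objects barely contaminate the background estimate.  On
  frames much smaller than a typical array (a handful of wells), pass a
  sigma of at least two well widths explicitly; otherwise dark clusters
  locally depress the estimate and inflate their own corrected intensity.
* The blur is computed on a frame padded by **odd reflection**
  (`f(edge+d) = 2f(edge) − f(edge−d)`), which continues the illumination
  gradient across the border.  Plain nearest/reflect padding flattens the
  gradient and leaves a border band in the corrected image; with odd
  reflection a quadratic vignette (center 0.9, corner 0.6) corrects to a
  residual relative range below 3%.
* Constant frames are exact fixed points; correction is idempotent to
  within 0.02 per pixel.

## Well detection

The well geometry is known a priori (250 × 150 µm footprint, dark rim), so
detection is model-based rather than generic:

1. threshold dark pixels at 60% of the robust background level (99th
   percentile of the corrected frame).  A fixed fraction is used instead
   of Otsu because the dark class occupies a few percent of the frame at
   most, and Otsu degenerates on near-noiseless histograms with a tiny
   minority class;
2. fill holes, label connected components, and fit a moment-based ellipse
   to each (centroid, principal-axis lengths, orientation);
3. shrink the fitted axes by the rim width (default 3 px) to recover the
   well *interior*, which defines the crop rectangle and the pixel-count
   mask — this keeps `N_t` free of rim-shadow pixels;
4. gate candidates by expected axis lengths (default tolerance ±30%) and
   aspect ratio within [1.2, 2.3] (nominal 250/150 ≈ 1.67), merge
   overlapping detections keeping the better-fitting one, and sort in
   raster order.

Wells whose interior would be clipped more than 40% by the frame edge are
discarded: a partial well biases `N_t` and therefore size and RGVS.  On
noise-free synthetic grids, recall is 100% with no false positives over
20 seeds, centers within 3 px, axes within 10%.

## Cluster segmentation

Edge detection plus morphology, in fixed order: Sobel gradient →
binarize → dilate with linear structuring elements (length 3 at 0° and
90°) → fill holes → clear objects touching the crop boundary → erode
(2 iterations with the same elements) → intersect with the well-interior
mask.  Erosion iterations match the dilation so the footprint bias roughly
cancels; both are configurable (`segment.dilate_len_px`,
`segment.erode_iters`).

Before the gradient is computed, every pixel outside the well interior is
replaced by the crop's robust background level (90th percentile of
interior gray values).  The rim's own edge is structural — its position is
known exactly from the fitted ROI — and without suppression it forms a
closed ring that hole-filling floods into a full-well mask, which
border-clearing then deletes wholesale.  With substitution, a cluster
reaching the well boundary still closes its edge ring against the
substituted background, so large clusters are segmented correctly.

The binarization threshold defaults to Otsu on the gradient magnitude and
accepts a scalar override for exact reproducibility.  A uniform crop (no
gradient) returns an empty mask, which is a valid "no cluster" outcome,
not an error.  Against ground-truth disks (radius 20 px, contrast 0.4,
sensor noise σ = 0.02) the mask IoU exceeds 0.85; measured area fractions
track the rasterized truth within ±0.07 across f ∈ {0.1, 0.2, 0.4, 0.6}.

## Phenotype parameters

* `S = (N_w/N_t) · L_m · W_m` with `L_m = 250` µm, `W_m = 150` µm; a full
  well is 37 500 µm².
* `GV_max` is the **99.5th percentile** of well-interior gray values, not
  the literal maximum, to resist hot pixels (configurable constant).
* `nGV` = mean cluster gray value / `GV_max`, clipped to [0, 1].  An empty
  mask reports `nGV = 1` (fully transmitting well) with a `no_cluster`
  flag.
* `SD_GV` is the **population** (n-divisor) SD over cluster pixels;
  `nSD_GV = SD_GV / GV_max`.  The population convention is used throughout
  (including cohort aggregates) because it reproduces the published
  ± figures exactly.
* `RGVS = nGV / (N_w/N_t)`.  The ratio is taken against the dimensionless
  area fraction rather than the µm² size: the published RGVS scale
  (≈ 2.6–6.0) is only compatible with a dimensionless denominator, and
  `S` is reported separately in µm².  This convention is a package
  decision, documented rather than asserted as the original authors'.
* `RGVSD = nGV / nSD_GV`.
* Ratios with a zero denominator are reported **missing** (NaN), never 0.
* All normalized metrics (`nGV`, `nSD_GV`, `RGVS`, `RGVSD`) are exactly
  invariant under global intensity rescaling, since `GV_max` scales with
  the image.

Metrics are computed over cluster pixels only, not the whole well; the
gray-value parameters describe the cluster material, and diluting them
with empty-well background would couple them to cluster size.

## Stratification

Patients form thick, rough clusters, so the patient-likeness direction is
fixed per parameter: lower `nGV`, higher `nSD_GV`, lower `RGVSD`.  Scores
are oriented before any ROC computation.

* AUC is the Mann–Whitney probability with ties counted 0.5 (computed via
  midranks); it equals exhaustive pair counting exactly, which the test
  suite asserts on 100 random instances.
* The Youden threshold maximizes `J = sens + spec − 1` over midpoints
  between consecutive distinct oriented scores plus ±∞; ties break toward
  higher sensitivity, then lower oriented threshold.  The returned cutoff
  is mapped back to original units (`value < t` calls patient for
  lower-is-positive parameters).
* Fixed-threshold calls use `nGV < 0.685`, `nSD_GV > 0.065`,
  `RGVSD < 9.712`.  The three votes combine by majority (configurable to
  per-parameter output only); a missing metric abstains, an exact tie or
  all-abstain yields "unknown".
* Two-sample comparisons use pooled-variance Student's t-tests, two-sided,
  uncorrected (an optional Holm adjustment is deliberately not applied by
  default, matching the uncorrected pairwise reporting convention).
  Zero-variance degenerate inputs resolve analytically (equal means →
  p = 1, unequal → p = 0).
* Group reports (treatment cycle, T/N/cancer stage) give per-group
  mean ± SD of `S`, `nGV`, `RGVS`, all pairwise t-tests, and a
  monotone-trend flag: the sign of the Spearman correlation between group
  order and group means.  Stage labels are parsed into orderable keys
  (T2 < T4, IA < IIIC …); unorderable labels raise an error naming the
  label.
* ROC analysis can pool every well (`unit="cluster"`, default) or average
  wells per sample first (`unit="sample"`).

## Synthetic scenes

The generator emulates what the phenotypes measure, not the full optics:

* bright background 0.85 × radial vignette (`1 − strength·d²`, strength
  ∈ [0, 0.5]); dark rims (0.25, 3 px) drawn just outside the nominal well
  interior; additive Gaussian sensor noise;
* cluster pixels are `background × (transmittance + texture)`, with
  texture ~ N(0, `roughness_sd_true`).  Ground-truth transmittance is thus
  defined **relative to local background**, matching the per-well-max
  normalization downstream — after flat-field correction the vignette must
  not bias `nGV`, and this coupling is the key end-to-end test of the
  correction module.  `roughness_sd_true` is in normalized units (the
  target `nSD_GV`); the rendered raw-intensity SD is ≈ `roughness × 0.85`;
* footprints are equal-area disks (elongating into well-shaped ellipses
  when a disk would not fit) or wobbled blobs; rasterized areas land
  within 2% of the requested fraction;
* default geometry: 2 µm/px, 400 × 280 µm well pitch.

Cohort presets use the published per-cluster statistics — healthy
`nGV 0.68 ± 0.07`, `nSD_GV 0.054 ± 0.013`; patient `0.62 ± 0.05`,
`0.085 ± 0.017` — drawn as truncated Gaussians.  Area fractions are not
published; the patient mean of 0.18 was chosen so that
`RGVS = nGV/f ≈ 3.4` matches the reported pretreatment RGVS level
(3.45 ± 1.15), and healthy monolayers get a looser 0.30 ± 0.08.  The
default fixture sizes (5 healthy, 4 patient samples) mirror the study
cohorts.

Within one sample, replicate wells share a **material constant**
(thickness per area): each well draws its own area fraction and scales its
transmittance proportionally, so size and `nGV` fluctuate together while
RGVS stays stable within the sample.  This encodes the assay's robustness
property — RGVS is approximately a per-sample invariant — and is what
makes the within-sample CV of RGVS smaller than the CVs of size and `nGV`.
Note that with *independent* per-well draws this inequality cannot hold
(`CV(nGV/f) ≥ CV(f)` by construction), so the correlation is a modeling
requirement, not a convenience.

What the generator does **not** emulate: phase-contrast halos, focus
drift, debris and bubbles, well-to-well illumination interplay, 3-D
cluster structure, or the frequency of cluster formation.  Passing the
synthetic suites therefore demonstrates correctness of the measurement
chain under the stated image model, not clinical performance; the
published patient-cohort AUCs are not reproducible without the original
images.

## Problem sizes in the test and acceptance runs

Synthetic suites use 2×2 or 1×2 well arrays at 2 µm/px (frames of roughly
280 × 400 px), 5–20 seeds per condition, and score-level cohort draws of
n = 60 per class over 50 seeds; the acceptance script runs a 9-sample
cohort with 8 wells per sample and a 40-well recovery sweep.  These sizes
give stable statistics for every asserted tolerance while keeping a full
run in tens of seconds.

## Known limitations

* Absolute cluster thickness in µm is out of reach without optical
  calibration; `nGV` is a relative proxy.
* Wells must match the expected geometry within the detection tolerance;
  the detector is deliberately not a generic ellipse finder.
* A cluster genuinely touching the well rim loses its rim-adjacent
  boundary to the border-clearing step, slightly shrinking its footprint.
* Sensitivity/specificity of the fixed thresholds on synthetic cohorts
  depend on the unpublished area-fraction presets; only directional
  statements (ordering of AUCs, sign of group trends) are asserted.
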