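# Methods

## Optical densitometry

Transmitted-light darkness of a stained region is expressed as
`OD = log10(I_bk / I_m)` with `I_bk` and `I_m` the mean 8-bit intensities
of a local background ROI and the tissue ROI.  Measuring against the
*geometrically closest* background ROI (centroid Euclidean distance, ties
broken by annotation order) cancels uneven specimen illumination; OD is
dimensionless and, for a chromogenic reaction stopped inside its
exponential phase, proportional to deposited chromogen and hence enzyme
activity.

Choices that needed fixing:

* **Grayscale conversion** of color images uses luminance weights
  0.299 R + 0.587 G + 0.114 B, the ImageJ default, so monochrome- and
  color-camera data are treated consistently.
* **Dark-pixel floor.**  `I_m` is floored at 1 intensity unit (logged when
  it triggers) so saturated-dark regions give a large finite OD rather than
  infinity.  Negative OD (background darker than sample) is allowed and
  logged, as it is a real signal of a mis-annotated or artifactual pair.
* **Slide matching.**  Mutant and reference measurements are only combined
  when they share a `slide_id`: sections must be stained on one glass slide
  to be directly comparable.  The normalized ratio is
  mean(mutant OD) / mean(reference OD) over slide-matched groups; the
  reference strain normalizes to exactly 1.  Whether means should be taken
  per slide first is genuinely open; pooling across matched slides was
  chosen because typical designs put all strains on every slide, making
  the two readings identical.
* **Statistics.**  "Student's t-test" is taken literally: two-sided,
  two-sample, pooled variance (not Welch).  Zero-pooled-variance samples
  follow a documented convention (equal means → p = 1, unequal → p = 0).
  Confidence intervals are mean ± t·sd/√n on the mutant OD sample, then
  divided by the reference mean — matching per-sample error bars rather
  than propagating the ratio's error.
* **Exposure linearity.**  Cameras with automatic exposure are checked by
  the Pearson correlation of exposure time against background intensity;
  the warning threshold (r < 0.99) is configurable.

## Oil-Red-O two-step segmentation

Step 1 converts the RGB image to grayscale and applies an IsoData
(Ridler–Calvard iterative intermeans) threshold: iterate
`T ← (mean(gray ≤ T) + mean(gray > T)) / 2` on the 256-bin histogram to its
fixed point.  Pixels at or below `T` form the section (sections are darker
than the bright background; the polarity is a config flag).  No
morphological cleanup is applied by default — opt-in small-component
removal exists but the core method uses the raw threshold mask.

Step 2 classifies each section pixel by its dominant channel with *strict*
inequalities; channel ties and green-dominant pixels form an explicit
`unclassified` class that enters neither numerator nor denominator of the
positivity ratio `PX_red / (PX_red + PX_blue)`.  The four classes
(background / red / blue / unclassified) partition the image exactly; this
conservation is property-tested.  When a scope contains no classified
pixel, the ratio is reported as undefined (None) rather than raising.

## Staining kinetics

Sigmoid stain accumulation (lag → steep rise → plateau) is modeled with a
four-parameter logistic, the minimal sigmoid with that shape:

    od(t) = baseline + A / (1 + exp(-k (t - t_mid)))

Fitting uses bounded least squares (`A, k > 0`) from a heuristic start —
baseline = min(od), A = od range, t_mid = first half-range crossing, k from
the steepest finite-difference slope via slope_max = A·k/4 — plus five
seeded, jittered restarts before declaring failure.  Traces need ≥ 5
points and an OD range > 0.02 (flat traces carry no kinetic information).

"Onset of the exponential phase" has no standard definition in staining
histochemistry, so the lag-time convention from growth-curve analysis is
adopted: the tangent at the inflection meets the baseline at
`t_onset = t_mid − 2/k` and the plateau at `t_end = t_mid + 2/k`.  Onset is
floored at the first sampled time, which matters for reactions whose start
cannot be recorded (wax-sealed slow reactions): such traces carry a
`truncated` flag and their fit tolerates the missing left tail.
Background-corrected OD is used throughout, so the window is invariant
under rescaling the OD axis and equivariant under time shifts (both
property-tested).

## Synthetic validation data

No real stained-section images with ground truth exist publicly, so every
pipeline stage is validated on synthetic data:

* **Sections** (default 256×192 px): a bright background (245,245,245), an
  elliptical wormlike section filled with counterstain blue (70,80,170),
  three tissue compartments (intestine, distal and proximal germline — the
  tissues annotated for lipid quantification), and red (180,40,50) disk
  droplets of radius 1–4 px placed by a seeded uniform point process.
  Droplet placement is bookkept pixel-exactly: the last droplet is trimmed
  so the achieved red fraction equals the target within rounding, and
  ground truth records the achieved fraction exactly.  Channel noise is
  Gaussian (σ = 8 by default), chosen to exercise but not defeat the
  strict-inequality classifier.  Preset lipid fractions (red pixels /
  compartment pixels): wild type `n2` = {intestine 0.30, proximal germline
  0.20, distal germline 0.08}; `daf2` doubles and `lpd3` halves every
  entry, so a two-fold increase and a 50% level are true by construction
  and must be *recovered*, not asserted, by the pipeline.
* **OD panels**: background intensity 240, compartment intensity
  240 × transmittance, Gaussian noise (σ = 2 default); true OD is
  −log10(transmittance).
* **Kinetics traces**: the logistic above sampled at fixed intervals with
  Gaussian OD noise (σ = 0.005).  Presets place the onset at 5 min (NADH:
  A = 0.60, t_mid = 7, k = 1), 10 min (SDH: A = 0.55, t_mid = 13,
  k = 2/3) and 120 min (COX: A = 0.25, t_mid = 135, k = 2/15, first
  10 min truncated, smaller amplitude because the DAB product is lighter
  than NBT formazan).

What the synthetic data does *not* emulate: sectioning artifacts, folds,
out-of-focus blur, stain batch variation, droplet size distributions of
real tissue, or spatial autocorrelation of camera noise.  Passing
recovery tests therefore demonstrates the *analysis* is correct and
unbiased under controlled conditions, not that segmentation is robust to
every real-world artifact.

## Validation problem sizes

Strain-contrast recovery uses 20 sections per preset at 256×192 px;
kinetics onset recovery uses 50 noisy traces per stain preset; the
statistical calibration suites use 10,000 null replicates (t-test type-I
error) and 2,000 replicates (CI coverage).  These sizes give Monte-Carlo
standard errors comfortably inside the stated tolerances.

## Numerical and design notes

* Coordinates are 0-based, x rightward, y downward, pixel centers at
  integers; rectangles/ovals rasterize half-open so adjacent ROIs tile
  without overlap; polygons use the even-odd rule.  A brute-force
  pixel-center enumeration is the test oracle for all rasterization.
* ImageJ `.roi` support covers the area shapes (type codes 0, 1, 2, 7);
  lines and points are rejected loudly.  Freehand and polygon outlines are
  treated interchangeably.  Tissue classes are inferred from ROI names by
  case-insensitive prefix (`bg`/`background`, `intestine`, `body`, …);
  unmatched names become `other`.
* The IsoData implementation is checked against both an exhaustive
  fixed-point search over all 256 levels and scikit-image's independent
  implementation.
* Batch CSV outputs are byte-reproducible for a fixed config and seed.
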