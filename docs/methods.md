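# Methods

This note records the models, parameter choices and numerical conventions
behind `hdabquant`, and what its synthetic-data tests do and do not show
about real slides.

## Optical density and stain separation

Transmitted-light chromogens obey Beer–Lambert absorption, so stain
concentrations combine (approximately) linearly in per-channel optical
density, `OD_c = −log10((I_c + ε)/I0_c)`. The offset ε (default 1 intensity
unit, configurable) guards the logarithm on black pixels; OD is clipped at
zero so any pixel at or above the white point maps to OD 0. The white point
I0 defaults to (255, 255, 255) and can be estimated as the 99th per-channel
intensity percentile.

Deconvolution solves the per-pixel 3×3 system with the stain matrix whose
columns are the hematoxylin, DAB and residual unit vectors. The residual is
the normalised cross product of the two stain vectors, completing an
invertible basis. Negative concentrations are clipped to zero *after* the
unconstrained solve — the common practice; the pre-clip solution is exact,
so round-trip recovery of noiseless synthetic concentrations is at machine
precision (tested < 1e-6).

Stain-vector estimation uses percentile-bracketed extreme directions in the
plane of the top two principal OD axes (the Macenko construction): pixels
with OD magnitude above 0.15 are projected onto that plane and the 1st/99th
angular percentiles become the stain directions; the one absorbing more
blue is labelled DAB. The original GUI workflow leaves its estimator
unnamed, so this estimator is a documented stand-in chosen for being
deterministic, robust, and standard for H-DAB. Fewer than 100 stained
pixels, or an angular spread under 8°, raises an estimation failure that
advises falling back to the canonical H-DAB prior (Ruifrok–Johnston
vectors, normalised).

## Nucleus detection

Detection runs on either the hematoxylin channel or the OD sum
(hematoxylin + DAB); the OD sum is the default because DAB-masked brown
nuclei disappear from the counterstain alone. The stages, all parameterised
in micrometres and converted to pixels via the raster's pixel size:

1. **Resampling** to the requested pixel size (default 0.5 µm/px) with
   area-weighted (anti-aliased) interpolation, which keeps OD statistics
   stable; requesting a size finer than native skips resampling.
2. **Median filter** (radius default 0 = off) and **Gaussian smoothing**
   (σ default 1.5 µm).
3. **Local background** by morphological opening with a disk of the
   background radius (default 8 µm; 0 disables). The opening removes
   structures smaller than the disk, so nuclei survive subtraction while
   broad fields — including tissue folds, whose background is darker than
   usual — move into the background raster. A background radius smaller
   than σ logs a warning rather than erroring.
4. **Threshold** (default 0.15 OD). The default is a starting profile for
   low-cellularity, ECM-rich tissue: high enough that faint diffuse ECM DAB
   texture stays sub-threshold, low enough that counterstained nuclei
   (OD ≳ 0.5) are kept with large margin. Like every detection parameter it
   is expected to be tuned per project during the training phase.
5. **Watershed splitting** of merged nuclei: markers are regional maxima of
   the smoothed detection image separated by at least σ, renumbered by
   (row, col) for determinism; the watershed runs on the negated image
   within the thresholded mask.
6. **Filtering** by nucleus area within [min, max] µm² (defaults 10–400)
   and by mean local-background OD under the candidate (default cutoff huge
   = disabled; enabling it at e.g. 0.3 OD rejects candidates sitting on
   folds or dense DAB debris). The "highest background considered
   acceptable" is read as the mean of the opening-based background raster
   under the nucleus mask — one concrete interpretation of a setting whose
   original semantics (pre- vs post-smoothing) are not published.
7. **Cell expansion** by a nearest-nucleus constrained dilation
   (`expand_labels`; default 5 µm — the original workflow does not state a
   distance — 0 makes cell = nucleus). Neighbouring cells never overlap.

Coordinates are 0-based pixels; physical coordinates in µm from the
top-left corner, x rightward, y downward; polygons are closed and ordered
counter-clockwise in that y-down frame; areas are pixel counts × pixel
area. Detections are sorted by (centroid y, centroid x) so object ids are
stable across runs. Circularity uses the 4-connected boundary perimeter
estimator, chosen because it keeps both calibration shapes acceptable at
0.5 µm/px (disk → 0.92, square → 0.84 against the continuum π/4 ≈ 0.785);
the residual positive bias at coarse pixel sizes is inherent to rasterised
perimeters.

## Object classification

Detections are labelled `PositiveCell` / `NegativeCell` / `NoCell` by a
seeded random forest (200 trees, inverse-frequency class weights because
NoCell examples are typically scarce) over the full measured feature set:
nucleus area, perimeter, circularity, hematoxylin and DAB OD means/maxima,
cell and cytoplasm DAB OD, cell area. Training requires at least one
example of each class and is deterministic for a fixed seed (byte-identical
serialized models). The interactive correction loop of GUI training is
replaced by file-based iteration: annotations are GeoJSON points labelled
with one of the three classes, matched to the nearest containing detection;
users append corrections and retrain. A one-feature threshold classifier
(positive iff mean nucleus DAB OD ≥ cut) serves as a deterministic baseline
and for bootstrapping annotation; it never emits `NoCell`.

Intensity grading (weak/moderate/strong) is deliberately out of scope: with
avidin-biotin amplified DAB the chromogen signal is not proportional to
antigen, so the package only scores binary cellular positivity.

## Regions and counting semantics

Regions are named polygons (holes = excluded folds) in µm, either drawn
manually (GeoJSON) or produced by the tissue thresholder: total-OD ≥ floor,
Gaussian-smoothed, small holes filled, small components dropped. Detections
are assigned to the *smallest* region containing their centroid; centroid
containment (rather than overlap fraction) makes border-straddling cells
unambiguous, and detections in no region or inside a fold hole are
"unassigned" and excluded from counts. Stain vectors and detection
parameters can be overridden per image, honouring the advice to set vectors
per region/project.

`NoCell` rows are written to results files but never enter
`positivity = 100·n_pos/(n_pos+n_neg)`; a group with no countable cells is
flagged undefined rather than silently zero. Per-slide results report each
region plus a pooled `ALL` row flagged as pooled. Isotype-control slides
are flagged in the project config; a control whose pooled positivity
exceeds a configurable bound (default 5%) raises a warning, since control
positivity bounds the method's false-positive staining.

## Post-processing

Results parsing strips vendor whole-slide suffixes (`.mrxs`, `.ndpi`,
`.czi`, `.bif`) as naming dialects only — no proprietary pyramid decoding.
The inventory join is a left join on the blinded scanner id with duplicate
keys rejected and unmatched ids reported, so no detection row is ever
silently lost; sample identity enters only at this stage, preserving
blinded analysis. Marker correlations are pairwise-complete with the
per-pair n reported and entries under 3 complete pairs suppressed —
listwise deletion would discard samples stained for subsets of markers. No
multiple-testing correction is applied to the exploratory correlation
matrix; any p-values are labelled unadjusted.

## Agreement statistics

Paired comparisons use `t = d̄/(s_d/√n)` on n−1 df, two-tailed p, the
t-based 95% CI of the mean difference, and η² = t²/(t²+df). Zero-SD inputs
are handled explicitly (p := 1 when the mean difference is also zero;
flagged infinite t otherwise).

The intraclass correlation comes from the two-way subjects × raters ANOVA
with *absolute agreement*:

```
ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))
ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)
```

with McGraw–Wong F-based 95% intervals; average-measure bounds are the
Spearman–Brown step-up of the single-measure bounds (the step-up of the
point estimate is algebraically *identical* to ICC(A,k), a property the
tests exercise to 1e-9). SPSS labels this model "two-way mixed, absolute
agreement" while computing these same two-way formulas, so either naming
convention applies. A lower CI bound past the step-up singularity
(−1/(k−1)) is reported as −∞. Subjects with any missing rating are dropped
with a logged count. Cronbach's α is `(k/(k−1))(1 − Σ item variances /
variance of sums)`. Significance (α = 0.05, two-tailed) is a report
annotation, never a filter.

One reproduction caveat: recomputing a paired test from a *printed*
(rounded) mean/SD/n summary does not exactly reproduce a p-value computed
from the raw vectors. For one of the two published method-comparison
summaries the recomputed p is 0.3844 against a printed 0.386 (and the
recomputed CI differs in the third decimal); the package reports the value
it computes and the tests carry the corresponding rounded-input tolerance
(±0.002 on p).

## Synthetic data: what it does and does not show

The generator emulates the imaging situation the pipeline targets: sparse
soft-edged nuclear disks (radius 4 ± 1 µm, ≥ 2 µm apart) over a white
background, hematoxylin OD 0.6 on all nuclei, DAB OD 0.6 on positive vs
0.05 on negative nuclei, faint diffuse ECM DAB texture (half-normal,
amplitude 0.06 OD), optional artifacts in the two classes that dominate
real low-cellularity slides — dense DAB debris blobs (12–18 µm, OD 0.9) and
fold-like streaks (20–32 µm wide bands, +0.45 OD in both stains) — then the
forward Beer–Lambert model with known stain vectors, 0.5 µm Gaussian blur
and 8-bit Gaussian sensor noise (SD 1). Default fields are 256 × 256 µm at
0.5 µm/px with 100 nuclei and 30% positive; rater tables default to the
17-slide × 3-rater design with subject SD 10, rater-bias SD 2 and error SD
5 percentage points (implied true single-measure ICC 0.775). Every output
is a pure function of its spec including the seed.

Nuclei are analytic disks rather than textured chromatin, so passing tests
demonstrate correctness of the *algorithms* (detection geometry, artifact
rejection, rate arithmetic, statistical formulas and their coverage), not
performance on real histology: real nuclei vary in shape and contrast,
ECM staining is structured rather than stationary, and scanner optics are
not modelled. Parameter defaults are starting profiles, and per-project
tuning on real slides remains the user's responsibility.

## Problem sizes in the shipped checks

The test suite and acceptance script use 512 × 512 px fields with 100
nuclei (10 seeds for end-to-end recovery, 5 for clean-field F1, 3 for the
artifact precision comparison), 200 replicate 17 × 3 rater tables for CI
coverage, and 64 × 64 OD rasters for deconvolution round trips — sizes
chosen so the full battery completes in about a minute on one CPU while
leaving the statistical assertions well-powered.
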