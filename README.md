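# hdabquant

Semi-automatic quantification of **cellular immunopositivity** on
hematoxylin–DAB (H-DAB) stained sections of **low-cellularity tissue** —
intervertebral disc, cartilage, tendon — where a high extracellular-matrix-
to-cell ratio makes naive cell detection drown in tissue artifacts (folds,
DAB debris). It is written for researchers who score immunohistochemistry by
counting positive and negative cells and want a reproducible, batch-capable
alternative to manual counting, plus the agreement statistics needed to
validate that alternative.

## What it computes

**Stain separation.** Chromogen absorbance is linear in optical density,
`OD_c = −log10((I_c + ε)/I0_c)` per RGB channel. Each pixel's OD vector is a
non-negative mixture of unit stain vectors, and colour deconvolution solves
the 3×3 system `OD = [v_H v_DAB v_res] · c` for the hematoxylin and DAB
concentration maps. Vectors can be supplied, taken from the canonical H-DAB
prior, or estimated from the image (percentile-bracketed extreme directions
in the top-2 principal OD plane).

**Nucleus detection.** On the hematoxylin or OD-sum image (the latter keeps
DAB-masked brown nuclei detectable): resample → median/Gaussian smooth →
subtract a morphological-opening local background → threshold → split merged
nuclei by marker-controlled watershed → filter by area (µm²) and by mean
local background OD (rejects folds/debris, whose background is darker than
usual) → expand nuclei into non-overlapping cell regions → measure area,
perimeter, circularity `4πA/P²`, and hematoxylin/DAB OD statistics.

**Three-class classification.** A seeded random forest (or a plain DAB-OD
threshold baseline) labels each detection `PositiveCell`, `NegativeCell` or
`NoCell`; `NoCell` detections (artifacts) are kept in the outputs but never
enter the rate

```
positivity = 100 · n_positive / (n_positive + n_negative)   [%]
```

**Batch + post-processing.** One project per antibody; per-image results are
written as tab-separated text named by the blinded scanner id
(`<ID_Slidescanning>.txt`), then parsed, joined with the sample inventory,
aggregated per (sample, antibody, image, region), correlated across markers
(Pearson/Spearman/Kendall, pairwise-complete), and rendered as heatmaps and
scatterplots.

**Agreement statistics.** Paired t-test (raw vectors or printed mean/SD/n),
95% CI of the mean difference, η² = t²/(t²+df), Pearson r, two-way
absolute-agreement ICC (single and average measures, McGraw–Wong F-based
CIs), Spearman–Brown step-up, Cronbach's α, inter-item correlation matrix.

A synthetic-data module renders H-DAB fields with known ground truth
(nucleus positions, labels, artifacts) and simulates rater tables with known
variance components, so the whole pipeline is testable without slide data.

## Worked example

```bash
hdabquant synth project --out proj --n-images 2 --seed 5
hdabquant batch run --project proj/project.yml
hdabquant postprocess --results proj/results --inventory proj/inventory.csv --out post
```

prints

```
SCAN001: ok
SCAN002: ok
results: proj/results (full)
wrote post/positivity.csv (2 groups)
```

i.e. both synthetic slides were detected, classified and written as results
files, and the post-processing step produced one positivity row per slide ×
region. Inter-rater agreement on a simulated 17-slide × 3-rater table:

```bash
hdabquant synth raters --out raters.csv --seed 2
hdabquant agree raters --table raters.csv
```

```
ICC single  = 0.792 (95% CI 0.605-0.910)
ICC average = 0.919 (95% CI 0.821-0.968)
Cronbach's alpha = 0.921
inter-item correlation matrix:
         rater_1  rater_2  rater_3
rater_1    1.000    0.757    0.814
rater_2    0.757    1.000    0.856
rater_3    0.814    0.856    1.000
```

The single-measure ICC rates one rater used alone; the average-measure ICC
(its Spearman–Brown step-up) rates the mean of all three, and α summarises
internal consistency. Here the generator's variance components imply a true
single-measure ICC of 0.775, which the estimate and its CI recover.

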