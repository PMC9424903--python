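# Methods

This note documents the models, conventions and numerical choices behind
`spatialtme`, and what the synthetic validation does and does not show.

## Tissue model and segmentation

A field of view is a square of side 1884 µm. Tumor tissue is modeled as
a union of disc-shaped cell nests; real tumor nests are irregular, but
discs admit exact analytic areas, which is what the geometry oracles in
the test suite rely on.

Segmentation works on a raster with `grid_resolution_um` = 4 µm per
pixel (about one cell radius — fine enough that halving it changes
region areas by under 2% on fixture geometries, coarse enough that a
full field is a 471 × 471 image). Pixels use half-open µm intervals with
the origin at the top-left corner. The steps are:

1. **Tumor mask.** Pixels within `dilation_radius_um` = 10 µm of any
   tumor cell (gated panCK⁺, or ground truth in simulations). This turns
   the point pattern into contiguous tissue; 10 µm is about one cell
   diameter.
2. **Center of tumor (CT).** The filled morphological closing of the
   tumor mask with a ball of `ct_closing_radius_um` = 150 µm. The
   closing at this scale bridges the stromal corridors between adjacent
   nests (anything narrower than ~300 µm), so CT contains both the nests
   and the stroma they enclose, while peritumoral connective tissue
   stays outside. A single closing radius cannot serve both this purpose
   and nest delineation — a 20 µm closing never bridges a 100 µm
   corridor — which is why CT and TN have separate radii.
3. **Tumor nests (TN) vs intratumoral stroma (ISA).** TN is the closing
   of the tumor mask with `closing_radius_um` = 20 µm (filling gaps
   smaller than a couple of cells), intersected with CT; ISA is CT \ TN.
   The partition is exact by construction: TN ∩ ISA = ∅ and
   TN ∪ ISA = CT to the pixel.
4. **Invasive front (IF).** Pixels outside CT whose Euclidean distance
   to it is under `band_width_um` = 300 µm. Note that a Euclidean band
   around a polygon has rounded corners: for a 600 µm square the band
   area is 4·600·300 + π·300² ≈ 1.003 mm², not the 1.08 mm² a
   square-cornered ring would give.

All morphology is implemented with exact Euclidean distance transforms
(dilation: distance-to-foreground ≤ r; erosion: distance-to-background
> r), so structuring elements are true discs at any radius and the cost
is linear in pixel count. Images are padded before closing so the field
border never clips the intermediate dilation.

Cells are labeled by the region of the pixel containing them; cells
outside the field are excluded (logged), cells in no region are
`OUTSIDE`. A field can lack a region (e.g. no ISA when nests merge): its
area is zero and the affected densities are *missing values*, never
zeros, and propagate as missing through patient averages, medians and
scores. Cells in the IF are excluded from CAF analyses (the αSMA CAF
marker also stains peritumoral smooth muscle), implemented as an
analysis-time region filter rather than a mask change.

## Phenotyping

FMO thresholds are nearest-rank empirical quantiles of the null sample
(the ⌈q·n⌉-th order statistic; stated explicitly because sample-quantile
conventions differ), with positivity defined by *strict* inequality so
ties with the threshold are negative. The default `positivity_quantile`
is 0.99.

The gating tree is an ordered rule list, first match wins; the tumor
(panCK⁺) gate runs first so panCK dominates double positives, and the M2
gate precedes M1 so CD163 splits the macrophage branch. The panel and
tree are configuration (YAML), not code: the MDSC myeloid marker in
particular is configurable (CD33 by default) since myeloid panels vary.

A consequence of quantile thresholding worth stating: at q = 0.99 every
truly negative marker is falsely positive with probability ≈ 1%. A rule
that requires three negative markers (the CAF gate) therefore
misclassifies ≈ 3% of its population *regardless of how well separated
the intensity distributions are* — the error is in the threshold
convention, not the data. The high-fidelity configuration used for
validation (and anywhere ≥ 99% lineage recovery matters) therefore sets
q = 0.999, where the compounded error is a few per mille; with the
simulator's default intensity models (log-normal positives at
e³ ≈ 20 over a background at ≈ 1) lineage recovery is then 99.7–99.9%.

## Scoring

Densities are cells/mm² per (population, region); a patient's value is
the arithmetic mean over that patient's fields (permutation-invariant,
missing fields skipped). Median dichotomization is uniform everywhere:
value ≤ cohort median → low. The Immunoscore sums four indicators
(CD3/CD8 density above the cohort median, in each of two regions) and is
high iff the total is ≥ 2; the conventional variant scores CT + IF, the
IS variant ISA + IF. When a component is missing, the total runs over
the available components with the ≥ 2 threshold unchanged and the result
is flagged via `n_components`. The MMP14⁺ CAF/CAF ratio averages
per-field ratios per patient (consistent with the field-averaging rule);
a pooled-counts mode is available since either reading of "average of
values from the multiple fields" is defensible. Risk groups: A = high
score/high ratio, B = high/low, C = low/high, D = low/low.

## Survival

Cox fits use Efron's tie correction and Wald CIs on the log-hazard scale
(the lifelines defaults; both are the standard choices when the source
analysis does not specify), two-sided p-values throughout. The model
surface is deliberately restricted to binary indicators — age ≥ 67,
female, left-sided/rectal location, stage IIIC, unfavorable histology,
5-FU-only chemotherapy, plus the two biomarker classes — matching the
dichotomized analysis the package reproduces. Replication invariance of
the HR holds only up to the tie correction (duplicating a dataset
creates ties and shifts the Efron estimate by a sub-percent amount).

## Synthetic data: what it emulates

The generators provide data with the statistical structure the analysis
assumes, plus ground truth:

* **Fields**: 15 nests of radius 140 ± 35 µm (truncated normal) in a
  1884 µm field; homogeneous Poisson cells — 2000 tumor cells/mm² inside
  nests; CAF 250, TIL 180, M2-TAM 70, M1-TAM 40, MDSC 30 cells/mm²
  outside. This yields ≈ 3000 cells and ≈ 0.2–0.4 mm² of ISA per field,
  enough intratumoral CAFs (tens per field) for a stable ratio.
  Intensities: log-normal, background exp(N(0, 0.4²)), positives
  exp(N(3, 0.35²)); MMP14 positivity per lineage (tumor 0.5, CAF 0.3 by
  default, macrophages 0.2, lymphoid 0.1), CD8 on 40% of T cells.
* **Cohorts**: 86 patients, 2–5 fields each. Planted classes: the
  MMP14⁺ CAF fraction is Beta(12, 8) (mean 0.6) for ratio-high vs
  Beta(4, 16) (mean 0.2) for ratio-low patients; T-cell infiltration
  scales the TIL density by 2.5 (high) or 0.6 (low). RFS is exponential
  with hazard 0.0055/month × 2.926^[ratio high] × 0.277^[score high]
  (the two default hazard ratios are the reported multivariable effect
  sizes), with independent exponential censoring at 1/60 per month
  capped at 100 months. The baseline and censoring rates follow from
  requiring ≈ 29% relapse under ≈ 5-year median follow-up: with equal
  quarters in the four groups the mean hazard multiplier is ≈ 1.25, and
  h/(h + c) = 0.29 at c = 1/60 gives h ≈ 0.0068, i.e. a baseline of
  ≈ 0.0055.
  Covariate prevalences mirror a stage III adjuvant-therapy cohort
  (age ≥ 67: 0.50, female: 0.49, left/rectum: 0.65, stage IIIC: 0.17,
  unfavorable histology: 0.15, 5-FU only: 0.52).
* **Expression**: the target gene and its planted correlates load with
  weight √ρ on a shared latent factor (pairwise population correlation =
  ρ, default 0.7); values are log-normal around a median of 10, with a
  planted low-expression block around 0.2 that the 1.5-threshold filter
  removes. Spearman statistics are invariant to the monotone log-normal
  map, so planted correlations survive the transform exactly.

One seed governs each generator call; per-patient and per-field streams
are spawned from it (`numpy.random.SeedSequence`), so cohorts are
bit-reproducible and the clinical table does not change when field
generation is switched off.

What passing on these data does **not** show: real nests are not discs;
real intensity distributions are heavier-tailed and spatially
autocorrelated (staining gradients, segmentation artifacts); real cell
placement is clustered within lineages, not Poisson; biomarker classes
in patients are continuous, not a clean two-component mixture; and real
censoring is administrative, not exponential. Recovery rates here are
upper bounds on field performance, and the defaults are fixtures, not
estimates of any real cohort.

## Expression screen conventions

Values are shifted by +1 before fold changes (defined at zero
expression); the low-expression filter applies to *raw* values (a gene
is dropped when strictly more than 50% of samples are below 1.5 — a gene
at exactly half is kept), since the threshold describes the scale of the
unshifted data; both the threshold and the boundary convention are
configurable. log₂FC is the log of the ratio of group means on shifted
values (ratio-of-means, not mean-of-log-ratios). The split at the
target's median sends ties to the low group, matching the pipeline-wide
tie rule. Per-gene p-values come from the two-sided Wilcoxon rank-sum
test (the package's generic two-group comparison), with BH step-up
q-values over all tested genes.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations for
desk-scale runs: one default field (~3000 cells) for gating fidelity;
100 random fields for the partition invariant; 50 replicate cohorts of
n = 400 with low censoring for Cox parameter recovery (CI coverage of
planted HRs 3.0 and 0.3); 200 null cohorts of n = 86 for log-rank
calibration; 500-sample matrices with 20 planted correlates at ρ = 0.9
for screen recovery; and one full end-to-end cohort of n = 86 — the
study-scale configuration — for the pipeline hazard ratios. At n = 86
with ~20 events the measured hazard ratios carry wide confidence
intervals; the end-to-end numbers are point estimates under sampling
noise, and the tighter recovery guarantees are the 50-replicate
coverage checks.

## Known limitations

* The TN/ISA rule is a morphological reconstruction with exposed
  parameters; the original tissue-segmentation platform is not publicly
  specified beyond being morphology-based.
* The CT region is derived from the same field as the IF band, whereas
  pathology workflows select CT and IF fields of view separately; a
  single-field pipeline needs an explicit CT definition, and the filled
  coarse closing is this package's.
* No image processing: cells enter as coordinates with intensities;
  nucleus detection, registration and unmixing are upstream concerns.
* No proportional-hazards diagnostics beyond convergence checks, no
  time-varying covariates, no competing risks.
* The default gating tree is a generic 10-marker reconstruction; panels
  differ, and the YAML configuration is the intended extension point.
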