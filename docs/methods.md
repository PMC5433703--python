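# Methods

## Grid model

The device grid is 26×26 cubes of edge 0.2 mm. Cube centres are addressed
in a display frame (1-based row/column, row 1 at the top) and in polar
coordinates about the grid centroid with the anatomical convention
superior = 90°, nasal = 180°, inferior = 270°, temporal = 0°. For a right
eye (OD) temporal points toward decreasing column index; a left eye is the
exact horizontal mirror, so `angle_OS = (180° − angle_OD) mod 360°`.

The optic-nerve-head mask is the 88 cubes nearest the centroid (ascending
Euclidean distance, row-major tie-break). The device documentation does not
publish the mask shape; nearest-to-centroid selection is deterministic,
point-symmetric, and approximately circular (π·r² = 88 cubes gives
r ≈ 5.3 cube widths), which matches the concentric appearance of the
published zone maps. Real devices adapt the masked region to the individual
disc; this package uses the constant 88-cube mask and the constant derived
areas (total 27.04 mm², ONH 3.52 mm², effective 23.52 mm²) throughout.

## Zones

Zone delineation bins the teaching-cohort mean map with half-open
intervals: (−∞, 105) → zone 2, [105, 140) → 3, [140, 175) → 4,
[175, ∞) → 5, compared in μm with no rounding. Half-open-right intervals
make the integer phrasing "105 to 139 μm" well defined for continuous
values. All 588 analysed cubes are always partitioned; the published
teaching counts sum to 580, and whether the missing 8 cubes fell below a
70 μm floor or were excluded otherwise is not stated — the package reports
a separate below-floor bin (< 70 μm) rather than dropping cubes.

Zone and regional statistics use the subject as the statistical unit: a
subject's zone mean is the average of their cubes in the zone, and group
summaries are mean ± sample SD (n−1) of those per-subject means. Published
zone SDs (≈ 9–16 μm) reflect between-subject variation, and all hypothesis
tests operate on subjects, so pooling cubes would be wrong.

## Regions and volumes

Quadrants are the 90° wedges centred on the anatomical axes (Superior
[45°, 135°), Nasal [135°, 225°), Inferior [225°, 315°), Temporal the rest);
sectors are six 60° wedges with Temporal centred on 0°. The device's true
boundaries are unpublished; equal-angle wedges are used because the
equal-area volume rule below then reproduces the published regional volume
tables. The OS partition is constructed as the exact mirror of the OD
partition, so cubes lying exactly on a wedge boundary (the grid diagonals)
land in mirror-consistent regions for the two eyes.

Volume is `thickness[mm] × effective_area / n_regions` with the constant
effective area 23.52 mm². This reproduces 20 of the 22 published
(thickness, volume) pairs exactly at two decimals; the remaining two differ
by one final-digit unit, consistent with rounding slips in the source
table. The alternative `cube_count × cube_area` normalisation is available
(`cube_count_volume`) but non-default, because regions of a square grid
with a circular mask have unequal cube counts and the published volumes are
clearly equal-area.

## Statistics

* Pooled-variance Student t (two-tailed) is the default two-sample test;
  Welch is available behind `pooled=False` but non-default.
* Chi-square is Pearson's, without Yates continuity correction (none is
  mentioned in the source analyses); configurable in principle by calling
  scipy directly.
* The Kolmogorov–Smirnov normality check estimates μ and σ from the
  sample, so its p-value is approximate and anti-conservative; it is
  screening-only and never switches the pipeline to rank-based tests.
* Bonferroni correction applies to exactly the 10 regional comparisons
  (4 quadrants + 6 sectors), m fixed at 10, giving the 0.005 threshold;
  the zone and covariate rows are reported at raw α = 0.05.
* Cube-bin counts are compared on the group mean maps. The published table
  prints one p per bin row, so the package computes a per-bin 2×2
  chi-square (in-bin vs rest, case vs control) for each non-empty bin, plus
  an omnibus 2×k chi-square over all non-empty bins. Which procedure the
  source used is not documented; both are reported.
* Percent difference is `100 (case − control) / control`, printed at 1 dp.
  From the published zone means, zone 4 recomputes to 21.4% where the
  source prints 21.5% — a rounding slip, flagged in the tests.

## Synthetic cohort generator

Each analysed cube of subject *i* is

    t = base + s·(r − r_rim) + a·cos(θ − θ_peak) + b_i
        + Δ·[PD] + c·(UPDRS_i − 25.1)·[PD] + ε,   clipped at the floor,

with r the cube radius (mm), r_rim the smallest analysed radius, b_i ~
N(0, σ_subj) shared across the subject's cubes, ε ~ N(0, σ_cube) i.i.d.

Defaults: base = 85 μm, slope s = 42 μm/mm, angular amplitude a = 18 μm,
peak θ_peak = 120°, σ_subj = 12 μm, σ_cube = 8 μm, PD offset Δ = 30 μm,
severity coupling c = 0, floor 40 μm. The surface parameters were fitted
once to the normative teaching table: the noiseless map yields zone cube
counts 119/253/186/30 against the published 120/248/181/31 and zone means
within ~3 μm of 95.0/121.8/156.6/186.9 μm, with an overall range (≈ 69–204
μm) matching the published 78–205 μm. σ_subj = 12 μm reproduces the
published between-subject zone SDs (9.5–16 μm); σ_cube = 8 μm is
uncalibrated (no within-subject estimate is published) and chosen so the
mean map stays smooth at n = 40. θ_peak = 120° places the thickest tissue
between superior and superonasal, which matches the published *regional
table* (superonasal slightly above superotemporal) even though the prose
headline says "superotemporal"; both orderings keep the superotemporal
sector well above the inferior quadrant.

The PD effect is an additive constant, not proportional: the published
absolute zone differences (≈ 30.4/31.4/33.5/26.6 μm) are near-constant
while the percent differences fall with distance, exactly the signature of
a constant offset. With Δ = 30 μm the simulated percent increases run
≈ 33/24/19/16% by zone (total ≈ 23%), approximating the published
31.5/25.8/21.5/14.2% (total 24.0%).

Severity scores use truncated normals (UPDRS N(25.1, 5.4) on (0, ∞),
Hoehn–Yahr N(2.7, 0.8) on [0, 5], duration N(6.7, 2.3) on (0, ∞)) — only
mean ± SD are published and the supports are bounded. Covariates (age, sex,
refraction, BCVA, IOP, disc area) are drawn to match the demographic table
and truncated inside the eligibility limits, so default cohorts pass the
eligibility filter intact.

A cohort consumes a single seeded stream subject by subject (covariates,
severity, subject level, full-grid noise — the grid draw is always the full
26×26 block regardless of the mask), so extending a cohort never perturbs
existing subjects. `simulate_study` derives the case-cohort seed from the
control seed by a fixed offset.

**What the generator does not emulate:** axial-length, IOP, age and
circadian effects on thickness; segmentation failures and speckle;
per-eye variation of the ONH mask; spatial correlation of cube noise
(cube errors are independent); treatment-subgroup structure. Tests passing
on synthetic cohorts therefore validate the pipeline's arithmetic and its
statistical calibration under the stated model, not the device physics.

## Statistical calibration of the defaults

Under the defaults (n = 40 per group), the zone-2 null comparison (offset
forced to 0) rejects in ≈ 3–5% of 1000 seeded replicates at α = 0.05; the
30 μm offset is recovered without detectable bias (within sampling error
across replicates) and all four zone comparisons reject in essentially
every replicate (standardised effect ≈ 2.5); with severity coupling 0 the
severity-correlation p-values are uniform on [0, 1]. Teaching-cohort zone
cube counts fluctuate with the shared mean of the 40 subject levels
(SD ≈ σ_subj/√40 ≈ 1.9 μm shifts all bin boundaries); most seeds land all
four counts within ±25% of the normative 120/248/181/31, but the zone-5
count (30 ± ≈4) occasionally leaves the band — an inherent property of the
emulated design, not a bug.

## Numerical choices and degenerate inputs

Problem sizes follow the study design throughout: cohorts of 40 per group,
1000 replicates for the null-rate experiment, 30 for offset recovery, 200
for the severity-null check. Zone/region means of empty cell sets are NaN
and flagged rather than raised; group SDs need n ≥ 2; the t-test needs
n ≥ 2 per arm, chi-square non-zero marginals, Pearson r non-degenerate
samples, KS n ≥ 5. Grid files store values at 2 dp; masked cells are the
token `NA`. Thickness values outside 20–600 μm warn but do not fail —
real exports contain segmentation outliers, and hard-failing would block
loading a cohort for inspection.

## Known limitations

* The fixed 88-cube mask ignores per-eye disc size; zone counts near the
  rim are therefore idealised.
* Wedge boundaries are equal-angle; if the device uses widened
  temporal/nasal regions the regional means shift slightly (volumes are
  unaffected by construction since they use area/n).
* The KS p-value does not account for estimated parameters (no Lilliefors
  correction); it is a screen, not a gate.
* Right eyes are the default analysis unit; OS support is by mirroring and
  has no empirical validation here.
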