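# Methods

## Problem and scope

Baseline metabolic tumour volume (MTV) on FDG-PET is a prognostic biomarker
in diffuse large B cell lymphoma (DLBCL), but its value depends on how
tumour is delineated. `petmtv` implements and compares three SUV-threshold
delineation rules, the statistics used to quantify their agreement, and the
survival analysis used to assess their prognostic value, together with
synthetic phantoms and cohorts that make every stage testable without
patient data. Scanner physics, DICOM-to-SUV conversion, multi-bed stitching
and any automatic organ detection are out of scope: images arrive as SUV
volumes on their native grid, and operator judgement (seeds, boxes,
reference-VOI placement, liver-involvement flags, physiological-uptake
edits) arrives as annotations.

## Image model

An `SUVImage` is a 3-D array of non-negative, finite SUV values with
per-axis voxel spacing (mm) and the physical coordinate of voxel (0,0,0)'s
centre. Indices are 0-based; centre of voxel *i* is `origin + i·spacing`.
Anisotropic grids are fully supported and nothing is ever resampled or
interpolated — every statistic is computed over original voxels, as the
clinical tools operate. A voxel belongs to a cuboid VOI iff its centre lies
in the closed box; boundary ties count as inside, which makes membership
deterministic and resolution-independent. NIfTI-1 I/O accepts only
axis-aligned scaling + translation affines (negative scalings are
normalised by flipping); oblique volumes are rejected with a clear error
rather than silently resampled.

## Segmentation rules

All thresholds are inclusive (`>=`), and 3-D connectivity defaults to 26
(vertex-adjacent), configurable to 18 or 6.

* **fixed25** — connected component of `SUV >= 2.5` containing an
  operator seed. A seed below threshold is an operator error and raises.
* **pct41** — within an operator-drawn constraining box, let M be the
  in-box maximum; the mask is the component of `SUV >= 0.41·M` containing
  the (first scan-order) argmax voxel. Supra-threshold islands in the box
  not connected to the argmax are treated as separate lesions that need
  their own box. The companion heterogeneity check compares per-box maxima
  pairwise (all unordered pairs, combinations order) and flags pairs whose
  relative difference exceeds 10%, advising subdivision; it never
  re-segments automatically. "Counts" are read as regional SUV maxima,
  since the regional maximum is what drives a too-high 41% threshold.
* **percist** — whole-image components of `SUV >= T` with
  `T = 1.5·mean + 2·SD` over a reference VOI: a 3 cm³ cuboid in the right
  liver lobe (the protocol fixes only the volume, so the default is a cube
  of edge 3000^(1/3) ≈ 14.42 mm, edges configurable), or a 10×10×20 mm box
  in the descending thoracic aorta when the caller flags liver involvement.
  The SD uses the sample (n−1) denominator by default; the vendor
  convention being unknowable, `ddof` is configurable. The multiplier 1.0
  variant (over-sensitive, historically rejected) is exposed through the
  same config. Components are labelled in decreasing volume order with
  scan-order tie-breaks; physiological uptake (brain, bladder) is removed
  by label exclusion and adjacent uptake by mask carving, after which
  labels are renumbered contiguously.

Total MTV is the sum of pairwise-disjoint lesion volumes (voxel count ×
voxel volume, exactly); TLG accumulates volume × mean SUV per lesion.

## Agreement statistics

MTV is strongly right-skewed, so the intraclass correlation is computed on
cube-root-transformed values by default. The ICC is the two-way mixed,
single-rater, consistency form (ICC(3,1)), computed from the closed-form
ANOVA decomposition with its F-test p-value ((n−1, n−1) df for two raters);
the variant choice is fixed but the transform is configurable. Kendall's
tau-b (tie-corrected, asymptotic p) measures rank agreement and is
invariant to the transform. The Bland–Altman analysis is deliberately
non-parametric: median difference and 2.5th/97.5th percentile limits of
agreement with linear-interpolation quantiles (pinned so the limits are
bit-reproducible), plus a descriptive least-squares slope of difference on
pairwise mean to flag proportional trends. Differences are A−B in caller
order, recorded in the report. Normality pre-checks use the
Lilliefors-corrected KS test by default — testing against a normal with
estimated parameters without the correction is anticonservative — with the
plain KS variant available.

## Survival analysis

The ROC endpoint is binary progression within a 5-year horizon (365.25
days/year): events at or before the horizon are positive, follow-up beyond
it negative, and patients censored before the horizon are excluded from the
ROC sweep only — they remain in Kaplan–Meier, log-rank and Cox, which use
the full right-censored times. Candidate cut-offs are the unique observed
MTV values, classification is `mtv >= t` (inclusive, also at the final
cut-off), AUC is trapezoidal with a DeLong CI by default (stratified
bootstrap as the alternative), and the optimal cut-off minimises
`(1−sens)² + (1−spec)²` with the smallest threshold taken among ties
(deterministic, favours sensitivity). OS blocks reuse each method's
PFS-derived cut-off. Kaplan–Meier and the log-rank test go through
lifelines; the median is undefined (NaN) when the curve never reaches 0.5.
The univariate Cox model for the binary high/low covariate uses the Breslow
tie convention by default, fitted by 1-D Newton–Raphson on the partial
likelihood with monotone-likelihood detection (complete separation raises
with a diagnostic); Efron tie handling is available via lifelines and
agrees to ~1e-4 in the absence of ties.

## Synthetic data

**Phantoms.** Lesions are ellipsoids — chosen because their volumes are
analytic, `(4/3)π·a·b·c`, giving exact ground truth — either uniform or
two-compartment (hot core occupying a configurable fraction of each
semi-axis inside a warm rim). Background is Gaussian noise clipped at zero
(soft tissue ≈ 0.4 ± 0.1 SUV at default 4 mm voxels), with painted
liver (2.0 ± 0.3) and aortic (1.5 ± 0.1) boxes and optional spherical
physiological hot spots. Composition is by maximum, not addition, so lesion
voxels carry exactly the specified SUV — essential for threshold tests.
Annotations are generated alongside: a seed at each lesion centre, a
constraining box snug to the lesion extent (emulating the tight boxes an
operator draws to separate adjacent regions), reference-VOI centres and
physiological-spot centres. A second observer is emulated by bounded
uniform jitter of every annotation; a jittered seed must stay inside its
lesion (bounded re-draws, then error). Phantoms do not emulate PET physics
— no point-spread blur, partial-volume effect, or reconstruction noise
texture — so passing volume-recovery tests demonstrates correctness of the
geometry and thresholding logic, not clinical accuracy at real lesion
boundaries, where partial-volume effects dominate.

**Cohorts.** The default cohort has n = 147. The fixed-2.5 MTV follows a
truncated cube-root-normal law, `MTV^(1/3) ~ N(592^(1/3), 3.5)` truncated
above 1 cm³: raw values are heavily right-skewed at the study's scale
(median ≈ 592 cm³) and fail a KS normality check, while the cube root is
near-normal and passes — the structure that motivates the cube-root
transform. (A log-normal of matching spread was rejected: its cube root is
itself log-normal and still fails normality at n = 147 in ~93% of seeds.)
The 41% column is a patient-specific fraction of fixed25 (mean 0.27, SD
0.08), preserving ranks while shrinking magnitudes; the PERCIST column is
0.95 ± 0.05 of fixed25 — its normal-liver threshold (~3.6) exceeds 2.5 —
except in a 12% low-liver-uptake subset inflated by 1.8 ± 0.3. Event times
are exponential with hazards set by 5-year survival targets (PFS 0.85 low /
0.43 high; OS 0.89 / 0.55) for the true groups defined by a generating
cut-off of 400 cm³ on fixed25; administrative censoring is uniform on
1.3–7.9 years, giving ≈ 65% 5-year PFS and ≈ 35–40% events overall. PFS
and OS times are drawn independently given the group; the generator does
not enforce OS ≥ PFS for an individual patient, which none of the analyses
require.

## Numerical choices and degenerate inputs

Box membership uses an index-space tolerance of 1e-9 so that voxel centres
on a box face are included regardless of floating-point representation.
Zero-variance paired lists make the ICC undefined (raised), as do all-tied
lists for tau; a flat-zero constraining box, a single-class ROC outcome,
and an empty group in log-rank/Cox all raise typed errors before any
computation. The Newton solver for the Cox model clips steps to ±5 on the
log-HR scale and diagnoses divergence beyond |β| > 30.

## Problem sizes

Tests run on grids up to 84³ voxels (2 mm spheres), 50-phantom observer
series at 48³, 200-replicate hazard-ratio recovery at n = 147, and
50-seed end-to-end cohort runs; the acceptance script uses the same sizes
with a 30-phantom observer series. These sizes give stable statistics for
the stochastic checks while keeping a full run interactive.

## Known limitations

* The pipeline measures agreement and prognosis on *synthetic* structure;
  cohort-specific quantities from any real population (absolute cut-offs,
  volume ratios between methods, hazard ratios) are reproduced
  directionally, not numerically.
* ROC-derived optimal cut-offs are intrinsically noisy at n ≈ 150: across
  simulated cohorts the recovered cut-off's classification agreement with
  the generating rule has a 5th percentile near 0.82. Users should treat a
  single cohort's optimal cut-off as an estimate with wide sampling error,
  not a transportable constant — consistent with the spread of cut-offs
  reported across published DLBCL cohorts.
* The 41% method's jitter sensitivity arises here through snug constraining
  boxes; other mechanisms in real data (operator choice of region grouping,
  reconstruction differences) are not modelled.
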