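# Methods

## Problem and pipeline

Equine odontoclastic tooth resorption and hypercementosis (EOTRH) is a
progressive disease of the equine incisors, graded radiographically from 0
(normal) to 3 (severe). Its two component processes have opposite
radiographic signatures: resorption appears as radiolucent (dark) mottling of
the dental hard tissue, hypercementosis as radiopaque (bright) bulbous
enlargement of the apex. Both increase the textural heterogeneity of the
tooth's radiographic image as the disease advances, which is what this
package quantifies.

The pipeline runs four stages per tooth:

1. **Acquisition** — a 2D grayscale radiograph patch and a binary tooth mask,
   either read from disk (PNG/TIFF + integer label image + grades CSV) or
   rendered by the synthetic cohort generator.
2. **Filtering** — nine filters applied independently (never chained) to the
   patch: mean and median (window 3), whole-patch z-score normalization,
   bilateral (domain sigma 4.0, range sigma 50), binomial blur (one
   [1,2,1]/4 pass per axis), curvature flow (5 explicit Euler steps of size
   0.05), Laplacian sharpening, discrete Gaussian (variance 1.0), and FIR
   Gaussian smoothing at sigma 3 (the "recursive Gaussian" slot of the
   bank; a direct truncated-kernel convolution is used since the IIR
   recursion is only an approximation to it).
3. **Texture extraction** — the masked patch is discretized to integer gray
   levels and 93 features are computed: first-order statistics (18) and five
   texture-matrix families — GLCM (24), NGTDM (5), GLDM (14), GLRLM (16),
   GLSZM (16).
4. **Screening** — per (feature, filter) series across the four grade
   groups: a Shapiro–Wilk normality gate, then one-way ANOVA + Tukey HSD on
   the Gaussian path or Kruskal–Wallis + Dunn (Bonferroni over the six grade
   pairs) otherwise, then monotone-trend labelling, the two selection
   criteria, and coefficient-of-variation ranking.

## Filter conventions

All neighbourhood filters use replicate (nearest) border padding; the
curvature flow uses zero-flux borders via edge-replicated ghost pixels.
Filter outputs stay real-valued until texture discretization, so intensities
are quantized exactly once.

The Laplacian sharpening is `output = input − L*input` with the 4-connected
kernel [[0,1,0],[1,−4,1],[0,1,0]] (8-connected optional via
`laplacian_connectivity`). Normalization uses the population (÷N) standard
deviation of all patch pixels and raises on a constant patch. The discrete
Gaussian kernel is Lindeberg's `T_n(t) = exp(−t) I_n(t)` (modified Bessel),
truncated when the discarded tail mass is below 1e−8. The curvature flow
step is `I_t = κ|∇I|` with central differences,
`κ|∇I| = (I_xx I_y² − 2 I_x I_y I_xy + I_yy I_x²) / (I_x² + I_y²)`, with the
speed set to zero where the squared gradient falls below 1e−12. The binomial
repetition count (1) and discrete Gaussian variance (1.0) are package
conventions; no protocol values exist for them, and both are configurable.

## Discretization and texture definitions

Gray levels are assigned by fixed bin width: `level = floor((I − min I)/w) + 1`
over masked pixels, default w = 25 intensity units. A fixed width (rather
than a fixed level count) keeps level distances comparable across teeth.
Because the normalize filter outputs a unit-variance patch whose full range
is a few intensity units, the pipeline carries per-filter bin-width
overrides, default `{normalize: 0.25}`, giving that filter's output a level
count comparable to the 8-bit default. Without the override every matrix
family would be degenerate (one gray level) for that filter.

Matrix conventions (all configurable):

- GLCM and GLRLM use the four 2D directions 0°/45°/90°/135° at distance
  δ = 1; features are computed per direction and averaged, which makes them
  exactly invariant to 90° patch rotations. GLCM is symmetric (both orderings
  of each pair are counted) and normalized per direction.
- NGTDM and GLDM use the 8-pixel Chebyshev δ = 1 neighbourhood; GLDM's
  dependence tolerance is α = 0 (a neighbour is dependent iff its level
  equals the centre's). The GLDM matrix stores the raw dependent-neighbour
  count j (from 0); feature formulas use the 1-based dependence size j + 1.
- GLSZM zones are 8-connected components of constant level.
- Pairs, runs, neighbourhoods and zones never cross the mask boundary.

First-order statistics run on raw (undiscretized) masked intensities, except
uniformity and entropy which use the fixed-bin-width histogram. Variance and
the absolute deviations are population-style (÷N); percentiles interpolate
linearly between order statistics; kurtosis is Pearson (not excess);
energy is ΣI² and total energy multiplies by the pixel area (1 when spacing
is unknown — bit depth and pixel spacing are carried as metadata and never
assumed).

Degenerate inputs produce NaN rather than arbitrary numbers: skewness and
kurtosis of a constant region, GLCM correlation at zero variance, and whole
families when no valid pair/run/neighbour exists (with a warning). NGTDM
coarseness is capped at 1e6 when its denominator vanishes. The screening
stage excludes NaN-bearing series from testing and reports their count.

## Screening details

The normality gate requires all four grade groups to pass Shapiro–Wilk at
α = 0.05; groups smaller than 3 fail the gate (non-parametric path). The
omnibus test is one-way ANOVA (Gaussian path) or tie-corrected
Kruskal–Wallis, α = 0.05. Post-hoc pairs use Tukey–Kramer HSD or Dunn's
rank z-tests with Bonferroni adjustment over the six pairs (the adjustment
flavour is configurable). The studentized-range survival function behind
Tukey HSD is evaluated with fixed Gauss–Legendre quadrature (48 nodes over
the scaled-chi variable, 96 over the normal kernel), which agrees with exact
quadrature to ~1e−9 across the df range the screen encounters while being
fast enough to test 837 series per cohort.

**Trend and onset.** Trend direction is the sign of the Spearman correlation
between grade and value. The onset grade is the smallest g ∈ {1,2,3} such
that (a) the (0, g) post-hoc pair is significant and (b) the group central
tendencies (means on the Gaussian path, mean ranks otherwise) are strictly
ordered in the trend direction from g through grade 3; ties break toward a
larger onset, and a significant series with no such g is labelled trendless.
This is the minimal formal rule consistent with "the grade from which the
increase or decrease begins", and it is isolated in one function
(`trend_onset`) so alternatives can be substituted.

**Selection criteria.** Criterion 1: some filter's trend begins at grade 1.
Criterion 2: all nine filters agree on one non-none direction. The
coefficient of variation is the sample SD over |mean| (percent), pooled over
all filters and teeth for a feature, and is compared with its family's mean
CV. No multiple-testing correction is applied across the 837 combinations —
a deliberate reproduction of the screening design this package implements;
an optional Benjamini–Hochberg switch (`fdr: true`) exists but is off by
default.

## Synthetic cohort

The generator emulates the structure of the motivating study population —
80 subjects × 6 maxillary incisors (Triadan 101–103, 201–203), 8 teeth
excluded for fractures, 472 graded teeth split 105/195/111/61 across grades
0–3 — because the original radiographs are not publicly deposited.

Each tooth is an elongated elliptical silhouette (≈0.40·H × 0.30·W
semi-axes with small random jitter) carrying a smooth crown-to-apex
brightness ramp (140 → 190) on a darker background (60), 8-bit by default.
Grade g adds, additively on this shared base model:

- `mottle_count_per_grade[g]` dark Gaussian blobs (σ ∈ [1.5, 3] px) of depth
  `mottle_contrast_per_grade[g]` inside the mask — resorptive mottling;
  defaults (0, 6, 12, 20) blobs at (0, 25, 40, 60) intensity units;
- one soft-edged bright apical disc of radius `bulb_radius_per_grade[g]`
  (defaults 0, 4, 7, 10 px at +45 units) — the hypercementosis bulb;
- i.i.d. Gaussian noise, σ = 3, everywhere;
- a per-subject brightness intercept (σ = 4) mimicking exposure variation
  across radiographs.

Effect sequences must be non-negative and non-decreasing in grade, so the
trend *direction* (not just group differences) is built into the cohort —
that is what exercises the onset and criterion logic. The default effect
sizes were chosen to make the four grades clearly separable in heterogeneity,
matching the qualitative description of the disease classes as visually
distinguishable. `CohortConfig.null()` zeroes all grade effects for type-I
checks.

What the generator does **not** model: periodontal-space lines, lamina dura,
skull superimposition, anatomically shaped roots, scatter, or detector
physics. Passing tests therefore demonstrate that the pipeline recovers
built-in monotone heterogeneity trends at realistic sample sizes and stays
calibrated under the null — not that any specific feature is diagnostic on
real radiographs.

## Problem sizes used by the test and acceptance suites

- Type-I calibration pools 12 zero-effect cohorts of 96 teeth
  (16 subjects, 24 per grade, 48×32 patches): 10,044 feature–filter series.
  Per-cohort rejection rates are strongly over-dispersed (all 837 series in
  a cohort share one random grade assignment), which is why the check pools
  across cohorts.
- Trend recovery runs 10 cohorts at the full default scale (472 graded
  teeth): criterion 2 demands all nine filters significant, and the
  weakest series (Laplacian-sharpened GLCM contrast, where sharpened noise
  dilutes the mottling signal) only has reliable power at study-scale group
  sizes.
- Oracle equivalence uses ≥100 random 12×12–16×16 masked patches per
  operation against direct-loop reference implementations.

## Known limitations

- The bilateral filter truncates its spatial kernel at 2.5 domain sigmas;
  toolkit implementations with other truncations differ at the 1e−3
  relative level.
- GLCM's maximal correlation coefficient is defined as 1 on a single-level
  patch (the 1×1 matrix edge case).
- Dunn p-values use the normal approximation; very small groups (< ~5 per
  grade) are better served by exact tests, which are out of scope.
- The onset rule requires strict monotone ordering of central tendencies
  from the onset grade onward; plateaus past the onset therefore defer the
  onset to a later grade, which is conservative.
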