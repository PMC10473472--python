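# Methods

This note documents the models implemented in `lentikit`, the defaults of
the synthetic-data generator, and the numerical and design choices made
where the underlying field procedures left the implementation open.

## The measurement problem

Lenticels on mango fruit are quantified from calibrated surface
micrographs: the *frequency* (number per mm² of skin), the *core area*
per lenticel (the region of loosely packed complementary cells, which
includes the pore) and the *pore area* (the opening inside the core).
Russeting severity is rated per fruit on an ordinal 0–4 scale from the
russeted surface fraction. Mechanical predisposition is probed two ways:
by the *apparent strains* released when a skin disc is excised, its
cuticle isolated and then dewaxed, and by the area around each lenticel
infiltrated by the fluorescent tracer acridine orange, which only enters
through openings or microcracks in the cuticle. The developmental
context is set by whole-fruit surface-area growth.

## Image morphometry

**Segmentation chain.** Bright-field intensities are inverted, thresholded
globally by Otsu's method, labelled into connected components,
hole-filled, and filtered by physical core area within
`[min_core_area_mm2, max_core_area_mm2]`. Inside each core a second Otsu
pass separates the darker pore; the pore is only accepted if the
within-core contrast exceeds 15 % of the image dynamic range, which
prevents noise from being reported as a pore in pore-less cores. Field
practice for this kind of measurement is interactive (ImageJ); an
automatic chain is required for reproducibility, and its correctness is
defined against the synthetic generator's ground truth, not against any
particular micrograph.

**No-signal guard.** If the foreground/background mean separation after
thresholding is below 6 background standard deviations, the image is
treated as object-free. Without this guard, Otsu applied to a pure-noise
raster splits the noise in half and connected clusters of suprathreshold
pixels would be reported as objects.

**Border policy.** Measurement windows are finite (real windows ranged
from roughly 1.7 × 1.3 mm to 13.9 × 10.5 mm). Regions touching the window
border count one half toward the frequency and are excluded from
per-lenticel area statistics: edge-truncated areas would bias the means,
while the half-count keeps the density estimator unbiased.

**Infiltrated area.** The fluorescence channel is thresholded (Otsu by
default, a fixed intensity quantile as the configurable alternative),
components are labelled, and each component is attributed to the lenticel
whose core footprint it overlaps; a component overlapping several
footprints is split pixel-wise by nearest lenticel centroid so no area is
double-counted. The lenticel core footprint lies inside the halo and is
*included* in the reported infiltrated area (configurable by subtracting
the core area downstream); components smaller than 9 px are ignored as
speckle. The same 6-sigma no-signal guard applies.

## Growth geometry

**Sphericity.** Surface area from the three linear dimensions is
operationalized as the sphere of the geometric-mean diameter,
`A = π·[(L·d₁·d₂)^{1/3}]²` (mm² → cm²). This is standard horticultural
practice for near-spheroid fruit and is consistent with calculated areas
tracking measured peel areas linearly.

**Sigmoid family.** The developmental series is fitted with a
3-parameter logistic by default because it has a closed-form derivative
and peak (`A_max·k/4` at `t_mid`); "sigmoidal" does not pin down a
family, so a Gompertz alternative (`peak A_max·k/e` at `t_mid`) is
available behind the `family` switch and recorded in the output metadata.
Initialisation is deterministic and data-driven
(`a_max ← 1.05·max(A)`, `t_mid ←` first crossing of half-max,
`k ← 4·max slope/a_max`), the solver is trust-region least squares with
tolerances of 1e-14, and non-convergence raises an error naming the fit.
On noiseless logistic data all three parameters are recovered to better
than six significant digits.

**Whole-fruit counts.** `lenticels_per_fruit` is areal frequency × fruit
surface area (cm² converted to mm²). A constant per-fruit count across
development implies frequency ∝ 1/area, which is how the pipeline's
developmental table is constructed.

## Strain relaxation

The three apparent strains are referenced to the fully relaxed (dewaxed)
area `A_DCM` — including the excision+isolation component, whose
denominator is deliberately `A_DCM`, *not* `A_CM`; this makes the total
strain the exact sum of the components
(`ε′_tot ≡ (A − A_DCM)/A_DCM × 100`), an identity the test suite asserts
to 1e-12 relative on 10⁵ random discs. All strains are invariant to a
common rescaling of the areas. Negative strains are returned unclamped
and flagged in the pipeline output, since clamping would bias group
means. The in-situ area `A` is the cross-section of the nominal 8-mm
biopsy punch unless measured per sample. When the two four-hole-pattern
areas are given they take precedence over a direct dewaxed-disc outline
(`A_DCM = A_CM · holes_DCM/holes_CM`), because dewaxed discs curl at the
rim and the hole pattern is the reliable measurement.

## Russet scoring

The printed integer bins are extended to continuous fractions as the
half-open intervals (0,10], (10,25], (25,50], (50,100], with score 0
reserved for exactly 0 %. Fractions strictly between 0 and 1 % therefore
score 1 — any russet at all earns a nonzero score. Every fraction in
[0, 100] maps to exactly one score and the mapping is monotone, both
asserted as property tests. Populations are summarized as the arithmetic
mean of the ordinal scores ± SE plus the score histogram, matching how
severity tables are conventionally reported.

## Statistics

Correlation and regression go through scipy/statsmodels; significance
stars follow the ***-convention (p < 0.05/0.01/0.001). Group separation
uses the Tukey studentized-range test (statsmodels `pairwise_tukeyhsd`)
with a compact letter display computed by the insert–absorb algorithm,
letters assigned in ascending-mean order from "a". If every group has
zero variance the test is degenerate and all groups share "a" with a
warning. Paired treatment/control summaries (the moisture-exposed cheek
vs the untreated opposite cheek of the same fruit) require complete
pairs per time point and report per-arm means ± SE and the mean
within-pair difference; no particular inferential test is asserted for
these comparisons.

## Synthetic-data generator: what it emulates

The generator defines the study conditions for all tests; its defaults
are fixed once, from the mature-'Apple'-mango magnitudes:

| parameter | default | rationale |
|---|---|---|
| field | 10 × 10 mm at 10 µm/px | inside the real measurement-window range |
| lenticel frequency | 0.05 mm⁻² | mature 'Apple' cheek value; cultivar span 0.05–0.33 mm⁻² |
| core area | lognormal, mean 0.50 mm², CV 0.5 | areas are positive and right-skewed; 'Apple' mean core area |
| pore/core ratio | 0.30, lognormal scatter CV 0.23 | pore well inside core; scatter sized so the population pore–core r² is 0.79 at core CV 0.5 (r² = 1/(1 + cv_R²(1 + 1/cv_X²))) |
| halo fraction / size | 0.5 / 3× core area | moisture-exposed subsets; infiltrated areas exceed core areas severalfold |
| pixel noise | additive Gaussian, sd 0.01 of range, clipped | benign sensor noise |
| growth | A_max 370 cm², k 0.04 d⁻¹, t_mid 100 DAFB, noise 5 cm² | gives the observed peak rate A_max·k/4 = 3.7 cm² d⁻¹ at 100 DAFB |
| strain groups | (12.6, 28.1) % with, (8.5, 15.8) % without lenticels | the group component means; areas back-solved so cv = 0 round-trips exactly |
| dewaxed/isolated core slope | 0.74, scatter 0.024 mm² | the observed proportionality, scatter sized to its reported precision at n = 24 |

Scenes are rendered as filled ellipses (aspect uniform in 1–2,
orientation uniform — lenticel shape statistics are not reported anywhere,
so the aspect range is a free choice), pores as concentric darker
ellipses, and halos as flat disks whose edges are smoothed by a Gaussian
of 1.5 px. The half-maximum boundary of a smoothed disk sits exactly at
the disk radius, so the ground-truth halo area is well defined under
midpoint-like thresholding; a literal Gaussian-decay profile was rejected
because its thresholded area would depend strongly on the threshold and
no ground truth could be stated. Placement is uniform rejection sampling
with a non-overlap constraint (0.1 mm clearance, halos included) and
bounded retries; an over-dense request fails with a "field too crowded"
error. Identical spec + seed reproduce bit-identical rasters and truth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mango skin texture and uneven illumination,
overlapping or merging lenticels, ruptured/irregular lenticel outlines,
curvature and perspective distortion of the fruit surface, and temporal
tracking of an individual lenticel. The segmentation chain's accuracy on
real micrographs is not established here; on synthetic scenes it recovers
planted frequencies exactly and mean core areas to well under 5 %.

## Problem sizes

The default verification runs use 10 × 10 mm scenes (10⁶ px) at planted
frequencies 0.05/0.15/0.33 mm⁻² with the matching cultivar core areas,
200 replicate noisy growth series for the bias check, 30 discs per strain
group, and populations of 240 core pairs / 20 000 lenticels / 20
replicate fruit per sampling date for the population-statistic
recoveries — sizes at which the Monte-Carlo error of every recovered
quantity is small compared to the tolerance it is checked against.

## Known limitations

- The apparent strains are a measurement calculus, not a viscoelastic
  model of the cuticle; no time dependence of relaxation is represented.
- The 0–4 russet score is ordinal; its arithmetic mean is reported
  because severity tables are conventionally presented that way, not
  because score distances are metrically meaningful.
- Compact letter displays depend on the pairwise significance pattern;
  with strong evidence imbalance the insert–absorb solution is standard
  but not unique.
- Segmentation assumes dark objects on a bright background with a
  bimodal histogram; heavily textured or low-contrast images need the
  quantile threshold override.
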