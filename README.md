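# lentikit

Quantitative analysis of **lenticels and russeting on mango fruit surfaces**,
packaged as a reusable, tested pipeline. Lenticels — pore-like structures
that develop from ruptured stomata — are sites where cuticular microcracking
and russet (a brown, corky secondary surface) initiate on susceptible mango
cultivars such as 'Apple'. Studying that process requires several distinct
quantitative steps, which this package implements end to end:

- **Image morphometry** — detect lenticels on calibrated bright-field
  micrographs and measure the *core* area (loosely packed complementary
  cells) and the *pore* area (the opening) per lenticel, plus lenticel
  frequency per unit surface area; quantify the area around each lenticel
  infiltrated by a fluorescent tracer (acridine orange) through cuticular
  microcracks.
- **Growth geometry** — fruit surface area from length and two orthogonal
  equatorial diameters assuming sphericity,
  `A = π·d_g²` with `d_g = (L·d₁·d₂)^{1/3}`; 3-parameter logistic fit
  `A(t) = A_max / (1 + e^{−k(t−t_mid)})` of the developmental surface-area
  time course; the growth-rate curve from the closed-form derivative, which
  peaks at `A_max·k/4` at `t = t_mid`; whole-fruit lenticel counts as
  frequency × surface area.
- **Strain relaxation** — the apparent-strain calculus of punched skin
  discs: `ε′_exc+iso = (A − A_CM)/A_DCM × 100`,
  `ε′_extr = (A_CM − A_DCM)/A_DCM × 100`, `ε′_tot = ε′_exc+iso + ε′_extr`
  (A: in-situ disc area = punch cross-section; A_CM: isolated cuticle;
  A_DCM: dewaxed cuticle, reconstructible from a four-hole pattern when the
  disc rim curls), plus per-lenticel core strain
  `ε′_lenticel = (A′_IL − A′_DL)/A′_DL × 100`.
- **Russet scoring** — the ordinal 0–4 severity scale from the russeted
  surface fraction (0 ↔ 0 %, 1 ↔ (0,10] %, 2 ↔ (10,25] %, 3 ↔ (25,50] %,
  4 ↔ (50,100] %) with population summaries.
- **Statistics** — r² with significance stars, OLS regression, one-way
  ANOVA with Tukey studentized-range compact letter displays, and paired
  treatment/control summaries (moisture-exposed vs the opposite cheek of
  the same fruit).
- **Synthetic data** — a first-class generator that produces every input
  the pipeline consumes (calibrated two-channel scenes, growth series,
  strain-sample area triplets, russet populations) with known ground truth,
  so all stages are testable without any field data.

## Worked example

```python
from lentikit import *

# a calibrated 10 x 10 mm scene at mature-'Apple'-mango conditions
spec = SceneSpec(seed=42)                      # 0.05 lenticels/mm^2, core 0.50 mm^2
bf, fl, truth = generate_surface_scene(spec)
regions = segment_lenticels(bf, min_core_area_mm2=0.001, max_core_area_mm2=5.0)
summary = summarize_window(regions, spec.field_area_mm2)
print(summary.frequency_per_mm2, summary.mean_core_area_mm2)

# with/without-lenticels strain comparison at the group component means
samples  = generate_strain_samples(12.6, 28.1, cv=0.0, n=30, seed=0, has_lenticels=True)
samples += generate_strain_samples(8.5, 15.8, cv=0.0, n=30, seed=0, has_lenticels=False)
print(compare_groups(samples)[["eps_exc_iso_pct_mean", "eps_extr_pct_mean", "eps_tot_pct_mean"]])

# developmental growth and its peak rate
series = generate_growth_series(370, 0.04, 100, range(20, 181, 10), noise_sd=5.0, seed=1)
fit = fit_growth(series)
print(fit.peak_rate_cm2_per_d, fit.t_peak_dafb)
```

prints (seeds as shown):

```
0.05 0.46149...
                         eps_exc_iso_pct_mean  eps_extr_pct_mean  eps_tot_pct_mean
group
with_lenticels                         12.600             28.100            40.700
without_lenticels                       8.500             15.800            24.300
ratio_with_over_without                 1.482              1.778             1.675
3.6657... 99.845...
```

All five planted lenticels are recovered at the planted density
(0.05 mm⁻²); the strain table shows discs containing lenticels releasing
1.7× the total apparent strain of lenticel-free discs; the fitted logistic
puts the peak surface-expansion rate near 3.7 cm² d⁻¹ at ~100 days after
full bloom — the developmental window in which lenticels rupture.

## Command line

A thin CLI wraps the library:

```sh
lentikit simulate --seed 42 --out scene/
lentikit segment --image scene/brightfield.tif --min-core 0.001 --out regions.csv
lentikit strain --table samples.csv --out strain_summary.csv
lentikit growth --table fruits.csv --sigmoid logistic --out fit.csv
lentikit score --table russet.csv --out scores.csv
lentikit run-all --seed 42 --out demo/     # full synthetic demonstration run
```

`run-all` simulates three "cultivar" conditions spanning the observed
range of lenticel frequency (0.05–0.33 mm⁻²), segments and summarizes
them, fits the growth model, runs the strain comparison and scores a
russet population; every run echoes its configuration and is
bit-reproducible from config + seed.

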