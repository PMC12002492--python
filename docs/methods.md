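# Methods

## Scope and model

soilrisk implements screening-level soil contamination assessment for
industrial territories. The procedure runs in four stages:

1. **Indices.** Per-site contamination factors (CF = concentration /
   background), hazard quotients (HQ = concentration / MPC), the pollution
   load index (PLI), the total pollution indicator (Zc) and the 0–100
   integral score B; plus the area-mean summary computed from per-element
   mean concentrations.
2. **Descriptive statistics.** Per-element min/max/mean/median, sample
   standard deviation (ddof = 1), coefficient of variation and the CV-based
   spatial regime: below 33% uniform, 33–64% random, above 64% clustered.
3. **Spatial.** Multilevel B-spline interpolation of site values to a metric
   raster, hazard classification on right-closed scales, per-class area
   accounting, marching-squares contours.
4. **Multivariate.** Pearson correlation with paired t-tests, standardized
   PCA, and the joint correlation of coordinates, concentrations, indices and
   principal-component scores.

The method is a screening tool: it assumes total (gross) concentrations,
compares them to fixed regulatory/background references, and makes no claim
about bioavailability, speciation or exposure pathways.

## Index conventions

- **Non-detects** are stored as concentration 0 with a detection flag; they
  contribute zeros to means and correlations (matching how survey tables are
  published) and never enter the PLI product or its root.
- **PLI inclusion rule.** Elements with CF ≤ 0.7 are excluded from the
  geometric mean; `n` counts only surviving elements. If nothing survives,
  PLI = 0 with n = 0.
- **Zc variants.** The default "literal" form is ΣCF − n − 1 over elements
  with CF ≥ 1.5; the classical Saet form ΣCF − (n − 1) is selectable. The
  two differ by exactly 2 whenever n ≥ 1. An empty anomaly set yields 0;
  small negative literal values are legitimate outputs and classify as
  permissible.
- **Integral score.** Weights Ki = 1/MPC; Df = ΣKi over *all* elements
  (including non-detects), D floors each CF at 1 so only MPC exceedances
  depress B. B = 100 exactly when no CF exceeds 1.
- **Background fallback.** Elements never detected in background soil carry
  `background_is_mpc`; their CF and HQ coincide by construction rather than
  by duplicated reference values.
- **Reporting precision.** Report tables round half-up to 2 decimals
  (`round_half_up`, decimal-based to avoid binary-float ties). The area-mean
  summary evaluates its aggregate PLI/Zc/D/Df/B on the 2-d.p. mean-CF vector
  — the convention such summary rows are printed with, and the only one under
  which the aggregate row is internally consistent with its own per-element
  cells — and B is formed from D and Df rounded to 2 decimals. Full-precision
  aggregates are returned alongside for analysis; per-site indices are always
  full precision.
- **Hazard scales.** Right-closed intervals: a value exactly on a breakpoint
  takes the lower class. Defaults: PLI 0 / 1 / 3 / 5 (none, low, moderate,
  considerable, very high) and Zc 16 / 32 / 128 (permissible through
  extremely hazardous). The Zc grades are the standard sanitary categories;
  the PLI breakpoints follow the conventional load-index grading — both are
  fully user-configurable, and the PLI grades in particular are a
  convention choice rather than a regulatory constant.

## Interpolation

Scattered site values are fitted with multilevel B-spline approximation: a
hierarchy of uniform cubic B-spline control lattices over the padded bounding
box, starting at 4×4 cells and doubling per level (8 levels by default), each
level fitted to the residuals of the sum of all coarser levels with the
standard local weighted-average control-point update. The surface is fitted
about the data mean, so constant fields reproduce exactly and the surface
relaxes toward the mean away from data support. Fitting stops early when the
maximum data-point residual drops below 1e-6 of the value range. Properties
that follow: determinism, independence of point order, monotonically
non-increasing data-point residuals across levels, and interpolation at
distinct data points at the final level. Coincident points with conflicting
values are averaged with a warning.

Grid defaults: 100 m cells over the sample bounding box padded by 5% per
side (≈ 20k cells for a 200 km² area), snapped to whole cells. Interpolated
index values below 0 are spline overshoot (indices are non-negative by
construction) and are clamped to 0 before classification. Area shares count
cells by their center, optionally inside a study polygon; with n classified
cells each share is a multiple of 100/n, and shares always sum to 100.

Peak localization depends on sampling density: a surface fitted to ~40
irregular sites over 200 km² places its maximum near the hottest *site*, not
the true source, so source-localization checks use a systematic grid layout
(~1 km spacing) where the fitted argmax falls within one 500 m cell of the
true plume center. An inverse-distance-weighted interpolator is included
purely as an independent cross-check in tests, not as a pipeline option.

## Multivariate stage

Pearson correlations are computed on the raw concentration matrix (zeros
included); zero-variance columns yield undefined coefficients, reported as
missing with a warning. The paired t-test uses t = mean(d)/(sd(d)/√n) with a
selectable degrees-of-freedom convention: the default n − 2 reproduces the
critical value 2.715 (α = 0.01, two-tailed, n = 39) quoted in survey
reports that apply the regression-style df to a paired test; the textbook
n − 1 is available. PCA standardizes columns to zero mean and unit variance
(population sd), drops constant columns with a warning, and retains the
smallest number of components whose cumulative explained variance reaches the
target (default 0.90).

## Synthetic-data generator

The generator emulates the sampling design the analysis assumes: by default
39 sites placed uniformly over a 14.5 × 13.95 km rectangle (202.28 km²).
Each element is lognormal background (median m, geometric sd g) plus a sum of
Gaussian point-source plumes a·exp(−d²/2r²), optionally elongated along a
wind direction; concentrations below the detection limit are recorded as 0
after noise, mimicking XRF censoring. All randomness flows through
`numpy.random.default_rng` (PCG64), so a seed fully determines the table on
any platform.

Presets are calibrated once against the three CV regimes:

- `uniform` — g = 1.25 and no sources (analytic lognormal CV ≈ 22.6%);
  empirical CV < 33% in well over 95% of replicates at n = 39.
- `clustered` — three plumes with amplitudes 8–13× the background median;
  CV > 64% essentially always.
- `anomalous_singleton` — detection limit placed at the lognormal quantile
  with exceedance probability 1/n, so the detected-site count is
  Binomial(39, 1/39) with median 1.
- `paper_like` — 12 elements spanning all three regimes with plumes around
  three fictional plants; medians and censoring chosen so the mean site PLI
  falls in the moderate band (measured ≈ 1.5–1.7 across seeds).

What the generator does *not* emulate: real atmospheric dispersion (no
stability classes or deposition physics — plumes are isotropic or simply
elongated Gaussians), spatially correlated background fields, analytical
error structure, or inter-element geochemical correlation beyond co-located
plumes. Passing tests therefore demonstrate algorithmic correctness under a
plausible spatial-statistical model, not fidelity to any particular field
dataset.

## Degenerate inputs and errors

Geographic (lon/lat-looking) coordinates are rejected — areas must be
metric. Zero/negative MPC or background values are rejected at construction.
Empty element sets raise; single-site tables support index computation but
not dispersion statistics (sd/CV need n ≥ 2). Contour levels outside the
grid range and out-of-bbox warnings are non-fatal. Pipeline stages abort
with the failing stage's name; the CLI maps usage errors to exit 2 and stage
errors to exit 1.

## Test problem sizes

The suite exercises: exact-arithmetic index checks against the published
39-site summary table; interpolation on 25-point analytic planes and ~200
site synthetic grids at 500 m cells; preset calibration over 200 seeded
replicates per preset; and an end-to-end pipeline run at 500 m cells. These
sizes were chosen as the smallest that make each property measurable.

## Known limitations

- Published per-class area shares of a specific survey are not
  bit-reproducible: they depend on the GIS tool's internal lattice
  parameters and an unpublished study polygon. Area accounting is therefore
  validated by internal-consistency properties (shares sum to 100, class
  sets match, dominant class matches the field's mean PLI band).
- The per-site concentration table of the reference survey is distributed
  only as a binary supplementary document; site-level published ranges are
  consequently not asserted in the suite, and the corresponding check
  reports that gap explicitly rather than substituting fabricated data.
- The HQ here is a concentration/MPC ratio; no ingestion/inhalation/dermal
  dose modelling, no carcinogenic risk, no geoaccumulation or enrichment
  indices.
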