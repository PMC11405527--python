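# Methods

This note documents the models and numerical choices behind `wsci`, what
the synthetic generators do and do not emulate, and the design decisions
taken where more than one defensible option existed.

## Canopy entropy (module `entropy`)

The reference complexity index treats a footprint-clipped point cloud as a
sample from a 3D occupancy distribution and scores its information
content. Each of the three orthogonal 2D projections (XY, XZ, YZ) is
summarized by the discrete entropy of a normalized kernel density estimate
on a regular lattice of spacing `s` (default 0.10 m, the native grid of
the reference index): `CE_2d = −Σ ρᵢ ln(ρᵢ) s²` in nats. The 3D index is
the Euclidean combination `CE_XYZ = √(CE_XY² + CE_XZ² + CE_YZ²)`, and the
vertical component is `CE_Z = (CE_XZ + CE_YZ)/2` since spaceborne
waveforms observe only one vertical direction. Both identities hold
exactly by construction in `ComplexityMeasures.from_planes`.

Numerical choices:

- **KDE evaluation.** Points are histogram-binned at the lattice spacing
  and convolved with an isotropic Gaussian kernel
  (`scipy.ndimage.gaussian_filter`). The binning error is O((s/h)²) and is
  negligible at the defaults (s = 0.1 m, bandwidths ≥ 0.5 m); the result
  matches brute-force integration of the exact Gaussian mixture to ~0.03%
  at n = 200 (tested at a 1% tolerance).
- **Bandwidth.** Silverman's rule for 2D, isotropic, using the mean of the
  per-axis standard deviations: `h = σ̄ · n^(−1/6)`, floored at `s/2` for
  numerical stability on nearly-degenerate projections. A scalar override
  is exposed. A plug-in selector was considered and not adopted: no
  installed library provides a 2D plug-in, and Silverman is adequate for
  the smooth, space-filling densities of forest footprints (the headline
  entropy cap is insensitive to the selector at dense fill).
- **Grid extent.** Data bounding box padded by 4 bandwidths; the density
  is renormalized on the grid so Σρs² = 1 exactly; nodes below 1e−12 are
  excluded from the entropy sum (they contribute ~0 and destabilize ln).
- **Footprint boundary.** Strict `<` on the radius: a point exactly on the
  25-m rim is excluded, making clipping deterministic.
- **Voxel thinning.** One centroid per occupied voxel, with the voxel edge
  found by geometric bisection until the retained count is within ±10% of
  `min(target, n)`; the default target of 5000 points per footprint keeps
  the KDE cost bounded while preserving structure at the 25-m scale.
- **Entropy cap.** A uniformly filled 25-m disk has differential entropy
  ln(π·12.5²) ≈ 6.20 nats; KDE boundary smoothing adds ≈ 0.15, so CE_XY
  saturates near 6.35 — the footprint-limited horizontal-complexity cap.

## Waveform simulation and RH metrics (module `waveform`)

Each point contributes energy `exp(−d²/2σ_f²)` (d = horizontal distance to
the footprint center) at its height; the height histogram is convolved
with a Gaussian transmit pulse. Defaults: σ_f = 6.25 m (the 25-m nominal
footprint treated as ±2σ), pulse σ_p = 2.35 m, bin height 0.15 m — all
configurable, since the reference simulator's exact constants are not
fixed here. The pulse kernel is truncated just inside 3σ (tail mass ~0.5%,
restored by renormalization) so that RH100 stays within three pulse widths
of the highest return. Total energy equals the total footprint weight to
1e−6 relative.

RHp is the smallest bin height at which cumulative energy from the
waveform bottom reaches ≥ p% of the total, minus ground elevation; RH0 is
the lowest energetic bin. With ties (e.g. equal ground and canopy spikes)
the ≥ convention assigns p ≤ 50 to the lower spike. Negative RH values of
real data are out of scope: the synthetic ground is known and normalized
to zero.

Geolocation matching searches a (dx, dy, dz) grid, re-simulating at
shifted centers and correlating amplitudes aligned by absolute height
(candidate dz shifts the simulated waveform; non-overlapping bins are
zero-padded). The score is the per-shot mean Pearson correlation (the
pooled alternative is a one-line change); ties break by smaller offset
norm then lexicographic order. Crossovers are retained only with ≥ 10
shots and mean r ≥ 0.75, both bounds inclusive. The default search grid is
dx, dy ∈ [−20, 20] m step 1 m and dz ∈ [−5, 5] m step 0.25 m; tests and
examples use coarser grids sized to their fixtures.

The shot quality filter is a pure truth table over the shot record
(algorithm run flag, degrade flag, water/urban proportions, peak amplitude
vs 8× corrected noise SD, sensitivity > 0.95 or 0.98 in the tropics, treed
PFT classes {1,2,3,4,5,6,11}); a missing field raises rather than passing.

## Complexity models (module `model`)

Per-PFT XGBoost regressors map the 101 RH metrics to CE_XYZ (= WSCI when
predicted), CE_XY and CE_Z. Hyperparameters (trees, subsample, feature
fraction, depth, learning rate) are selected by a 5-fold grid search whose
folds partition *sites*, never rows — validation folds contain only
geographically unseen locations. Fold assignment is greedy by descending
site size onto the smallest fold (seeded tie-shuffle), balancing row
counts within 20%.

The selection constraint admits only configurations whose cross-validated
train/validation gaps in RMSE **and** R² are below 5%. The gap is relative
— `|train − val| / |train| · 100` — chosen for scale-freeness; an absolute
variant is available (`relative_gap=False`). Among admissible
configurations the winner minimizes mean validation RMSE, with ties broken
by fewer trees then smaller depth; an all-inadmissible grid raises rather
than returning a silently over-fit model. At desk scale (≈2,000 rows, 10
sites) the constraint is satisfied only by strongly regularized boosters
(tens of trees, depth ≤ 2–3, small learning rates), so default and example
grids span down to that regime while still containing higher-capacity and
deliberately over-fitting candidates.

The 80/20 train/test split is by site; the 20% is reserved exclusively for
conformal calibration. PFT groups under 100 rows are refused with a
warning (floor configurable). Model bundles serialize as xgboost JSON plus
a JSON sidecar (PFT, target, hyperparameters, metrics, seed); Booster-level
(de)serialization is used for sklearn-version robustness.

## Conformal intervals (module `conformal`)

Split-conformal half-widths are the `⌈(n_b+1)(1−α)⌉`-th smallest absolute
residuals of the calibration rows, computed per Mondrian bin. The Mondrian
taxonomy variable is the **predicted** value (the deployable choice — true
values are unavailable at prediction time), with 10 equal-count bins by
default, merged with a neighbor below 20 rows; fewer than 40 calibration
rows is an error. Predictions outside the calibrated range borrow the
nearest bin's quantile and are flagged. The reported relative interval
size is `(upper − lower) / center` for positive centers; the denominator
choice is a documented convention. Under exchangeability the intervals
carry the usual marginal coverage guarantee per bin, which the tests check
within binomial noise at α = 0.05 and 0.5.

## Attribution (module `attribution`)

Feature contributions are exact TreeSHAP values from the fitted ensemble
(xgboost's native `pred_contribs`); base value plus contributions equals
each prediction (local accuracy; float32 tree traversal puts the additivity
residual near 1e−6 relative). Importance is accumulated as the **mean
absolute contribution** per feature — the standard convention where a
single "accumulated importance" is needed — then summed into strata:
lower = RH0..RH33 (boundary inclusive), middle = RH34..RH66,
upper = RH67..RH100, normalized to fractions. The "top decile" summary
defaults to RH91..RH100 (`start_percentile` exposes RH90..RH100).
Composites map per-cell mean fractions to R/G/B with per-band min–max
rescaling over the mapped extent; rasters are written as ESRI ASCII grids.

## Analyses (module `analysis`)

- **Grid aggregation** excludes non-forest shots (RH98 ≤ 5 m, exclusive
  bound) and records per-cell arithmetic means and counts; counts are
  conserved.
- **PCA/PCR** min–max standardizes all metrics to [0,1] before the
  decomposition (avoiding unit-driven eigenvector weighting), regresses
  the complexity index on the first three components, and repeats with
  the index excluded from the decomposition; the difference between the
  two PCR R² values bounds the structural information unique to the index.
- **Scaling fits** regress WSCI on ln(RH98) — natural log, so the slope is
  the power-law scaling exponent. Per-cell OLS flags cells with slope
  p > 0.05 (two-tailed t-test) as excluded; cells below a 30-shot floor
  (configurable; the fit floor is a package choice) are excluded with a
  reason rather than fitted. Biome-level fits use IRLS with Tukey's
  biweight (tuning constant 4.685, configurable), tolerance 1e−6, max 50
  iterations, raising on non-convergence.

## Synthetic generators (module `forestgen`)

`generate_stand` emulates the geometry that drives the entropy index:
stems placed uniformly over the footprint disk at a Poisson-drawn count
from the per-hectare density; heights drawn from a configurable law
(constant/uniform/normal/lognormal/Weibull); `n_layers` splits stems into
vertical strata via mean-preserving multipliers `2(l+1)/(L+1)`, so
layering spreads the canopy through more vertical space without changing
the mean height; crowns are sampled on a cone (conifer) or ellipsoid
(broadleaf) surface plus a 30% interior fill at the stated surface point
density; understory stems (1–4 m) replace a configurable fraction; ground
returns sit on the plane z = 0 with Gaussian noise. Everything is driven
by one `default_rng(seed)` — identical (params, seed) gives bitwise
identical clouds. Not emulated: terrain, occlusion, radiative transfer,
species allometry, GEDI instrument noise. Passing tests therefore
demonstrate the pipeline's mathematical behavior (monotone entropy
responses, offset recovery, coverage), not performance on real ALS/GEDI
crossovers.

Auxiliary metrics are deliberately rank-faithful proxies: cover = fraction
of occupied 1-m ground cells with points above 2 m; height proxy = 98th
height percentile; PAI-like via Beer–Lambert `−ln(1−cover)/0.5`; FHD-like
= Shannon entropy of the 1-m vertical histogram of canopy points;
AGBD-like = 5·height²·cover. Only their rank structure matters for the
variance-partition analysis.

`generate_training_table` produces the RH→complexity tables used to
exercise the model, conformal and attribution layers at sample sizes the
point-cloud pipeline cannot reach in test budgets. Each row draws a latent
canopy height (lognormal, site-shifted with σ = 2 m so spatial blocking is
meaningful), cover and layering; the RH vector inverts a two-part
cumulative-energy model (ground spike + Beta canopy profile scaled to the
height); the complexity targets are smooth functions of the latents with
additive noise whose scale **decreases** with the signal — reproducing the
heteroskedastic, low-complexity-is-noisier residual pattern the Mondrian
intervals exist for. The horizontal target is capped at 6.3 nats,
mirroring the footprint-limited cap.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: stands of
a few hundred stems (2–7×10⁴ points), training tables of 2,000–5,000 rows
over 10 sites, holdouts of 1,000 rows, offset grids of ~10³ candidates,
and 2,000 shots per biome for scaling recovery. These sizes were chosen so
every statistical property under test (coverage bands, slope recovery
within 5%, monotone entropy responses over ≥10 seeds) has adequate power
while the whole suite stays fast on a single CPU.

## Known limitations

- The entropy bandwidth selector differs from the reference
  implementation's (unspecified here); absolute CE values are therefore
  comparable within this package, not across implementations.
- Horizontal complexity beyond the footprint cap, negative RH values,
  ground-finding, and GEDI noise are out of scope.
- The conformal guarantee is marginal and assumes exchangeability between
  calibration and deployment rows; strong covariate shift across sites
  weakens per-bin coverage.
- Published global quantities (PFT-level R², biome scaling exponents,
  global map statistics) depend on the real multi-billion-shot archive and
  are not reproducible from synthetic stands; only their qualitative
  orderings (vertical more predictable than horizontal; conifer-like
  canopies top-weighted in attribution) are asserted.
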