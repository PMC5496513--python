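# Methods

This note documents the models, algorithms and numerical choices behind
`kelpscape`, the assumptions they rest on, and what the synthetic test
conditions do and do not show about real surveys.

## Data model and quality control

A survey is a table of 1 × 1 m photo quadrats: position (lon/lat plus
local planar x/y in meters), along-track order, camera altitude, seabed
depth, a reef flag, and a point count *k* of *m* classification points
labelled as the focal taxon (default m = 25; m is a per-record field, so
other annotation densities work unchanged). Cover is k/m ∈ [0, 1].

Quadrats imaged at altitude < 0.4 m or > 5 m are excluded (strict
inequalities: records exactly at a boundary are kept) because image
geometry outside that window is unreliable; the filter is idempotent and
reports low/high exclusion counts.

All spatial computation runs in planar meters after a local
equirectangular projection about a per-survey origin
(x = R·cosφ₀·Δλ, y = R·Δφ, R = 6,371,008.8 m). At site scale (< 2 km)
its distance distortion is far below 0.1%, and the projection inverts
exactly; surveys wider than ~20 km are refused with advice to project per
site. Track geometry accumulates consecutive planar distances in
`track_order`; spacings above `max_gap` (default 10 m ≈ 2.6 × the 3.8 m
mean quadrat spacing, marking surfacing/repositioning) split the track
into segments that transect sections may not span.

## Synthetic surveys

The generator produces, per site:

- a dive track of `n_quadrats` positions with gamma-distributed spacings
  (mean 3.8 m, sd 1.0 m by default) along either a fixed heading
  (`straight`) or a smooth heading random walk with 0.25 rad step sd
  (`meander`, the default — it keeps multi-hundred-quadrat tracks inside a
  realistic site footprint);
- a zero-mean latent Gaussian field z with exponential covariance
  C(h) = sill·e^(−h/range) + nugget·1{h=0}, simulated exactly by dense
  Cholesky factorization (jitter fallback of 10⁻¹⁰·(sill+nugget),
  escalating ×10; refusal with eigenvalue diagnostics if still not
  positive definite). Dense factorization caps a site at ~5,000 positions,
  which covers any one-site survey this package targets. The exponential
  model is the simplest range-parameterized choice consistent with
  monotone-decay empirical correlograms; nothing downstream fits or
  assumes it;
- cover probabilities p = logit⁻¹(α + β_depth·depth + z), with depth
  sampled at quadrat positions from the generated bathymetry so records
  and rasters agree;
- counts k ~ Binomial(m, p(1−e) + (1−p)e), where e is an optional
  per-point symmetric label-flip rate emulating classifier error
  (flipping each point independently is exactly a binomial at the flipped
  probability).

Bathymetry is a smooth onshore–offshore gradient (0.03 m/m toward a
northern shoreline) plus low-amplitude smooth variation, clipped at 0.5 m;
the reef mask is a 15 m corridor around the surveyed positions, so every
quadrat lies on reef. Rasters default to 5 m resolution.

The bundled `paperlike` preset is eight sites of 735 quadrats (5,880
before QC), target mean covers {2, 5, 10, 15, 20, 25, 30, 38}%, two
near-random sites (range ≤ 2 m, sill ≈ nugget) and six patchy sites
(ranges 15–40 m, sill 1.2 ≫ nugget 0.2), depth coefficient −0.08 per
meter. Site intercepts are calibrated by scalar root finding against the
*realized* per-quadrat offsets (β_depth·depth + z), so each site's mean
true cover hits its target exactly; marginal (Gauss–Hermite) calibration
is also provided for the case where only the field's distribution is
known, but a single spatially-correlated realization can drift ±0.05 from
the marginal mean, which would blur the intended 2–38% span. The preset
leaves label error at zero: a symmetric flip rate e bounds observable
mean cover below by e, which is incompatible with a 2%-cover site; the 7%
option remains for studies whose site means all exceed it.

Generative truth (true p per quadrat, all site parameters, realized
intercepts) is written separately from the survey tables and is read only
by tests.

What the synthetic conditions do **not** emulate: asymmetric classifier
confusion, GPS positional error, within-quadrat cropping artifacts,
non-stationary or anisotropic patchiness, and environmental covariates
beyond depth and the reef corridor. Passing tests therefore demonstrate
the correctness and qualitative behavior of the estimators, not
field-level accuracy figures.

## Simulated transect designs

The whole-site mean cover over all quadrats is the reference ("true")
value. A design with n transects draws n mutually non-overlapping 50 m
windows of along-track distance, each wholly inside one gap-free segment
and containing at least 5 quadrats; quadrat membership is half-open
[start, start + 50), ties at the boundary going to the later section.
Placement is rejection sampling, uniform over feasible starts, with a
budget of 1,000 tries per section; near capacity — where independent
uniform placements essentially never avoid each other — a constructive
fallback allocates sections to segments with probability proportional to
remaining capacity and places them by the order-statistics trick (sorted
uniforms on the slack, offset by multiples of the length), which is an
exact uniform draw of non-overlapping configurations within a segment and
remains valid at zero slack. Any n up to Σ⌊segment/50⌋ is therefore
drawable; beyond it a capacity error reports the bound.

Each draw is scored by t = |x̄ − μ| / (s/√N) over the pooled quadrat
covers of its sections (s with the n−1 denominator; a constant off-truth
sample is flagged +∞, a constant on-truth sample is 0). Pooled quadrats
are the default because the quadrat is the measurement unit; a
transect-means mode is available for sensitivity analysis. Repeats are
independent fresh draws (placements may recur across repeats); a strict
no-reuse-across-repeats flag is provided. The per-site summary reports the
smallest n at which *every* repeat at n and at every larger tested n stays
below t = 2 — a deliberately conservative "reliable from here on" rule.

## Spatial structure

Moran's I per half-open distance band [k·5, (k+1)·5) m out to 100 m, with
classic binary (not row-standardized) symmetric weights, which is the
standard omnidirectional correlogram. Bands with fewer than 30 pairs are
omitted; a site needs ≥ 30 quadrats and ≥ 2 reportable bands. Pairwise
distances are computed once and shared between the observed statistic and
the null replicates. The x-intercept is the linear interpolation of the
first positive-to-nonpositive crossing of I between band midpoints (none
if I starts nonpositive or never crosses). The null envelope is the
2.5–97.5 percentile band of I over 199 replicates that randomly reassign
the observed covers among the fixed locations (`permute`, default,
preserving the cover distribution) or draw i.i.d. Uniform(0, 1) covers
(`uniform`); raw percentiles are reported rather than a smoothed band.

A caution established during verification: the zero-crossing distance of
an empirical correlogram is sharply estimated only when the underlying
correlation decays quickly; for ranges ≳ 20 m the crossing occurs where
the true correlation is already far-lag and small, so its sampling
distribution is wide (tens of meters). Mean x-intercepts across seeds
remain strictly monotone in the generative range — the statistic ranks
patchiness reliably even where its absolute value is noisy.

## Abundance SDM

`(k, m−k) ~ LAT + LONG + BATH + REEF`, binomial family, logit link, fitted
by IRLS (statsmodels) with covariates standardized internally for
conditioning and coefficients (with covariance from the inverse Fisher
information) mapped back to the original scale; predictions are invariant
to the standardization. Latitude/longitude enter as projected meters by
default (a raw-degrees mode exists for comparison); REEF is the binary
flag. Constant covariates and rank-deficient designs are refused with the
offending columns named — notably, REEF is constant on fully-on-reef
synthetic surveys, and the pipeline then drops it with a logged warning
rather than failing the run. No interactions or polynomial terms; the
model is strictly additive on the logit scale. Overdispersion is not
modelled; a quasi-binomial dispersion diagnostic (Pearson χ²/df) is
reported but unused.

Prediction onto the raster grid: per unmasked cell, η = x'β,
se_η = √(x'Σx), p̂ = logit⁻¹(η), and the response-scale standard error by
the delta method, se_p = p̂(1−p̂)·se_η. Off-reef cells carry no-data by
default. Non-converged or separated fits (standardized |coef| > 50)
refuse to predict.

## Predictive accuracy

AUC uses the rank (Mann–Whitney) formulation with midrank tie handling,
over presence = (k > 0) by default (minimal assumption for abundance
counts; a cover-threshold rule, k/m ≥ 0.1, is available). "Prediction
error" is the RMSE of held-out predicted cover against observed k/m (MAE
reported alongside) — the metric choice matters when comparing against
other work, so it is stated explicitly wherever printed.

LOOCV refits the model without each record; at survey scale it is capped
to a seeded random subset of held-out records (pipeline default 500; every
fit still uses all n−1 records). k-fold (default k = 10) stratifies folds
on presence/absence, reports per-fold AUC, mean AUC and pooled error, and
refolds once if a fold lacks both classes. Non-convergent folds are
skipped, warned about and counted.

The learning curve trains on random subsets of size n (default grid
10–450 step 40, 5 repeats per size) and scores each subset by LOOCV
*within* it, uncapped — at most 450 fits per cell, which is cheap, and a
capped estimate proved too noisy for a stable asymptote. A
train-on-subset/test-on-the-rest evaluator is available as an alternative.
The full-data reference error is LOOCV capped at 1,000 held-out records.
The asymptote estimate is the smallest grid size whose mean error — and
that of every larger grid size — is within ε = 0.005 of the full-data
error; requiring stability at all larger sizes guards against single-cell
noise flukes. Sizes below 10 are warned about as unstable.

## Pipeline and reproducibility

One master seed spawns an independent stream per stage (and per site,
repeat, etc.) by a counter-based `SeedSequence` derivation recorded in the
run manifest, so stages never share or perturb each other's draws. Tables
are written with fixed 9-significant-digit formatting; two runs from the
same config are byte-identical, and this is asserted in the test suite.
Stage outputs already on disk are reused, so deleting one stage's files
and re-running regenerates only that stage and its dependents. Figures
(t-vs-n panels with the t = 2 line, correlograms with null envelope and
x-intercept, prediction/SE maps, learning curve with full-data reference)
summarize a run; curve overlays are simple binned medians/means, not LOESS
smooths.

Problem sizes used by the default test and acceptance runs — 735-quadrat
sites, 500-repeat design sweeps, 50 site pairs for the patchiness
comparison, 100-fit coverage studies, the 10–450 learning grid — were
chosen as the smallest that make the Monte-Carlo assertions stable.

## Known limitations

- The correlogram x-intercept is a noisy patch-scale estimator at long
  ranges (see above); prefer comparing intercepts across sites to reading
  any single one literally.
- The SDM has no spatial random effects, so residual autocorrelation
  inflates its nominal precision on patchy sites; the delta-method SE maps
  propagate coefficient uncertainty only.
- Cross-validation is not spatially blocked; held-out quadrats can sit
  meters from training quadrats, so reported AUC/RMSE measure
  interpolation skill, not transfer to unsurveyed reefs.
- The transect simulator models section placement only: no diver
  behavior, detection error, or transect widths other than 1 m.
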