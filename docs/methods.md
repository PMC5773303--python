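# Methods

This note documents the statistical models implemented in `traitshift`,
the choices made where the design was genuinely open, and what the
synthetic test conditions do and do not establish about real data.

## The analysis problem

Natural history collections give sparse, uneven samples of a species'
morphology (snout–vent length, SVL) and of collection dates that, for an
explosive breeder collected mostly at breeding ponds, proxy breeding
phenology. The pipeline asks two questions: (i) which climate variables —
frost-free days (FFD) and precipitation, chosen over temperature because
temperature and FFD are nearly collinear (VIF ≫ 5) — predicted trait
variation *before* rapid warming; and (ii) whether the spatially explicit
trait changes observed *after* a cutoff year track proportional changes in
those same variables.

## Season filter

Within each 1° latitude band, the two-cluster solution of 1-D k-means on
Julian day is computed exactly by enumerating the n−1 sorted cut points
and minimizing within-cluster sum of squares (prefix sums; deterministic
and permutation-invariant, unlike iterative k-means). The later-centered
cluster is labeled nonbreeding when the centers are more than 45 days
apart and the band has at least 4 records; otherwise the band passes
through. The 45-day threshold replaces the visual histogram inspection a
human analyst would do; both it and the band width are configurable.
Nonbreeding records are removed from phenology analyses only — they carry
valid size information.

## Historic spatial mixed models

For each response (log SVL per sex; Julian day) the model is

    y_i = x_i' β + b_{year(i)} + e_i,
    b_year ~ N(0, σ²_year),  Cov(e_i, e_j) = σ²_resid · exp(−d_ij / ρ),

with x covering an intercept and centered/scaled FFD, precipitation and
their product, and d the Euclidean distance in coordinate space. Fitting
is maximum likelihood (not REML): the overall variance is profiled out
analytically, so the optimizer works in (log γ, log ρ) with
γ = σ²_year/σ²_resid, using bounded Nelder–Mead from several seeded starts
(default 5; simulation studies in the tests use 2). β is the GLS solution
given the variance parameters and SEs come from (X'V⁻¹X)⁻¹. Numerical
choices: a 1e−8 diagonal jitter keeps the correlation matrix positive
definite under duplicate coordinates; no nugget term is modeled.

Distance defaults to raw (lat°, lon°, elev m) coordinates, mirroring how
the standard mixed-model correlation structures consume covariates
verbatim; because meters then dominate degrees, a `normalized` coordinate
mode (unit SD per axis) and an elevation on/off switch are provided, and
the simulation studies use (lat, lon) to match the generator.

Model selection uses AICc with k = fixed effects (incl. intercept) + 3
variance/correlation parameters, constant across the family so ΔAICc is
well defined. Averaging over the ΔAICc ≤ 2 set is *full* (zero
substitution) with unconditional SEs,
SE = Σ w_i sqrt(se_i² + (b_i − b̄)²); 95% CIs are Wald (±1.96 SE).
Marginal/conditional R² follow the variance-partition definition:
R²m = varF/(varF + σ²_year + σ²_resid), with varF the sample variance of
the fixed-effect predictor.

## Bootstrap thin-plate-spline maps

The 3-D order-2 thin plate spline uses the polyharmonic kernel φ(r) = −r
(sign chosen so the kernel is conditionally positive definite on the
complement of its affine null space). Coordinates are standardized to unit
SD internally so elevation cannot dominate. The penalized system
[K + nλI, T; T', 0][c; d] = [y; 0] is solved through a QR reduction of T
and one eigendecomposition, after which the GCV score
V(λ) = n·RSS/(n − tr A)² is evaluated over a 60-point log grid per fit.

Bootstrap ensembles use case resampling (B = 100 by default), with each
replicate seeded from (seed, replicate index). Duplicated records in a
resample are collapsed to unique points with frequency weights before
fitting: GCV applied to literally duplicated rows treats a k-fold repeat
as k noise-free replicates and collapses to interpolation, which destroys
the calibration of the percentile intervals. The weighted criterion
Σ w_i (y_i − f(x_i))² + penalty whitens to the same eigenstructure with
n = Σw. Per replicate, the in-sample (weighted) r² and the mean squared
prediction error on the replicate's out-of-bag records are recorded; the
in-sample mean r² is the headline fit statistic, MSPE the holdout one.

Per pixel the ensemble yields the mean, 2.5/97.5 percentile bounds and the
bootstrap SD ("pooled SE"). Change between periods is the difference of
mean maps, declared significant exactly where the two percentile intervals
are disjoint (a deliberately conservative rule: disjoint 95% intervals
correspond to a far smaller pairwise error rate); the combined SE for
downstream weighting is the root sum of squares of the two periods' SDs —
the standard pooling for a difference of independent estimates.

## Change GLS

At n = 484 pixel centers sampled uniformly without replacement from the
valid cells, trait change Δy is regressed on second-order polynomials of
proportional climate change (built from the raw proportional values —
already on a common, interpretable scale — not re-centered) by ML GLS with
covariance σ² D C(ρ) D, C the exponential correlogram over (lon, lat) and
D the per-point SD. Weighting is precision weighting: SD ∝ pooled SE
(weights 1/SE²); `weight_mode="se"` gives the milder 1/SE alternative.
The intercept is always included. The candidate family is the 10
marginality-respecting subsets of {F, F², P, P², F:P} plus the
intercept-only model; ranking and full averaging are as in the mixed
models, with k = fixed effects + 2.

## Synthetic study system

The generator draws the conditions the analysis assumes, at the study's
scale: 679 pre- and 585 post-cutoff records (female fraction 484/1264),
decades 1901–2000 with cutoff 1960, a 5-arc-minute grid. Climate fields
are a smooth dominant latitudinal gradient plus Gaussian-filtered noise;
temperature and FFD share the latent gradient, with independent-noise SD
calibrated iteratively until their cell-wise correlation is within ±0.02
of the 0.87 target. Post-cutoff decades get an additive shift
(+1.2 °C, +12 FFD days, +60 mm by default — plausible late-century
magnitudes). Trait coefficients default to the historic point estimates
(e.g. −42.4 days per FFD SD for Julian day; size responses of a few
percent per climate SD). Phenology noise is σ_resid = 15 d, σ_year = 6 d —
tight, as expected for an explosive breeder in which most breeding at a
site happens within days. Residuals are drawn from the exponential
correlogram (range 2°) over (lat, lon); elevation comes from a smooth
synthetic DEM.

Nonbreeding contaminant dates (default 15% of records) are drawn uniformly
90–210 days after the *latitude band's* mean breeding day. The band-level
reference matters: breeding date varies tens of days within a band
(longitudinal FFD variation), so offsets relative to each record's own
site mean would overlap neighboring records' breeding windows and make the
planted labels unrecoverable in principle; the breeding *season* is a
property of the latitude, which is also how the field determines it.

The change-detection scenario (`gen_change_scenario`) imposes a shift of
Δ = 15 (3× the residual SD of 5) on a subregion whose edges taper
smoothly to zero over 0.2° inside the box: a climate-driven subregional
shift has smooth boundaries, and a step discontinuity is unresolvable by
any smooth surface estimator, which would leak apparent change into the
unchanged region. Operating characteristics are evaluated on the exact-Δ
core and the exactly-unchanged exterior; the transition band, where truth
is intermediate by construction, is excluded. The scenario grid (20×30
cells for 400 records/period) keeps sampling density near one record per
two cells; percentile bootstrap CIs lose calibration when most pixels are
far from any record, and larger shift amplitudes corrupt the post-period
surface globally through the kernel's unbounded support — both effects are
properties of the mapping method that the test sizes are chosen to avoid
conflating with the detection rule itself.

What passing these tests shows: the estimators are correctly implemented
(exactness and oracle checks), approximately calibrated (CI coverage
0.90–0.985 at study-scale n), and able to recover planted effects of the
published magnitudes. What they do not show: robustness to the pathologies
of real collections — georeferencing error, observer size bias,
non-Gaussian residuals, climate-data error — none of which the generator
emulates.

## Simulation sizes

Simulation-based checks use 100 replicates for CI coverage (LMM n = 350,
GLS n = 484), 50 for sign-pattern recovery, 150 (n = 35) for the LRT
type-I rate with a correspondingly widened acceptance band [0.01, 0.11],
and reduced replicate counts (6–20) for unit-level properties; these sizes
are the package's own balance of statistical resolution against suite
runtime.

## Known limitations

* Percentile bootstrap CIs for penalized smoothers are only approximately
  calibrated; undercoverage grows where records are sparse.
* ML (not REML) variance estimates are biased low at small n; Wald CIs
  inherit this (coverage ~0.93–0.95 in the tests' regimes).
* The exponential correlogram over raw coordinates treats a degree of
  latitude and of longitude as equal distances and ignores great-circle
  geometry; adequate at continental mid-latitudes, not near poles.
* Model-averaged SEs ignore between-coefficient covariances, so the
  partial-effect bands built from them are approximations.
* The GeoTIFF interchange format of GIS toolchains is not written; rasters
  are exchanged as ESRI ASCII grids.
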