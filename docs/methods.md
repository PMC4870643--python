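# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind `fledgemove`, and states what the passing test
suite does and does not demonstrate about real tracking data.

## Displacement model family

Net squared displacement (NSD) is the squared beeline distance from the
natal colony to each fix. Distances use the haversine formula on a sphere
of radius 6371.0088 km (IUGG mean; no ellipsoid). Time is measured in
fractional days from *departure*, the first fix at least 5 km from the
colony, which excludes pre-fledging colony attendance.

Four candidate NSD curves are fitted per individual:

* **home range** — `κ (1 − e^{−t/τ})`. This is the expected NSD of a
  diffusive process with attraction (an Ornstein–Uhlenbeck-type walk):
  maximal slope at t = 0, saturation at `κ`.
* **nomad** — `β t`, the diffusive (uncorrelated-wandering) signature.
* **half-migration** — a single logistic `δ / (1 + e^{(θ−t)/φ})`: a
  directed transit with inflection at `θ`, transition width ~4`φ`, and a
  settlement plateau `δ` with no return inside the observation window.
* **migration** — the symmetric double logistic, `θ₂ > θ`, adding a
  completed return leg.

### Unwrapped displacement for circumpolar movement

A bird circling Antarctica eastward at 350 km/day passes the half-turn
point after ~5 weeks; from there its *beeline* distance to the colony
shrinks again, producing an oscillating NSD that no member of the family
can describe — and 3-month ranges printed for circumpolar species exceed
the spherical beeline maximum (~20 015 km), which a shortest-wrap distance
cannot produce. Model fitting, looping detection and `range_at` therefore
operate on an **azimuthally unwrapped loxodromic displacement**: fix
longitudes are unwrapped cumulatively along the track and the rhumb-line
distance is evaluated on the unwrapped longitude difference, so a full lap
keeps accumulating displacement. For tracks that stay within half a turn
of the colony this agrees with the great-circle distance to within a few
percent. `compute_nsd` itself remains the plain haversine-squared series;
`range_at(..., unwrap=False)` gives the beeline variant.

## Fitting

Each model is fitted by nonlinear least squares (`scipy.optimize.
least_squares`, trust-region reflective, bounded) with squared residuals
weighted by `1/max(NSD, 1 km²)`, which tames the km² scale and makes the
fit sensitive to the early, small-displacement phase. Starts are
quantile-derived heuristics (plateau level from the last quarter of the
series, half-rise crossing time) plus four seeded log-normal jitters; the
best weighted SSE wins. The migration model is parameterized internally
with `θ₂ = θ + Δθ, Δθ > 0` so the ordering constraint is structural.
Goodness of fit is Lin's concordance correlation coefficient (population
moments) between observed and fitted NSD, computed unweighted; identical
constants score 1, shifted constants 0, by convention. A fit that fails
from every start is carried with `cc = −inf` so it can never be selected.

### Plausibility screen

Selection runs only over fits whose parameters are consistent with the
spatio-temporal scale of the observed trajectory. A fit is discarded
when:

* an inflection time lies outside `[0, 1.5 × duration]`;
* an asymptotic distance (`√δ` or `√κ`) exceeds 1.25 × the largest
  observed displacement;
* a transition timescale `φ` exceeds the track duration, or is shorter
  than the mean fix interval (a 10–90% transition spans ~4.4 φ, so such a
  transition would cross fewer than ~4 fixes and is unresolvable at the
  actual sampling rate);
* the linear NSD slope implies a 3-month range beyond 40 000 km;
* a **settlement claim is not witnessed**: for the half-migration model
  the plateau must begin inside the window (`θ + 2φ ≤ duration`), the
  final displacement must not exceed 1.15 `√δ`, and the displacement must
  not keep trending upward through the claimed plateau (linear trend of
  `√NSD` over the plateau window amounting to > 15% of `√δ`);
* a **return is not witnessed**: a migration fit must be at or below
  `δ/2` at the last fix, otherwise its return leg is pure extrapolation.

The witness rules matter because the logistic family nests shapes that
mimic both saturating and accelerating curves: on a ballistic circumpolar
track a logistic with an asymptote placed just beyond the last fix out-fits
the linear model (cc ≈ 0.97 vs 0.72) while asserting a settlement the bird
demonstrably never made. Discarding unfalsifiable settlement/return claims
restores the intended competition. Among plausible fits the highest
concordance wins; ties within 1e−6 go to the model with fewer parameters.
If nothing is plausible the best overall fit is returned flagged
implausible.

### Looping override

Wide loops that keep a bird within a bounded range produce a non-monotone
NSD with large colony-bearing rotation. The detector fires when (i) the
unwrapped-displacement series declines by ≥ 25% of its running maximum and
(ii) the colony→bird bearing (at fixes ≥ 100 km out, where bearing is not
noise-dominated) sweeps ≥ π unwrapped. When it fires, the best model is
not full migration, and the 3-month range is below 3500 km, the movement
type is overridden to `large_scale_looping`. Circumnavigators are immune
twice over: their unwrapped displacement never declines, and their range
exceeds the guard.

Ranges at 3 months map to dispersal scale as < 3000 km small, 3000–6000 km
medium, > 6000 km large. The dispersion distance of a settlement fit is
`√δ`; the variation about the asymptote is the standard deviation of
`√NSD − √fitted` over the plateau phase (`θ+2φ` to `θ₂−2φ₂`, or the series
end for half-migration).

## Trajectory statistics

All per-track metrics aggregate over consecutive 15-day blocks since
departure (months are 30-day blocks, not calendar months):

* **sinuosity** `S = 1 − beeline/path` in [0, 1]; straight transits score
  ~0, closed loops 1. The straightness-index form is used because it is
  bounded, scale-free, and matches the qualitative split between transits
  (< 0.5) and looping (≈ 0.5 and above).
* **daily distance travelled** sums step distances and step durations only
  over steps with gaps ≤ 36 h — the longest common transmitter OFF period
  (24 h) plus slack — so the 54–60 h OFF gaps of the sparser schedules
  neither deflate nor bias the speed.
* **departure bearing** is the great-circle bearing from the colony to the
  first fix ≥ 100 km out (beyond Argos scatter and colony attendance);
  month-2/3 orientation uses the rhumb (constant-azimuth) bearing to the
  position nearest 60/90 days (± 3 days).
* **circular summaries**: mean direction, mean resultant length R, angular
  range (2π minus the largest circular gap), and the Rayleigh test with
  `Z = nR²` and the standard second-order series approximation of its
  p-value. The test suite verifies 4–6% empirical type-I error at
  α = 0.05 for n = 20 and agreement with an independent circular-statistics
  package to ~1e−4 (the reference uses a different classical
  approximation).

## Track cleaning

The speed filter iteratively removes, among fixes adjacent to any step
implying > 90 km/h (a sustained procellariiform ground-speed ceiling), the
fix with the largest mean speed to its neighbours, until no step exceeds
the ceiling; it is deterministic and idempotent. Geolocator (GLS) tracks
are smoothed by averaging non-overlapping 3-day windows (longitudes
unwrapped about the window's first fix, so the antimeridian is safe). No
temporal regularization is applied: the NSD approach is continuous-time
and handles irregular, duty-cycled sampling as-is.

## Habitat annotation

Rasters are regular lon/lat grids (plain ESRI ASCII text); lookup is
nearest-cell, matching the coarse accuracy of Argos/GLS positions — no
interpolation. Depth is negative below sea level; water shallower than
3000 m is neritic (shelf to lower slope), at or below −3000 m oceanic,
and positive depths signal land. Settlement habitat is the majority class
over the final 15-day segment (ties to neritic), with the class fraction
reported.

## Group comparisons

Species/period effects on period metrics use a linear mixed model
(`response ~ group + period`, random intercept per individual, statsmodels
MixedLM, REML) with all pairwise group contrasts adjusted by the
studentized-range (Tukey) distribution; adjusted p-values are clamped to
be at least the raw p. Designs with ≤ 1 observation per individual are
detected and fall back to a one-way Tukey HSD on per-individual means,
flagged in the result. Juvenile-vs-adult latitude uses the two-sided
Wilcoxon rank-sum test on per-individual month-3 means: exact null
distribution when the combined n ≤ 20 without ties (verified against full
enumeration for all sizes up to 8/8), normal approximation with tie and
continuity correction otherwise. Residual autocorrelation beyond the
random intercept is not modelled.

## Synthetic study conditions

The generator produces hourly latent paths, then subsamples and noises
them, so duty-cycle and noise effects stay separable. Defaults are frozen
as the study conditions:

* **colonies** Crozet (46.2° S, 52.4° E; default), Kerguelen (49.4° S,
  70.1° E), Amsterdam (38.4° S, 77.3° E); track duration 93 days (a shade
  over three months, so the day-90 range always has a fix within its
  ±3-day window); fledging epoch mid-January.
* **nomad**: hourly correlated walk (von Mises heading wobble, κ = 8)
  drifting east at 350 km/day with relaxation toward 55° S —
  circumnavigation in ~10 weeks.
* **half-migration / migration**: departure azimuth drawn once from a von
  Mises (mean east, κ = 20, matching the low observed departure-heading
  dispersion), 16-day transit to a 4000 km settlement (10–30 day transits
  are the observed range), then an Ornstein–Uhlenbeck wander (sd 150 km,
  τ = 3 d) about the settlement point; migration adds a mirrored return
  leg and a final stay near the colony.
* **home range**: a sector-biased wander whose foraging radius expands as
  `R√(1 − e^{−2t/τ})` (R = 450 km, τ = 16 d) with short-memory radial
  jitter — by construction its expected NSD is exactly the saturating
  home-range curve, i.e. diffusive settlement resolved over ~5 fixes at
  the actual sampling rate.
* **looping**: a ~240 km/day arc of radius 1000 km whose centre sits
  300 km from the colony, so the colony lies inside the loop: the bearing
  sweeps 2π per lap while the range stays below ~2000 km; ~3 laps in three
  months, consistent with looping daily distances around 240 km/day.
* **sampling**: the three Argos schedules (10 h ON/24 h OFF, 18/54,
  12/60) rotate across individuals; within each ON window only ~`h_on`/8
  acquisitions are kept, giving 0.65–0.72 locations/day, bracketing the
  0.65 ± 0.12 of real duty-cycled juvenile tags. The exact deployment fix
  at the colony is retained. Argos noise is isotropic Gaussian with 5 km
  per-axis sd; GLS positions are sampled at 2/day with per-axis sd
  180/√(2 ln 2) km, calibrated so the median radial error is 180 km.

All randomness flows from `SimConfig.seed`; equal configs give identical
tracks.

**What the generator does not emulate:** location-class-dependent Argos
error (noise is homoscedastic), wind fields and their effect on route
choice, stopovers on the nomadic transit, land avoidance (there are no
continents), device failure/attrition, and behavioural switching within a
phenotype. Mode-recovery rates measured on this cohort therefore
demonstrate that the estimator correctly inverts its own generative
assumptions at realistic sampling and noise levels — not that real tracks
are this clean. The residual confusion that does remain (a sedentary bird
whose saturating NSD is read as a small-scale half-migration) mirrors a
genuine ambiguity of the NSD family rather than an implementation
artefact.

## Numerical details and degenerate inputs

Longitudes are normalized to [−180, 180) and all longitude differences
taken on the shorter wrap unless explicitly unwrapped. Bearings are
radians clockwise from north in [0, 2π); coincident points raise rather
than returning an arbitrary bearing. Fit preconditions: ≥ 8 points over
≥ 20 days. `range_at` and `bearing_at_month` return a missing signal
(`None`) rather than extrapolating when no fix falls within ±3 days.
Empty 15-day periods are emitted as rows with zero fixes and missing
metrics. Tracks shorter than 80 days are classified but flagged
`partial`. The pipeline writes a JSON manifest with per-stage counts so
dropped individuals are always visible.

## Problem sizes

The default validation cohort is 50 tracks × 5 phenotypes (seeds 1–50 per
mode, schedules rotating), chosen to estimate a 90% recovery rate with a
binomial standard error under 2 points; noise calibrations use 100
replicates (asymptote recovery), 2000 (Rayleigh type-I), and 500
(Rayleigh power, mixed-model calibration in the test suite).
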