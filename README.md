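# fledgemove

Movement-mode classification and trajectory statistics for juvenile seabird
tracking data.

When albatross and petrel fledglings leave their natal colony they disperse
into an ocean they have never seen, and different species do it in
strikingly different ways: giant petrels race eastward and circle
Antarctica within three months, mollymawks and white-chinned petrels make a
directed 10–30 day transit to a distant settlement area and stay there,
sooty and Amsterdam albatrosses wander in wide loops that never take them
far from home. `fledgemove` implements the quantitative machinery needed to
tell these strategies apart from sparse, duty-cycled satellite tracks — and
a synthetic track generator that reproduces their statistical structure, so
every step of the pipeline can be validated against known ground truth.

## The method

The core statistic is the **net squared displacement** (NSD): the squared
great-circle distance between the colony and each location,
`NSD(t) = d(colony, x_t)²` in km². Its shape over time discriminates broad
movement modes, each expressed as a parametric curve fitted per individual
by multi-start weighted nonlinear least squares:

| mode | NSD model | signature |
|---|---|---|
| home range | `κ (1 − e^{−t/τ})` | fast saturation near the colony |
| nomadism | `β t` | unbounded diffusive growth |
| half-migration | `δ / (1 + e^{(θ−t)/φ})` | transit then plateau, no return |
| migration | `δ/(1+e^{(θ−t)/φ}) − δ/(1+e^{(θ₂−t)/φ₂})` | out, residence, and back |

Here `δ` is the asymptotic NSD (so `√δ` is the dispersion distance), `θ`
and `θ₂` the outbound/return inflection times (days), `φ, φ₂` the
transition timescales, `κ` the home-range plateau and `τ` its relaxation
time. The winning mode is the candidate with the highest **Lin concordance
correlation coefficient** between observed and fitted NSD, after a
plausibility screen discards fits whose timing or distances are
inconsistent with the spatio-temporal scale of the observed trajectory
(e.g. a "settlement" the track demonstrably moved past). A post-hoc
detector flags **large-scale looping** — bounded range combined with a
colony-bearing sweep ≥ π — which none of the four curves can represent.
For circumpolar birds, model fitting and ranges use an azimuthally
*unwrapped* displacement, so a full lap keeps accumulating range instead of
folding back at the antipode.

Around this core the package provides: iterative speed filtering and
3-day smoothing of coarse geolocator tracks; per-15-day-period trajectory
statistics (sinuosity `S = 1 − beeline/path`, daily distance travelled with
transmitter-off gaps excluded, mean latitude); circular statistics with the
Rayleigh uniformity test; bathymetry/SST/chlorophyll annotation with the
−3000 m neritic/oceanic rule; and mixed-model group comparisons with Tukey
contrasts plus exact Wilcoxon rank-sum tests.

## Worked example

Simulate one juvenile with a half-migration program (4000 km settlement,
16-day transit, 10 h ON / 24 h OFF duty cycle, 5 km Argos noise) and
classify it:

```python
from fledgemove import SimConfig, simulate_track, classify_movement

track, truth = simulate_track(SimConfig(mode="half_migration", seed=7))
c = classify_movement(track, seed=0)

print("fixes:", track.n_fixes, " duration: %.1f d" % track.duration_days)
print("best model:        ", c.best_model)
print("movement type:     ", c.movement_type)
print("range at 3 months: ", round(c.range_3mo_km), "km ->", c.scale)
print("dispersion distance:", round(c.dispersion_distance_km), "km")
for m, f in sorted(c.fits.items()):
    print(f"  cc[{m:14s}] = {f.cc:+.3f}  plausible={f.plausible}")
```

This prints:

```
fixes: 67  duration: 92.3 d
best model:         half_migration
movement type:      half_migration
range at 3 months:  3678 km -> medium
dispersion distance: 4014 km
  cc[half_migration] = +0.973  plausible=True
  cc[home_range    ] = +0.832  plausible=True
  cc[migration     ] = +0.980  plausible=False
  cc[nomad         ] = +0.488  plausible=True
```

Sixty-seven fixes (~0.7 locations/day) suffice to recover the generating
mode: the full migration curve actually fits marginally better (+0.980) but
is discarded as implausible because its fitted return leg is never
observed, and the half-migration model wins among the plausible candidates.
The dispersion distance `√δ` ≈ 4014 km recovers the generating 4000 km
settlement; the 3-month range (3678 km) puts the bird in the *medium*
dispersal class (3000–6000 km).

The same pipeline runs from the shell:

```bash
fledgemove run --seed 5 --out results/demo      # simulate -> classify -> stats -> compare
fledgemove simulate --n-per-mode 10 --seed 1 --out cohort/
fledgemove classify cohort/tracks.csv --out classes.csv
```

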