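"""Named constants and default thresholds for the analysis pipeline.

Every threshold that enters a scientific decision lives here under a name,
never as a literal inside an algorithm.  Values marked "configurable" are
the defaults picked up by :class:`fledgemove.pipeline.RunConfig` and can be
overridden from a config file or CLI flag.
"""
from __future__ import annotations

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM: float = 6371.0088

#: A bird is considered to have left the colony at its first fix at least
#: this far (km) from the colony; time zero of every track-relative clock.
DEPARTURE_RADIUS_KM: float = 5.0

#: Departure *bearing* is taken to the first fix at least this far (km)
#: from the colony, beyond typical Argos noise and colony attendance.
DEPARTURE_BEARING_RADIUS_KM: float = 100.0

#: Juvenile tracks are expected to start within this distance of the colony.
MAX_START_DISTANCE_KM: float = 50.0

#: Iterative speed-filter ceiling (km/h): sustained procellariiform ground
#: speed upper bound.
SPEED_FILTER_VMAX_KMH: float = 90.0

#: Adult geolocator tracks are smoothed over windows of this many days.
GLS_SMOOTHING_WINDOW_DAYS: float = 3.0

#: Dispersal-scale class bounds on the range from the colony at 3 months (km):
#: < 3000 small, 3000-6000 medium, > 6000 large.
SCALE_SMALL_MAX_KM: float = 3000.0
SCALE_MEDIUM_MAX_KM: float = 6000.0

#: Water shallower than this depth (m, negative down) is neritic
#: (continental shelf and lower slope); at or below it, oceanic.
NERITIC_DEPTH_THRESHOLD_M: float = -3000.0

#: Trajectory statistics are aggregated over blocks of this many days.
PERIOD_LENGTH_DAYS: float = 15.0

#: Months of track time are 30-day blocks since departure.
MONTH_LENGTH_DAYS: float = 30.0

#: Steps whose time gap exceeds this (hours) are excluded from the daily
#: distance travelled: longest transmitter OFF period (54-60 h) would
#: otherwise deflate speeds, while the common 24 h OFF gap stays included.
DDT_MAX_GAP_HOURS: float = 36.0

#: Tolerance (days) when locating the fix nearest a nominal time point
#: (range at 3 months, bearing at month 2/3).
TIME_MATCH_TOLERANCE_DAYS: float = 3.0

# --- model fitting and plausibility -----------------------------------------

#: Minimum data requirements for a nonlinear displacement-model fit.
FIT_MIN_POINTS: int = 8
FIT_MIN_DURATION_DAYS: float = 20.0

#: Number of jittered restarts around the heuristic start in multi-start
#: nonlinear least squares.
FIT_N_JITTER_STARTS: int = 4

#: Residuals are weighted by 1/max(nsd, FIT_WEIGHT_EPS_KM2) to tame the
#: quadratic scale of NSD (km^2).
FIT_WEIGHT_EPS_KM2: float = 1.0

#: Plausibility screen: inflection times must fall within this multiple of
#: the track duration; asymptotic distances within this multiple of the
#: largest observed displacement.
PLAUSIBILITY_TIME_FACTOR: float = 1.5
PLAUSIBILITY_DISTANCE_FACTOR: float = 1.25

#: A settlement-family fit is implausible when the track's final
#: displacement exceeds the claimed asymptotic distance by more than this
#: factor (the bird demonstrably kept going past the fitted settlement).
PLAUSIBILITY_ASYMPTOTE_OVERSHOOT: float = 1.15

#: A linear (nomadic) NSD slope is implausible if it implies a 3-month
#: range beyond this (km) -- roughly the antipodal maximum.
PLAUSIBILITY_MAX_RANGE_KM: float = 40000.0

#: Concordance ties below this margin are broken in favour of the model
#: with fewer parameters.
SELECT_CC_TIE_EPS: float = 1e-6

#: Looping detector: decline after an NSD local maximum must reach this
#: fraction of the maximum, and the unwrapped colony->bird bearing must
#: sweep at least LOOP_MIN_SWEEP_RAD over the track.
LOOP_DECLINE_FRACTION: float = 0.25
LOOP_MIN_SWEEP_RAD: float = 3.141592653589793
LOOP_MIN_DAYS: float = 30.0

#: classify_movement overrides the best NSD model with "large_scale_looping"
#: only when the looping detector fires, the best model is not full
#: migration, and the 3-month range is below this (km).
LOOP_MAX_RANGE_KM: float = 3500.0

#: Tracks shorter than this (days) get a partial classification flag.
CLASSIFY_MIN_DAYS: float = 80.0
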