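"""Displacement-model fitting and movement-mode classification.

Net squared displacement (NSD) — the squared beeline distance from the
natal colony — has a characteristic shape for each broad movement mode:

* ``home_range``   kappa * (1 - exp(-t/tau)): saturates quickly, the
  signature of attraction to a bounded area;
* ``nomad``        beta * t: unbounded linear growth, the diffusive
  signature of wandering with no destination;
* ``half_migration``  delta / (1 + exp((theta - t)/phi)): a single
  logistic — directed transit to a distant settlement area with no return
  within the observation window;
* ``migration``    the double logistic delta/(1+exp((theta-t)/phi)) -
  delta/(1+exp((theta2-t)/phi2)), theta2 > theta: transit, residence, and a
  completed return.

Each candidate is fitted per individual by multi-start weighted nonlinear
least squares and the winner is chosen by Lin's concordance correlation
coefficient among fits whose parameters survive a plausibility screen
(timing and distances must be consistent with the spatio-temporal scale of
the observed trajectory).  Wide loops that keep a bird within a bounded
range of the colony produce a non-monotone NSD that none of the four
models describes; they are caught post hoc by a dedicated detector and
reported as ``large_scale_looping``.

Model fitting operates on an azimuthally *unwrapped* displacement series
(:func:`fledgemove.geo.unwrapped_displacement_km`) so that circumpolar
birds accumulate displacement through a full lap instead of folding back
at the antipode; ranges and scale classes use the plain great-circle
distance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import config
from .geo import GeoPoint, NSDSeries, compute_nsd, haversine_km, initial_bearing, range_at, unwrapped_displacement_km
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES", "ModelFit", "MovementClassification",
    "eval_model", "fit_model", "concordance", "plausibility_check",
    "select_model", "detect_looping", "classify_movement", "classify_scale",
    "dispersion_distance", "asymptote_variation", "summarize_population",
]

MODEL_NAMES = ("home_range", "nomad", "half_migration", "migration")

#: Free parameters per model, used by the parsimony tie-break.
N_PARAMS = {"nomad": 1, "home_range": 2, "half_migration": 3, "migration": 5}

_PARAM_ORDER = {
    "home_range": ("kappa", "tau"),
    "nomad": ("beta",),
    "half_migration": ("delta", "theta", "phi"),
    "migration": ("delta", "theta", "phi", "theta2", "phi2"),
}

#: Juvenile models are fitted to the first three months after departure.
FIT_WINDOW_DAYS = 92.0


@dataclass
class ModelFit:
    """One candidate displacement model fitted to one NSD series."""

    model: str
    params: dict[str, float]
    cc: float  # Lin's concordance of fitted vs observed, [-1, 1]
    plausible: bool
    residual_sd: float  # km^2
    converged: bool = True

    def predict(self, t: np.ndarray) -> np.ndarray:
        return eval_model(self.model, self.params, t)


@dataclass
class MovementClassification:
    """Final movement-mode call for one individual."""

    individual_id: str
    species_code: str
    best_model: str
    movement_type: str  # best model, or "large_scale_looping" on override
    range_3mo_km: float | None
    scale: str | None  # small | medium | large
    fits: dict[str, ModelFit] = field(default_factory=dict)
    looping: bool = False
    plausible: bool = True
    partial: bool = False  # track shorter than the 3-month window
    dispersion_distance_km: float | None = None
    asymptote_variation_km: float | None = None


# --- model evaluation --------------------------------------------------------


def _logistic(t, delta, theta, phi):
    return delta / (1.0 + np.exp(np.clip((theta - t) / phi, -500, 500)))


def eval_model(model: str, params: Mapping[str, float], t) -> np.ndarray:
    """Evaluate a displacement model at times ``t`` (days); returns NSD in km^2."""
    t = np.asarray(t, dtype=float)
    if model == "home_range":
        return params["kappa"] * (1.0 - np.exp(-t / params["tau"]))
    if model == "nomad":
        return params["beta"] * t
    if model == "half_migration":
        return _logistic(t, params["delta"], params["theta"], params["phi"])
    if model == "migration":
        if params["theta2"] <= params["theta"]:
            raise ValueError("migration requires theta2 > theta")
        return (_logistic(t, params["delta"], params["theta"], params["phi"])
                - _logistic(t, params["delta"], params["theta2"], params["phi2"]))
    raise ValueError(f"unknown model {model!r}")


# --- concordance -------------------------------------------------------------


def concordance(observed, predicted) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    cc = 2 cov(o, p) / (var(o) + var(p) + (mean(o) - mean(p))^2), in [-1, 1].
    Rewards agreement in both trend and level: a fit that is precise but
    shifted, or centred but flat, scores low.  Two constant inputs give 1
    when equal and 0 otherwise, by convention.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite values in concordance inputs")
    vo, vp = o.var(), p.var()
    dm = o.mean() - p.mean()
    denom = vo + vp + dm * dm
    if denom == 0.0:
        return 1.0  # identical constants
    cov = ((o - o.mean()) * (p - p.mean())).mean()
    return float(np.clip(2.0 * cov / denom, -1.0, 1.0))


# --- fitting -----------------------------------------------------------------


def _weights(nsd: np.ndarray) -> np.ndarray:
    # 1/max(nsd, eps) residual weighting tames the quadratic km^2 scale
    return 1.0 / np.sqrt(np.maximum(nsd, config.FIT_WEIGHT_EPS_KM2))


def _heuristic_start(series: NSDSeries, model: str) -> np.ndarray:
    t, nsd = series.t, series.nsd
    T = max(series.duration_days, 1.0)
    rel = t - t[0]
    plateau = float(np.median(nsd[rel >= 0.75 * T])) if np.any(rel >= 0.75 * T) else float(nsd[-1])
    plateau = max(plateau, config.FIT_WEIGHT_EPS_KM2)
    above = rel[nsd >= 0.5 * plateau]
    t_half = float(above[0]) if len(above) else 0.5 * T
    if model == "home_range":
        return np.array([plateau, max(t_half, 0.5)])
    if model == "nomad":
        w = 1.0 / np.maximum(nsd, config.FIT_WEIGHT_EPS_KM2)
        beta = float(np.sum(w * rel * nsd) / max(np.sum(w * rel**2), 1e-12))
        return np.array([max(beta, 1e-6)])
    if model == "half_migration":
        return np.array([plateau, max(t_half, 0.5), max(T / 15.0, 0.5)])
    if model == "migration":
        below = rel[(rel > t_half) & (nsd < 0.5 * plateau)]
        t_down = float(below[0]) if len(below) else 0.8 * T
        t_down = max(t_down, t_half + 1.0)
        return np.array([plateau, max(t_half, 0.5), max(T / 20.0, 0.5),
                         t_down, max(T / 20.0, 0.5)])
    raise ValueError(f"unknown model {model!r}")


def _bounds(series: NSDSeries, model: str):
    T = max(series.duration_days, 1.0)
    amax = max(series.nsd.max(), 1.0) * 9.0  # (3 x max distance)^2
    lo_t, hi_t = 0.0, 3.0 * T
    lo_phi, hi_phi = 0.05, 2.0 * T
    if model == "home_range":
        return ([1e-9, 0.05], [amax, 3.0 * T])
    if model == "nomad":
        return ([0.0], [1e10])
    if model == "half_migration":
        return ([1e-9, lo_t, lo_phi], [amax, hi_t, hi_phi])
    if model == "migration":
        # theta2 parameterized as theta + dtheta, dtheta > 0, for ordering
        return ([1e-9, lo_t, lo_phi, 0.1, lo_phi], [amax, hi_t, hi_phi, 3.0 * T, hi_phi])
    raise ValueError(model)


def _unpack(model: str, x: np.ndarray) -> dict[str, float]:
    if model == "migration":
        d, th, ph, dth, ph2 = x
        return {"delta": d, "theta": th, "phi": ph, "theta2": th + dth, "phi2": ph2}
    return dict(zip(_PARAM_ORDER[model], x))


_MODEL_SEED_OFFSET = {m: i for i, m in enumerate(MODEL_NAMES)}


def fit_model(series: NSDSeries, model: str, seed: int = 0) -> ModelFit:
    """Fit one displacement model to an NSD series by multi-start weighted NLS.

    Residuals are weighted by ``1/sqrt(max(nsd, eps))`` (i.e. squared
    residuals by ``1/max(nsd, eps)``); the best of one heuristic start plus
    :data:`~fledgemove.config.FIT_N_JITTER_STARTS` seeded jitters (by
    weighted SSE) is kept.  Deterministic given ``seed``.

    A fit that fails to converge from every start is returned with
    ``converged=False`` and ``cc=-inf`` so it can never be selected.
    """
    if len(series) < config.FIT_MIN_POINTS or series.duration_days < config.FIT_MIN_DURATION_DAYS:
        raise ValueError(
            f"need >= {config.FIT_MIN_POINTS} points over >= "
            f"{config.FIT_MIN_DURATION_DAYS} days to fit {model}")
    rel = series.t - series.t[0]
    nsd = series.nsd
    w = _weights(nsd)
    lo, hi = _bounds(series, model)
    x0 = np.clip(_heuristic_start(series, model), np.asarray(lo) + 1e-12, hi)
    if model == "migration":  # convert theta2 start to dtheta
        x0 = x0.copy()
        x0[3] = max(x0[3] - x0[1], 0.2)

    def resid(x):
        return (eval_model(model, _unpack(model, x), rel) - nsd) * w

    rng = np.random.default_rng(max(int(seed), 0) * 8 + _MODEL_SEED_OFFSET[model])
    starts = [x0]
    for _ in range(config.FIT_N_JITTER_STARTS):
        jitter = np.exp(rng.normal(0.0, 0.4, size=len(x0)))
        starts.append(np.clip(x0 * jitter, np.asarray(lo) + 1e-12, hi))

    best = None
    for start in starts:
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf",
                                x_scale="jac", max_nfev=400)
        except Exception:  # singular Jacobian, overflow, ...
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ModelFit(model=model, params={}, cc=-np.inf, plausible=False,
                        residual_sd=np.inf, converged=False)
    params = _unpack(model, best.x)
    pred = eval_model(model, params, rel)
    fit = ModelFit(model=model, params=params, cc=concordance(nsd, pred),
                   plausible=True, residual_sd=float(np.std(nsd - pred)))
    fit.plausible = plausibility_check(fit, series)
    return fit


# --- plausibility ------------------------------------------------------------


def _plateau_growing(series: NSDSeries, plateau_start: float, asym_km: float,
                     growth_frac: float = 0.15) -> bool:
    """True when displacement keeps trending upward through a claimed plateau.

    A settlement fit asserts that displacement stops growing after
    ``theta + 2 phi``; if the linear trend of sqrt(nsd) over that window
    amounts to more than ``growth_frac`` of the asymptotic distance, the
    bird demonstrably had not settled.
    """
    rel = series.t - series.t[0]
    sel = rel >= plateau_start
    if sel.sum() < 3:
        return False
    tt, dd = rel[sel], np.sqrt(series.nsd[sel])
    slope = np.polyfit(tt, dd, 1)[0]
    return slope * (tt[-1] - tt[0]) > growth_frac * max(asym_km, 1.0)


def plausibility_check(fit: ModelFit, series: NSDSeries) -> bool:
    """Screen fitted parameters against the trajectory's spatio-temporal scale.

    A fit is implausible when its timing or distances lie outside what the
    observed track can support:

    * an inflection time outside ``[0, 1.5 x duration]``;
    * an asymptotic distance (sqrt(delta) or sqrt(kappa)) beyond 1.25 x the
      largest observed displacement;
    * a transition timescale phi longer than the track, or shorter than
      half the mean sampling interval (a transition the sampling cannot
      resolve);
    * a linear slope implying a 3-month range beyond
      :data:`~fledgemove.config.PLAUSIBILITY_MAX_RANGE_KM`;
    * a settlement (half-migration) fit whose settlement is not actually
      witnessed: the plateau must begin within the window
      (``theta + 2 phi <= duration``), the track must not end beyond the
      claimed asymptote (final displacement <= 1.15 sqrt(delta)), and
      displacement must not keep trending upward through the claimed
      plateau;
    * a migration fit whose return is not substantially observed (model
      still above delta/2 at the last fix): the return leg would be pure
      extrapolation.
    """
    if not fit.converged:
        return False
    p = fit.params
    T = max(series.duration_days, 1.0)
    dmax = float(np.sqrt(series.nsd.max()))
    t_hi = config.PLAUSIBILITY_TIME_FACTOR * T
    d_hi = config.PLAUSIBILITY_DISTANCE_FACTOR * max(dmax, 1.0)
    mean_dt = T / max(len(series) - 1, 1)
    phi_lo = mean_dt  # 10-90% transition ~4.4 phi: need >= ~4 fixes across it
    d_end = float(np.median(np.sqrt(series.nsd[-5:])))
    overshoot = config.PLAUSIBILITY_ASYMPTOTE_OVERSHOOT

    if fit.model == "home_range":
        return bool(np.sqrt(p["kappa"]) <= d_hi and 0 < p["tau"] <= t_hi)
    if fit.model == "nomad":
        return bool(np.sqrt(max(p["beta"], 0.0) * 90.0) <= config.PLAUSIBILITY_MAX_RANGE_KM)
    if fit.model == "half_migration":
        return bool(0.0 <= p["theta"] <= t_hi and phi_lo <= p["phi"] <= T
                    and np.sqrt(p["delta"]) <= d_hi
                    and p["theta"] + 2.0 * p["phi"] <= T
                    and d_end <= overshoot * np.sqrt(p["delta"])
                    and not _plateau_growing(series, p["theta"] + 2.0 * p["phi"],
                                             np.sqrt(p["delta"])))
    if fit.model == "migration":
        end_val = float(eval_model("migration", p, np.array([T]))[0])
        return bool(0.0 <= p["theta"] <= t_hi and 0.0 <= p["theta2"] <= t_hi
                    and phi_lo <= p["phi"] <= T and phi_lo <= p["phi2"] <= T
                    and np.sqrt(p["delta"]) <= d_hi
                    and p["theta"] + 2.0 * p["phi"] <= T
                    and end_val <= 0.5 * p["delta"])
    raise ValueError(fit.model)


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Best fit by concordance among plausible candidates.

    If no candidate is plausible the highest-concordance fit is returned
    with its ``plausible=False`` flag intact.  Concordance ties (within
    :data:`~fledgemove.config.SELECT_CC_TIE_EPS`) go to the model with
    fewer parameters; the result is invariant to input order.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    pool = [f for f in fits if f.plausible] or fits

    def key(f: ModelFit):
        return (-f.cc, N_PARAMS[f.model], f.model)

    ordered = sorted(pool, key=key)
    best = ordered[0]
    for f in ordered[1:]:
        if best.cc - f.cc < config.SELECT_CC_TIE_EPS and N_PARAMS[f.model] < N_PARAMS[best.model]:
            best = f
    return best


# --- looping detection -------------------------------------------------------


def detect_looping(series: NSDSeries, track: Track) -> bool:
    """Detect large-scale looping: bounded range plus rotation about the colony.

    Fires when (i) the NSD series has a maximum followed by a decline of at
    least 25% of that maximum, and (ii) the colony-to-bird bearing,
    unwrapped along the track, sweeps at least pi radians.  Bearings are
    only evaluated at fixes beyond the departure-bearing radius, where they
    are not dominated by position noise.  Requires >= 30 days of data.
    """
    if series.duration_days < config.LOOP_MIN_DAYS:
        return False
    nsd = series.nsd
    cummax = np.maximum.accumulate(nsd)
    declined = np.any(nsd <= (1.0 - config.LOOP_DECLINE_FRACTION) * cummax)
    if not declined:
        return False
    far = track.distances_from_colony() >= config.DEPARTURE_BEARING_RADIUS_KM
    if far.sum() < 3:
        return False
    lon, lat = track.lon[far], track.lat[far]
    bearings = np.array([
        initial_bearing(track.colony, GeoPoint(float(lo), float(la)))
        for lo, la in zip(lon, lat)
    ])
    sweep = np.unwrap(bearings)
    return bool(sweep.max() - sweep.min() >= config.LOOP_MIN_SWEEP_RAD)


# --- classification ----------------------------------------------------------


def classify_scale(range_3mo_km: float) -> str:
    """Dispersal scale from the 3-month range: <3000 small, 3000-6000 medium, >6000 large."""
    if range_3mo_km < 0:
        raise ValueError("range must be non-negative")
    if range_3mo_km < config.SCALE_SMALL_MAX_KM:
        return "small"
    if range_3mo_km <= config.SCALE_MEDIUM_MAX_KM:
        return "medium"
    return "large"


def dispersion_distance(fit: ModelFit) -> float | None:
    """Distance to colony of the migratory asymptote, sqrt(delta) km.

    Defined for the migration family only; ``None`` otherwise.
    """
    if fit.model not in ("half_migration", "migration"):
        return None
    return float(np.sqrt(fit.params["delta"]))


def asymptote_variation(fit: ModelFit, series: NSDSeries) -> float | None:
    """Spread (km) of observed minus fitted displacement over the plateau.

    The plateau is ``t`` between ``theta + 2 phi`` and ``theta2 - 2 phi2``
    (or the series end for half-migration); returns the standard deviation
    of ``sqrt(nsd) - sqrt(fitted)`` there, or ``None`` when the window is
    empty.
    """
    if fit.model not in ("half_migration", "migration"):
        return None
    rel = series.t - series.t[0]
    lo = fit.params["theta"] + 2.0 * fit.params["phi"]
    hi = (fit.params["theta2"] - 2.0 * fit.params["phi2"]
          if fit.model == "migration" else rel[-1])
    sel = (rel >= lo) & (rel <= hi)
    if sel.sum() < 2:
        return None
    pred = fit.predict(rel[sel])
    resid = np.sqrt(series.nsd[sel]) - np.sqrt(np.maximum(pred, 0.0))
    return float(np.std(resid))


def unwrapped_nsd_series(track: Track, origin: GeoPoint | None = None) -> NSDSeries:
    """NSD series on the azimuthally unwrapped displacement, from departure."""
    origin = origin if origin is not None else track.colony
    d = unwrapped_displacement_km(track, origin)
    i0 = track.departure_index()
    if i0 is None:
        raise ValueError("track never leaves the departure radius")
    t = track.days_since(track.times[i0])[i0:]
    return NSDSeries(t=t, nsd=d[i0:] ** 2, origin=origin)


def classify_movement(track: Track, seed: int = 0) -> MovementClassification:
    """Fit all four displacement models to a track and call its movement mode.

    Models are fitted (on the unwrapped displacement, first three months)
    and the concordance winner among plausible fits is taken; the looping
    detector then overrides the call to ``large_scale_looping`` when it
    fires, the winner is not full migration, and the 3-month range is below
    :data:`~fledgemove.config.LOOP_MAX_RANGE_KM`.  Tracks shorter than
    :data:`~fledgemove.config.CLASSIFY_MIN_DAYS` are flagged ``partial``.
    """
    series = unwrapped_nsd_series(track)
    partial = series.duration_days < config.CLASSIFY_MIN_DAYS
    window = series.t - series.t[0] <= FIT_WINDOW_DAYS
    fit_series = NSDSeries(t=series.t[window], nsd=series.nsd[window], origin=series.origin)

    fits = {}
    for m in MODEL_NAMES:
        try:
            fits[m] = fit_model(fit_series, m, seed=seed)
        except ValueError as exc:
            logger.warning("%s: %s fit skipped (%s)", track.individual_id, m, exc)
    if not fits:
        raise ValueError(f"track {track.individual_id} too short to classify")

    best = select_model(list(fits.values()))
    r3 = range_at(track, t_days=90.0)
    scale = classify_scale(r3) if r3 is not None else None
    looping = detect_looping(fit_series, track)
    # guard range for the looping override: last in-window distance when the
    # 3-month range itself is unavailable
    r_guard = r3 if r3 is not None else float(np.sqrt(fit_series.nsd[-1]))
    movement_type = best.model
    if (looping and best.model in ("home_range", "nomad", "half_migration")
            and r_guard < config.LOOP_MAX_RANGE_KM):
        movement_type = "large_scale_looping"
    return MovementClassification(
        individual_id=track.individual_id, species_code=track.species_code,
        best_model=best.model, movement_type=movement_type,
        range_3mo_km=r3, scale=scale, fits=fits, looping=looping,
        plausible=best.plausible, partial=partial,
        dispersion_distance_km=dispersion_distance(best),
        asymptote_variation_km=asymptote_variation(best, fit_series),
    )


def summarize_population(classifications: Sequence[MovementClassification]) -> pd.DataFrame:
    """Per-species summary: mode prevalences and parameter means +- SD.

    A per-individual stand-in for population-level random-effect estimates:
    one row per (species, best model) with the count, share, mean and SD of
    each fitted parameter, and mean 3-month range.
    """
    rows = []
    for c in classifications:
        fit = c.fits.get(c.best_model)
        row = {"species": c.species_code, "movement_type": c.movement_type,
               "best_model": c.best_model, "range_3mo_km": c.range_3mo_km}
        if fit is not None:
            row.update({f"param_{k}": v for k, v in fit.params.items()})
            row["cc"] = fit.cc
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    grouped = df.groupby(["species", "movement_type"])
    out = grouped.agg(n=("best_model", "size"),
                      range_3mo_mean=("range_3mo_km", "mean"),
                      range_3mo_sd=("range_3mo_km", "std"),
                      cc_mean=("cc", "mean"))
    counts = df.groupby("species")["movement_type"].size()
    out["share"] = [n / counts[sp] for (sp, _), n in out["n"].items()]
    param_cols = [c for c in df.columns if c.startswith("param_")]
    for col in param_cols:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_sd"] = grouped[col].std()
    return out.reset_index()
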