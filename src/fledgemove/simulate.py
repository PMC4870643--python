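"""Synthetic juvenile/adult seabird tracks and environmental rasters.

The generator emulates the statistical structure the analysis assumes:

* five large-scale movement phenotypes — sedentary *home range* (bounded
  wandering in a foraging sector near the colony), *nomad* (fast eastward
  circumpolar drift in the Westerlies), *half migration* (a 10-30 day
  directed transit to a distant settlement area, no return), full
  *migration* (transit, residence and a completed return), and *large-scale
  looping* (a wide arc that keeps the bird within a bounded range of the
  colony while its bearing from the colony sweeps around);
* Argos-like duty-cycled sampling (10 h ON / 24 h OFF, 18/54 or 12/60) with
  sparse within-window acquisitions, yielding on the order of 0.65
  locations per day;
* isotropic positional noise, a few km for Argos, ~180 km median radial
  error for light-level geolocation (GLS).

The latent path is built at hourly resolution before subsampling, so
duty-cycle and noise effects stay separable.  All randomness flows from
``SimConfig.seed``; equal configs give identical tracks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import GeoPoint, destination_point, haversine_km, initial_bearing, normalize_lon
from .habitat import EnvRaster
from .tracks import Track

__all__ = [
    "CROZET", "KERGUELEN", "AMSTERDAM", "SIM_MODES", "SimConfig",
    "simulate_track", "apply_duty_cycle", "add_positional_noise",
    "simulate_cohort", "make_env_rasters",
]

#: The three source colonies, south-western Indian Ocean.
CROZET = GeoPoint(52.4, -46.2)
KERGUELEN = GeoPoint(70.1, -49.4)
AMSTERDAM = GeoPoint(77.3, -38.4)

SIM_MODES = ("home_range", "nomad", "half_migration", "migration", "looping")

#: Transmitter duty cycles in use (hours ON, hours OFF).
DUTY_CYCLES = ((10, 24), (18, 54), (12, 60))

#: Per-axis Gaussian sd (km) whose radial error has median 180 km (GLS).
GLS_NOISE_SD_KM = 180.0 / math.sqrt(2.0 * math.log(2.0))

_EPOCH = np.datetime64("2014-01-10T00:00:00", "s")

_MODE_DEFAULTS = {
    # nominal_speed (km/day), heading_mean (rad cw from N), heading_kappa
    "home_range": dict(nominal_speed_kmday=300.0, heading_mean_rad=np.pi / 2, heading_kappa=1.0),
    "nomad": dict(nominal_speed_kmday=350.0, heading_mean_rad=np.pi / 2, heading_kappa=20.0),
    "half_migration": dict(nominal_speed_kmday=250.0, heading_mean_rad=np.pi / 2,
                           heading_kappa=20.0, transit_days=16.0, settlement_distance_km=4000.0),
    "migration": dict(nominal_speed_kmday=250.0, heading_mean_rad=np.pi / 2,
                      heading_kappa=20.0, transit_days=16.0, settlement_distance_km=4000.0),
    "looping": dict(nominal_speed_kmday=240.0, heading_mean_rad=np.pi / 2,
                    heading_kappa=1.0, loop_radius_km=1000.0),
}

_MODE_SPECIES = {"home_range": "SHR", "nomad": "SNM", "half_migration": "SHM",
                 "migration": "SMG", "looping": "SLP"}


@dataclass
class SimConfig:
    """Generative parameters of one synthetic track; ``seed`` fixes all randomness."""

    mode: str
    colony: GeoPoint = CROZET
    duration_days: float = 93.0  # a shade over 3 months so day 90 is always sampled
    nominal_speed_kmday: float | None = None
    heading_mean_rad: float | None = None
    heading_kappa: float | None = None
    transit_days: float | None = None
    settlement_distance_km: float | None = None
    loop_radius_km: float | None = None
    loop_center_frac: float = 0.3  # loop centre at this fraction of the radius from the colony
    home_range_sd_km: float = 450.0  # stationary foraging radius of the sedentary wander
    home_range_tau_days: float = 16.0  # radius expansion; NSD saturates over ~tau/2
    home_range_sector_sd_rad: float = 0.4
    settle_sd_km: float = 150.0  # wander around the settlement point
    settle_tau_days: float = 3.0
    target_lat: float = -55.0  # nomads relax toward this latitude
    lat_pull_gain: float = 0.06  # rad of heading bias per degree of latitude error
    step_kappa: float = 8.0  # hourly heading concentration during directed phases
    duty_cycle: tuple[float, float] = (10.0, 24.0)
    fixes_per_on: int | None = None  # Argos acquisitions kept per ON window (None: ~h_on/8)
    argos_noise_sd_km: float = 5.0
    noise_kind: str = "argos"  # "argos" | "gls"
    source: str = "argos"  # "argos" duty-cycled | "gls" 2 fixes/day
    gls_interval_hours: float = 12.0
    seed: int = 0
    species_code: str | None = None
    individual_id: str | None = None
    age_class: str = "juvenile"

    def __post_init__(self) -> None:
        if self.mode not in SIM_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        for name, default in _MODE_DEFAULTS[self.mode].items():
            if getattr(self, name) is None:
                setattr(self, name, default)
        if self.mode in ("half_migration", "migration") and not self.settlement_distance_km:
            raise ValueError(f"{self.mode} requires a positive settlement_distance_km")
        if self.mode == "looping" and not self.loop_radius_km:
            raise ValueError("looping requires a positive loop_radius_km")
        if self.heading_kappa is not None and self.heading_kappa < 0:
            raise ValueError("heading_kappa must be >= 0")
        if self.species_code is None:
            self.species_code = _MODE_SPECIES[self.mode]
        if self.individual_id is None:
            self.individual_id = f"{self.species_code}_{self.seed:05d}"


# --- low-level path helpers --------------------------------------------------


def _dest_arrays(origin: GeoPoint, bearing: np.ndarray, dist_km: np.ndarray):
    """Vectorized great-circle destination from a single origin."""
    from .config import EARTH_RADIUS_KM
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    th = np.asarray(bearing, dtype=float)
    p1, l1 = math.radians(origin.lat), math.radians(origin.lon)
    p2 = np.arcsin(np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(th))
    l2 = l1 + np.arctan2(np.sin(th) * np.sin(delta) * np.cos(p1),
                         np.cos(delta) - np.sin(p1) * np.sin(p2))
    return normalize_lon(np.degrees(l2)), np.degrees(p2)


def _slerp_hourly(way_lon: np.ndarray, way_lat: np.ndarray, sub: int = 24):
    """Great-circle interpolation of daily waypoints to hourly positions."""
    lam = np.radians(way_lon)
    phi = np.radians(way_lat)
    xyz = np.stack([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=1)
    out = [xyz[0]]
    for a, b in zip(xyz[:-1], xyz[1:]):
        dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
        omega = math.acos(dot)
        for k in range(1, sub + 1):
            f = k / sub
            if omega < 1e-9:
                v = a * (1 - f) + b * f
            else:
                v = (math.sin((1 - f) * omega) * a + math.sin(f * omega) * b) / math.sin(omega)
            out.append(v / np.linalg.norm(v))
    out = np.asarray(out)
    lat = np.degrees(np.arcsin(np.clip(out[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(out[:, 1], out[:, 0]))
    return normalize_lon(lon), lat


def _crw_segment(start: GeoPoint, n_steps: int, step_km: np.ndarray,
                 wobble: np.ndarray, target: GeoPoint | None = None,
                 heading_fixed: float | None = None,
                 lat_pull: tuple[float, float] | None = None):
    """Sequential correlated-walk steps; returns (lon, lat) arrays incl. start.

    The mean heading at each step either points at ``target``, or is
    ``heading_fixed`` (optionally biased toward a target latitude by
    ``lat_pull = (target_lat, gain)``); ``wobble`` is added on top.
    Stops early once within one step of ``target``.
    """
    lons = np.empty(n_steps + 1)
    lats = np.empty(n_steps + 1)
    lons[0], lats[0] = start.lon, start.lat
    pos = start
    n_done = n_steps
    for i in range(n_steps):
        if target is not None:
            d_left = haversine_km(pos, target)
            if d_left <= step_km[i]:
                lons[i + 1], lats[i + 1] = target.lon, target.lat
                pos = target
                n_done = i + 1
                break
            mu = initial_bearing(pos, target)
        else:
            mu = heading_fixed
            if lat_pull is not None:
                t_lat, gain = lat_pull
                mu = mu + float(np.clip(gain * (pos.lat - t_lat), -0.7, 0.7))
        pos = destination_point(pos, mu + wobble[i], step_km[i])
        lons[i + 1], lats[i + 1] = pos.lon, pos.lat
    return lons[: n_done + 1], lats[: n_done + 1], pos


def _ou_1d(n: int, sigma: float, tau: float, rng: np.random.Generator,
           x0: float = 0.0) -> np.ndarray:
    """Daily Ornstein-Uhlenbeck samples, stationary sd ``sigma``, clip 2.5 sd."""
    if sigma == 0:
        return np.full(n, x0)
    s = sigma * math.sqrt(2.0 / tau)
    x = np.empty(n)
    x[0] = x0
    noise = np.clip(rng.normal(0.0, 1.0, size=n - 1), -2.5, 2.5) * s
    for i in range(1, n):
        x[i] = x[i - 1] * (1.0 - 1.0 / tau) + noise[i - 1]
    return x


def _ou_waypoints(center: GeoPoint, n_days: int, sigma: float, tau: float,
                  rng: np.random.Generator, start: GeoPoint | None = None):
    """Daily OU wander (per-axis sd ``sigma`` km) around ``center`` in local km."""
    coslat = math.cos(math.radians(center.lat))
    if start is None:
        x0 = y0 = 0.0
    else:
        x0 = normalize_lon(start.lon - center.lon) * 111.32 * coslat
        y0 = (start.lat - center.lat) * 111.32
    x = _ou_1d(n_days + 1, sigma, tau, rng, x0)
    y = _ou_1d(n_days + 1, sigma, tau, rng, y0)
    lat = center.lat + y / 111.32
    lon = normalize_lon(center.lon + x / (111.32 * coslat))
    return lon, lat


# --- latent paths per mode ---------------------------------------------------


def _steps(rng, n, mean_km, sd_frac=0.25):
    raw = mean_km * np.exp(rng.normal(0.0, sd_frac, size=n))
    return np.clip(raw, 0.1 * mean_km, 2.5 * mean_km)


def _latent_home_range(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sector-biased wander whose foraging radius expands diffusively.

    The radius approaches its stationary value R like sqrt(1 - exp(-2t/tau))
    (so the expected NSD is exactly the saturating home-range curve) with
    short-memory jitter on top; the bearing from the colony wobbles slowly
    around a per-individual preferred sector.
    """
    n_days = int(math.ceil(cfg.duration_days))
    t = np.arange(n_days + 1, dtype=float)
    R = cfg.home_range_sd_km * float(np.exp(rng.normal(0.0, 0.15)))
    base = R * np.sqrt(1.0 - np.exp(-2.0 * t / cfg.home_range_tau_days))
    jitter = _ou_1d(n_days + 1, 0.12 * R, 2.5, rng)
    r = np.clip(base + jitter, 0.0, None)
    psi0 = float(rng.vonmises(cfg.heading_mean_rad, cfg.heading_kappa))
    psi = psi0 + _ou_1d(n_days + 1, cfg.home_range_sector_sd_rad, 5.0, rng)
    way_lon, way_lat = _dest_arrays(cfg.colony, psi, r)
    return _slerp_hourly(way_lon, way_lat)


def _latent_nomad(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    n = int(cfg.duration_days * 24)
    mu0 = float(rng.vonmises(cfg.heading_mean_rad, cfg.heading_kappa))
    wobble = rng.vonmises(0.0, cfg.step_kappa, size=n)
    steps = _steps(rng, n, cfg.nominal_speed_kmday / 24.0)
    lon, lat, _ = _crw_segment(cfg.colony, n, steps, wobble, heading_fixed=mu0,
                               lat_pull=(cfg.target_lat, cfg.lat_pull_gain))
    return lon, lat


def _latent_half_migration(cfg: SimConfig, rng, with_return: bool = False):
    alpha = float(rng.vonmises(cfg.heading_mean_rad, cfg.heading_kappa))
    dest = destination_point(cfg.colony, alpha, cfg.settlement_distance_km)
    transit_h = int(cfg.transit_days * 24)
    speed_h = cfg.settlement_distance_km / transit_h
    wob = rng.vonmises(0.0, cfg.step_kappa, size=transit_h * 3)
    steps = _steps(rng, transit_h * 3, speed_h, sd_frac=0.15)
    lon_t, lat_t, pos = _crw_segment(cfg.colony, min(transit_h * 3, int(cfg.duration_days * 24)),
                                     steps, wob, target=dest)
    used_h = len(lon_t) - 1
    total_h = int(cfg.duration_days * 24)
    if used_h >= total_h:
        return lon_t[: total_h + 1], lat_t[: total_h + 1]
    if not with_return:
        n_days = int(math.ceil((total_h - used_h) / 24))
        wlon, wlat = _ou_waypoints(pos, n_days, cfg.settle_sd_km, cfg.settle_tau_days, rng)
        slon, slat = _slerp_hourly(wlon, wlat)
        lon = np.concatenate([lon_t, slon[1 : total_h - used_h + 1]])
        lat = np.concatenate([lat_t, slat[1 : total_h - used_h + 1]])
        return lon, lat
    # full migration: settle, then a mirrored return leg
    return_h = transit_h
    settle_h = max(total_h - used_h - int(1.3 * return_h), 24)
    n_days = int(math.ceil(settle_h / 24))
    wlon, wlat = _ou_waypoints(pos, n_days, cfg.settle_sd_km, cfg.settle_tau_days, rng)
    slon, slat = _slerp_hourly(wlon, wlat)
    slon, slat = slon[1 : settle_h + 1], slat[1 : settle_h + 1]
    pos = GeoPoint(float(slon[-1]), float(slat[-1]))
    left_h = total_h - used_h - len(slon)
    wob = rng.vonmises(0.0, cfg.step_kappa, size=left_h)
    steps = _steps(rng, left_h, speed_h, sd_frac=0.15)
    rlon, rlat, pos = _crw_segment(pos, left_h, steps, wob, target=cfg.colony)
    parts_lon = [lon_t, slon, rlon[1:]]
    parts_lat = [lat_t, slat, rlat[1:]]
    done = used_h + len(slon) + len(rlon) - 1
    if done < total_h:  # arrived home early: linger near the colony
        n_days = int(math.ceil((total_h - done) / 24))
        wlon, wlat = _ou_waypoints(cfg.colony, n_days, 40.0, 2.0, rng, start=pos)
        hlon, hlat = _slerp_hourly(wlon, wlat)
        parts_lon.append(hlon[1 : total_h - done + 1])
        parts_lat.append(hlat[1 : total_h - done + 1])
    return np.concatenate(parts_lon), np.concatenate(parts_lat)


def _latent_looping(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    alpha = float(rng.vonmises(cfg.heading_mean_rad, cfg.heading_kappa))
    r_loop = cfg.loop_radius_km
    center = destination_point(cfg.colony, alpha, cfg.loop_center_frac * r_loop)
    gamma0 = initial_bearing(center, cfg.colony)
    start_pt = destination_point(center, gamma0, r_loop)
    total_h = int(cfg.duration_days * 24)
    speed_h = cfg.nominal_speed_kmday / 24.0
    # short directed transit from the colony onto the loop
    d0 = haversine_km(cfg.colony, start_pt)
    # allow slack so jittered steps still reach the arc start
    transit_h = min(2 * (int(d0 / speed_h) + 2), total_h)
    wob = rng.vonmises(0.0, cfg.step_kappa, size=transit_h)
    steps = _steps(rng, transit_h, speed_h, sd_frac=0.15)
    lon_t, lat_t, pos = _crw_segment(cfg.colony, transit_h, steps, wob, target=start_pt)
    used_h = len(lon_t) - 1
    left = total_h - used_h
    if left <= 0:
        return lon_t[: total_h + 1], lat_t[: total_h + 1]
    direction = 1.0 if rng.random() < 0.5 else -1.0
    omega = direction * speed_h / r_loop  # rad per hour along the arc
    jitter = _ou_1d(left, 0.04, 48.0, rng)  # slow fractional radius breathing
    gwob = np.cumsum(rng.normal(0.0, 0.004, size=left))
    gam = gamma0 + omega * np.arange(1, left + 1) + gwob
    rr = r_loop * (1.0 + jitter)
    llon, llat = _dest_arrays(center, gam, rr)
    return np.concatenate([lon_t, llon]), np.concatenate([lat_t, llat])


# --- public operations -------------------------------------------------------


def simulate_track(cfg: SimConfig) -> tuple[Track, dict]:
    """Generate one synthetic track and its ground-truth record.

    Builds the hourly latent path for ``cfg.mode``, subsamples it (Argos
    duty cycle with sparse within-window acquisitions, or 2 fixes/day for
    GLS) and applies positional noise.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(int(cfg.seed))
    if cfg.mode == "home_range":
        lon, lat = _latent_home_range(cfg, rng)
    elif cfg.mode == "nomad":
        lon, lat = _latent_nomad(cfg, rng)
    elif cfg.mode == "half_migration":
        lon, lat = _latent_half_migration(cfg, rng, with_return=False)
    elif cfg.mode == "migration":
        lon, lat = _latent_half_migration(cfg, rng, with_return=True)
    else:
        lon, lat = _latent_looping(cfg, rng)
    n = len(lon)
    times = _EPOCH + (np.arange(n) * 3600).astype("timedelta64[s]")
    latent = Track(individual_id=cfg.individual_id, species_code=cfg.species_code,
                   age_class=cfg.age_class, colony=cfg.colony, times=times,
                   lon=lon, lat=lat, source="simulated")

    if cfg.source == "gls":
        step = max(int(cfg.gls_interval_hours), 1)
        tr = latent.subset(np.arange(0, n, step))
        tr = add_positional_noise(tr, None, kind="gls", rng=rng)
    else:
        tr = apply_duty_cycle(latent, cfg.duty_cycle)
        tr = _thin_on_windows(tr, cfg, rng)
        tr = add_positional_noise(tr, cfg.argos_noise_sd_km, kind=cfg.noise_kind, rng=rng)
        if tr.times[0] != latent.times[0]:
            # keep the deployment fix (known colony position, no Argos
            # error) so every juvenile track starts at its colony
            first = latent.subset(np.array([0]))
            tr = dc_replace(tr, times=np.concatenate([first.times, tr.times]),
                            lon=np.concatenate([first.lon, tr.lon]),
                            lat=np.concatenate([first.lat, tr.lat]))

    truth = {"individual_id": cfg.individual_id, "species": cfg.species_code,
             "mode": cfg.mode, "seed": cfg.seed,
             "nominal_speed_kmday": cfg.nominal_speed_kmday,
             "settlement_distance_km": cfg.settlement_distance_km,
             "loop_radius_km": cfg.loop_radius_km,
             "duration_days": cfg.duration_days,
             "duty_cycle": f"{cfg.duty_cycle[0]:g}on-{cfg.duty_cycle[1]:g}off"}
    return tr, truth


def apply_duty_cycle(track: Track, pattern: tuple[float, float]) -> Track:
    """Keep only fixes whose time-of-cycle falls in the ON window.

    The cycle is anchored at the departure fix (first fix beyond the
    departure radius), or at the first fix if the track never departs.
    ``(h_on, 0)`` leaves the track unchanged.
    """
    h_on, h_off = pattern
    if h_on <= 0:
        raise ValueError("ON period must be positive")
    if h_off <= 0:
        return track
    i0 = track.departure_index()
    anchor = track.times[i0 if i0 is not None else 0]
    hours = track.days_since(anchor) * 24.0
    phase = hours % (h_on + h_off)
    return track.subset(np.nonzero(phase < h_on)[0])


def _thin_on_windows(track: Track, cfg: SimConfig, rng: np.random.Generator) -> Track:
    """Keep a few random acquisitions per ON window, emulating sparse Argos fixes."""
    h_on, h_off = cfg.duty_cycle
    k = cfg.fixes_per_on
    if k is None:
        k = max(1, round(h_on / 8.0))
    if h_off <= 0:
        return track
    i0 = track.departure_index()
    anchor = track.times[i0 if i0 is not None else 0]
    hours = track.days_since(anchor) * 24.0
    cycle = np.floor(hours / (h_on + h_off)).astype(int)
    keep: list[int] = []
    for c in np.unique(cycle):
        idx = np.nonzero(cycle == c)[0]
        if len(idx) <= k:
            keep.extend(idx.tolist())
        else:
            keep.extend(sorted(rng.choice(idx, size=k, replace=False).tolist()))
    return track.subset(np.asarray(sorted(keep), dtype=int))


def add_positional_noise(track: Track, sd_km: float | None, kind: str = "argos",
                         rng: np.random.Generator | None = None,
                         seed: int | None = None) -> Track:
    """Displace every fix by isotropic Gaussian noise; timestamps untouched.

    ``kind="gls"`` defaults the per-axis sd to the value whose radial error
    has a 180 km median; ``sd_km=0`` returns the track unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if sd_km is None:
        sd_km = GLS_NOISE_SD_KM if kind == "gls" else 5.0
    if sd_km < 0:
        raise ValueError("noise sd must be >= 0")
    if sd_km == 0 or track.n_fixes == 0:
        return track
    dx = rng.normal(0.0, sd_km, size=track.n_fixes)
    dy = rng.normal(0.0, sd_km, size=track.n_fixes)
    lat = track.lat + dy / 111.32
    lon = track.lon + dx / (111.32 * np.cos(np.radians(np.clip(track.lat, -89.0, 89.0))))
    return dc_replace(track, lon=normalize_lon(lon), lat=np.clip(lat, -90.0, 90.0))


def simulate_cohort(n_per_mode: int, seed: int = 0,
                    modes: Sequence[str] = SIM_MODES,
                    **overrides) -> tuple[list[Track], pd.DataFrame]:
    """Simulate ``n_per_mode`` tracks per phenotype with a truth table.

    Track ``j`` (1-based) of every mode runs with seed ``seed + j``; the
    three duty-cycle schedules rotate across individuals.  ``overrides``
    are forwarded to every :class:`SimConfig`.
    """
    if n_per_mode < 1:
        raise ValueError("n_per_mode must be >= 1")
    tracks, rows = [], []
    for mode in modes:
        for j in range(1, n_per_mode + 1):
            cfg = SimConfig(mode=mode, seed=seed + j,
                            duty_cycle=DUTY_CYCLES[(j - 1) % len(DUTY_CYCLES)],
                            individual_id=f"{_MODE_SPECIES[mode]}_{j:03d}",
                            **overrides)
            tr, truth = simulate_track(cfg)
            tracks.append(tr)
            rows.append(truth)
    return tracks, pd.DataFrame(rows)


# --- synthetic environmental rasters -----------------------------------------


def make_env_rasters(extent: tuple[float, float, float, float] = (0.0, 180.0, -70.0, -15.0),
                     cell_deg: float = 0.5, seed: int = 0,
                     shelf_center: GeoPoint | None = None,
                     shelf_width_km: float = 300.0,
                     shelf_length_km: float = 2500.0) -> dict[str, EnvRaster]:
    """Synthetic bathymetry / SST / CHLa climatology rasters.

    Bathymetry is a -4500 m basin with one shelf ridge rising to -200 m
    along an east-west arc (default centred where an eastbound half-migrant
    from Crozet settles, ~4000 km from the colony); SST falls linearly from
    25 degC at 20 S to -1 degC at 65 S with seeded noise; CHLa is a 0.1
    mg m-3 background with patches up to ~3 mg m-3 over the shelf.
    """
    if cell_deg <= 0:
        raise ValueError("cell size must be positive")
    lon_min, lon_max, lat_min, lat_max = extent
    rng = np.random.default_rng(seed)
    lon_ax = np.arange(lon_min + cell_deg / 2, lon_max, cell_deg)
    lat_ax = np.arange(lat_min + cell_deg / 2, lat_max, cell_deg)
    LON, LAT = np.meshgrid(lon_ax, lat_ax)
    if shelf_center is None:
        shelf_center = destination_point(CROZET, np.pi / 2, 4000.0)
    # distance to an east-west shelf segment through shelf_center
    dx = normalize_lon(LON - shelf_center.lon) * 111.32 * np.cos(np.radians(LAT))
    dy = (LAT - shelf_center.lat) * 111.32
    along = np.clip(np.abs(dx) - shelf_length_km / 2.0, 0.0, None)
    d_shelf = np.sqrt(along**2 + dy**2)
    ridge = 4300.0 * np.exp(-((d_shelf / shelf_width_km) ** 2))
    depth = -4500.0 + ridge
    sst = 25.0 + (LAT + 20.0) * (25.0 - (-1.0)) / (65.0 - 20.0) + rng.normal(0, 0.5, LON.shape)
    chla = 0.1 + 2.9 * np.exp(-((d_shelf / (0.5 * shelf_width_km)) ** 2)) \
        * np.clip(rng.normal(1.0, 0.2, LON.shape), 0.0, None)
    out = {}
    for name, vals in (("bathymetry_m", depth), ("sst_c", sst), ("chla_mg_m3", chla)):
        out[name] = EnvRaster(variable=name, lon=lon_ax, lat=lat_ax,
                              values=np.asarray(vals, dtype=float))
    return out
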