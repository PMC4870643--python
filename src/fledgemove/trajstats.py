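"""Per-track trajectory statistics over 15-day periods, and circular summaries.

For each individual the first three months at sea are cut into 15-day
blocks since departure; per block the path sinuosity (1 minus the
straightness index, 0 straight to 1 closed loop), the daily distance
travelled (DDT, km/day, transmitter-off gaps excluded) and the mean
latitude are computed.  Orientation is summarised with circular statistics:
departure bearing (great-circle, at the 100-km crossing), rhumb bearing of
the position at 2 and 3 months, mean direction, resultant length and the
Rayleigh uniformity test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config
from .geo import GeoPoint, haversine_km, initial_bearing, rhumb_bearing
from .tracks import Track

__all__ = ["PeriodStats", "CircularSummary", "partition_periods", "sinuosity",
           "daily_distance", "departure_bearing", "bearing_at_month",
           "circular_summary", "mean_latitude", "period_stats_table"]


@dataclass
class PeriodStats:
    """Aggregated trajectory metrics of one individual in one 15-day block."""

    individual_id: str
    species_code: str
    period_index: int  # 1-based 15-day block since departure
    n_fixes: int
    sinuosity: float | None  # in [0, 1]
    ddt_kmday: float | None
    mean_lat: float | None


@dataclass
class CircularSummary:
    """Circular statistics of a sample of angles (radians)."""

    n: int
    mean_direction: float  # radians in [0, 2*pi)
    resultant_length: float  # R in [0, 1]
    angular_range: float  # 2*pi minus the largest circular gap
    rayleigh_z: float  # n * R^2
    rayleigh_p: float


# --- period partitioning -----------------------------------------------------


def partition_periods(track: Track, length_days: float = config.PERIOD_LENGTH_DAYS,
                      n_periods: int = 6) -> list[Track | None]:
    """Split a track into consecutive half-open ``[k*L, (k+1)*L)`` day blocks
    since departure; a block with no fix yields ``None``."""
    rel = track.days_since_departure()
    if rel is None:
        raise ValueError(f"track {track.individual_id} has no departure")
    out: list[Track | None] = []
    for k in range(n_periods):
        sel = np.nonzero((rel >= k * length_days) & (rel < (k + 1) * length_days))[0]
        out.append(track.subset(sel) if len(sel) else None)
    return out


# --- per-segment metrics -----------------------------------------------------


def _step_distances(track: Track) -> np.ndarray:
    return np.atleast_1d(haversine_km(track.lon[:-1], track.lat[:-1],
                                      track.lon[1:], track.lat[1:]))


def sinuosity(segment: Track) -> float | None:
    """Path tortuosity: 1 - (beeline first-to-last) / (along-path length).

    0 for a straight constant-heading path, 1 for a closed loop; ``None``
    (undefined) for fewer than 3 fixes or zero path length.
    """
    if segment.n_fixes < 3:
        return None
    path = float(_step_distances(segment).sum())
    if path <= 0:
        return None
    beeline = haversine_km(segment.point(0), segment.point(-1))
    return float(np.clip(1.0 - beeline / path, 0.0, 1.0))


def daily_distance(segment: Track,
                   max_gap_hours: float = config.DDT_MAX_GAP_HOURS) -> float | None:
    """Daily distance travelled (km/day) excluding transmitter-off gaps.

    Step distances and durations are summed only over steps whose time gap
    is at most ``max_gap_hours`` (the longest ON-OFF duty cycle plus
    slack), then divided: gaps where the transmitter slept neither add
    distance nor time, so a constant-speed track keeps its true speed.
    ``None`` when no step qualifies.
    """
    if segment.n_fixes < 2:
        return None
    d = _step_distances(segment)
    gap_h = np.diff(segment.times).astype(float) / 3600.0
    ok = gap_h <= max_gap_hours
    if not np.any(ok) or gap_h[ok].sum() <= 0:
        return None
    return float(d[ok].sum() / (gap_h[ok].sum() / 24.0))


def departure_bearing(track: Track, colony: GeoPoint | None = None,
                      radius_km: float = config.DEPARTURE_BEARING_RADIUS_KM) -> float | None:
    """Great-circle bearing from the colony to the first fix >= ``radius_km`` away.

    ``None`` when the track never reaches the radius.
    """
    colony = colony if colony is not None else track.colony
    d = np.atleast_1d(haversine_km(np.full(track.n_fixes, colony.lon),
                                   np.full(track.n_fixes, colony.lat), track.lon, track.lat))
    far = np.nonzero(d >= radius_km)[0]
    if len(far) == 0:
        return None
    return initial_bearing(colony, track.point(int(far[0])))


def bearing_at_month(track: Track, colony: GeoPoint | None = None, month: int = 2,
                     tolerance_days: float = config.TIME_MATCH_TOLERANCE_DAYS) -> float | None:
    """Rhumb bearing from the colony to the position nearest ``30*month`` days.

    ``None`` when no fix falls within the tolerance window.
    """
    colony = colony if colony is not None else track.colony
    rel = track.days_since_departure()
    if rel is None:
        return None
    target = config.MONTH_LENGTH_DAYS * month
    dt = np.abs(rel - target)
    dt = np.where(np.isnan(dt), np.inf, dt)
    i = int(np.argmin(dt))
    if dt[i] > tolerance_days:
        return None
    return rhumb_bearing(colony, track.point(i))


def mean_latitude(track: Track, month: int = 3) -> float | None:
    """Arithmetic mean fix latitude in month ``m``: days [30(m-1), 30m) since departure."""
    rel = track.days_since_departure()
    if rel is None:
        return None
    lo = config.MONTH_LENGTH_DAYS * (month - 1)
    hi = config.MONTH_LENGTH_DAYS * month
    sel = (rel >= lo) & (rel < hi)
    if not np.any(sel):
        return None
    return float(np.mean(track.lat[sel]))


# --- circular statistics -----------------------------------------------------


def circular_summary(angles) -> CircularSummary:
    """Mean direction, resultant length, angular range and the Rayleigh test.

    The Rayleigh statistic is Z = n R^2 with the standard second-order
    series approximation of its p-value,
    ``p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``,
    clamped to [0, 1].  The angular range is 2*pi minus the largest gap
    between circularly sorted angles.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need at least 2 angles")
    n = len(a)
    C, S = np.cos(a).mean(), np.sin(a).mean()
    R = float(np.hypot(C, S))
    mean_dir = float(np.arctan2(S, C) % (2 * np.pi))
    srt = np.sort(a % (2 * np.pi))
    gaps = np.diff(np.concatenate([srt, [srt[0] + 2 * np.pi]]))
    angular_range = float(2 * np.pi - gaps.max())
    Z = n * R * R
    p = np.exp(-Z) * (1.0 + (2.0 * Z - Z * Z) / (4.0 * n)
                      - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n))
    return CircularSummary(n=n, mean_direction=mean_dir, resultant_length=R,
                           angular_range=angular_range, rayleigh_z=float(Z),
                           rayleigh_p=float(np.clip(p, 0.0, 1.0)))


# --- table builder -----------------------------------------------------------


def period_stats_table(tracks, length_days: float = config.PERIOD_LENGTH_DAYS,
                       n_periods: int = 6) -> pd.DataFrame:
    """One row per individual x 15-day period with sinuosity, DDT and mean latitude."""
    rows = []
    for tr in tracks:
        try:
            segments = partition_periods(tr, length_days, n_periods)
        except ValueError:
            continue
        for k, seg in enumerate(segments, start=1):
            if seg is None:
                rows.append(PeriodStats(tr.individual_id, tr.species_code, k, 0,
                                        None, None, None))
                continue
            rows.append(PeriodStats(
                tr.individual_id, tr.species_code, k, seg.n_fixes,
                sinuosity(seg), daily_distance(seg),
                float(np.mean(seg.lat)),
            ))
    return pd.DataFrame([vars(r) for r in rows])
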