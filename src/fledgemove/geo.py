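"""Spherical geometry primitives.

Great-circle distance (haversine), initial and rhumb (loxodrome) bearings,
net squared displacement (NSD) and range-at-time.  All positions are
geographic coordinates on a sphere of radius :data:`~fledgemove.config.EARTH_RADIUS_KM`;
bearings are radians clockwise from true north in ``[0, 2*pi)``.

Longitudes are normalized to ``[-180, 180)`` and every longitude difference
is taken on the shorter wrap, which keeps circumpolar tracks well behaved.
For model fitting on circumnavigating birds an *unwrapped* loxodromic
displacement is also provided (:func:`unwrapped_displacement_km`): there the
cumulative longitude is not reduced modulo 360, so displacement keeps
growing through a full lap instead of folding back.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .config import (
    DEPARTURE_RADIUS_KM,
    EARTH_RADIUS_KM,
    TIME_MATCH_TOLERANCE_DAYS,
)

if TYPE_CHECKING:  # pragma: no cover
    from .tracks import Track

__all__ = [
    "GeoPoint",
    "NSDSeries",
    "haversine_km",
    "initial_bearing",
    "rhumb_bearing",
    "rhumb_distance_km",
    "unwrapped_displacement_km",
    "destination_point",
    "compute_nsd",
    "range_at",
    "normalize_lon",
]

TWO_PI = 2.0 * np.pi


def normalize_lon(lon):
    """Normalize longitude(s) to the half-open interval [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _check_lat(lat) -> None:
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(~np.isfinite(lat)):
        raise ValueError(f"latitude outside [-90, 90]: {lat!r}")


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position: degrees east in [-180, 180), degrees north."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        _check_lat(self.lat)
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


@dataclass(frozen=True)
class NSDSeries:
    """Net squared displacement of one track from its origin.

    Attributes
    ----------
    t : ndarray
        Days since departure, non-negative and strictly increasing.
    nsd : ndarray
        Squared great-circle distance from ``origin``, km^2.
    origin : GeoPoint
        The natal colony (or other reference point).
    """

    t: np.ndarray
    nsd: np.ndarray
    origin: GeoPoint

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        nsd = np.asarray(self.nsd, dtype=float)
        if t.shape != nsd.shape or t.ndim != 1:
            raise ValueError("t and nsd must be 1-D arrays of equal length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("t must be non-negative and strictly increasing")
        if np.any(nsd < 0):
            raise ValueError("nsd must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "nsd", nsd)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_days(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


def haversine_km(a, b, lon2=None, lat2=None):
    """Great-circle distance in km between two points (or arrays of points).

    Accepts either two :class:`GeoPoint` objects, or four array-likes
    ``haversine_km(lon1, lat1, lon2, lat2)`` in degrees.
    """
    if lon2 is None:
        lon1, lat1, lon2, lat2 = a.lon, a.lat, b.lon, b.lat
    else:
        lon1, lat1 = a, b
    _check_lat(lat1)
    _check_lat(lat2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(normalize_lon(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float)))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Forward great-circle azimuth at ``a`` toward ``b``, radians in [0, 2*pi).

    Raises
    ------
    ValueError
        If the points coincide (bearing undefined).
    """
    if a.lon == b.lon and a.lat == b.lat:
        raise ValueError("bearing undefined for coincident points")
    p1, p2 = np.radians(a.lat), np.radians(b.lat)
    dlam = np.radians(normalize_lon(b.lon - a.lon))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return float(np.arctan2(y, x) % TWO_PI)


def _mercator_lat(lat_rad: np.ndarray) -> np.ndarray:
    return np.log(np.tan(np.pi / 4.0 + np.asarray(lat_rad) / 2.0))


def rhumb_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Constant-azimuth (loxodrome) bearing from ``a`` to ``b``.

    The longitude difference is taken on the shorter wrap; the latitude
    difference is stretched through the Mercator projection.
    """
    if a.lon == b.lon and a.lat == b.lat:
        raise ValueError("bearing undefined for coincident points")
    dpsi = _mercator_lat(np.radians(b.lat)) - _mercator_lat(np.radians(a.lat))
    dlam = np.radians(normalize_lon(b.lon - a.lon))
    return float(np.arctan2(dlam, dpsi) % TWO_PI)


def rhumb_distance_km(lon1, lat1, lon2, lat2, wrap: bool = True):
    """Loxodrome (rhumb-line) distance in km.

    With ``wrap=False`` the longitude difference is used as given, so values
    beyond +-180 degrees accumulate distance: this is the basis of
    :func:`unwrapped_displacement_km` for circumnavigating tracks.
    """
    _check_lat(lat1)
    _check_lat(lat2)
    p1, p2 = np.radians(np.asarray(lat1, dtype=float)), np.radians(np.asarray(lat2, dtype=float))
    dphi = p2 - p1
    dlam_deg = np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float)
    if wrap:
        dlam_deg = normalize_lon(dlam_deg)
    dlam = np.radians(dlam_deg)
    dpsi = _mercator_lat(p2) - _mercator_lat(p1)
    # stretch factor q = dphi/dpsi, limiting to cos(lat) on a parallel
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(np.abs(dpsi) > 1e-12, dphi / np.where(np.abs(dpsi) > 1e-12, dpsi, 1.0), np.cos(p1))
    d = EARTH_RADIUS_KM * np.sqrt(dphi**2 + (q * dlam) ** 2)
    return float(d) if np.ndim(d) == 0 else d


def destination_point(p: GeoPoint, bearing_rad: float, distance_km: float) -> GeoPoint:
    """Great-circle destination from ``p`` along ``bearing_rad`` for ``distance_km``."""
    delta = distance_km / EARTH_RADIUS_KM
    p1 = np.radians(p.lat)
    l1 = np.radians(p.lon)
    p2 = np.arcsin(
        np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(bearing_rad)
    )
    l2 = l1 + np.arctan2(
        np.sin(bearing_rad) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * np.sin(p2),
    )
    return GeoPoint(float(np.degrees(l2)), float(np.degrees(p2)))


# --- track-level displacement ------------------------------------------------


def compute_nsd(track: "Track", origin: GeoPoint | None = None,
                departure_radius_km: float = DEPARTURE_RADIUS_KM) -> NSDSeries:
    """Net squared displacement series of a track from its colony.

    NSD is the squared great-circle ("beeline") distance between the origin
    and each fix, in km^2.  Time is measured in fractional days from the
    first fix at least ``departure_radius_km`` from the origin (departure),
    excluding earlier colony-attendance fixes.

    Raises
    ------
    ValueError
        If the track is empty or never leaves the departure radius.
    """
    if track.n_fixes == 0:
        raise ValueError("empty track")
    origin = origin if origin is not None else track.colony
    d = haversine_km(np.full(track.n_fixes, origin.lon), np.full(track.n_fixes, origin.lat),
                     track.lon, track.lat)
    d = np.atleast_1d(d)
    dep = np.nonzero(d >= departure_radius_km)[0]
    if len(dep) == 0:
        raise ValueError("track never leaves the departure radius; no NSD series")
    i0 = int(dep[0])
    t = track.days_since(track.times[i0])[i0:]
    return NSDSeries(t=t, nsd=d[i0:] ** 2, origin=origin)


def unwrapped_displacement_km(track: "Track", origin: GeoPoint | None = None) -> np.ndarray:
    """Per-fix loxodromic displacement from the origin with *unwrapped* longitudes.

    The fix longitudes are unwrapped cumulatively along the track, so a bird
    that circumnavigates keeps accumulating eastward (or westward)
    displacement instead of folding back once past the antimeridian.  For
    tracks that never stray more than half a turn from the origin this is
    within a few percent of the great-circle distance.
    """
    origin = origin if origin is not None else track.colony
    lon_u = np.degrees(np.unwrap(np.radians(track.lon)))
    # re-anchor so the first fix keeps its shorter-wrap offset from origin
    lon_u += float(normalize_lon(track.lon[0] - origin.lon)) - (lon_u[0] - origin.lon)
    return np.atleast_1d(
        rhumb_distance_km(
            np.full(track.n_fixes, origin.lon), np.full(track.n_fixes, origin.lat),
            lon_u, track.lat, wrap=False,
        )
    )


def range_at(track: "Track", origin: GeoPoint | None = None, t_days: float = 90.0,
             tolerance_days: float = TIME_MATCH_TOLERANCE_DAYS,
             unwrap: bool = True) -> float | None:
    """Range (km) from the origin at the fix nearest ``t_days`` after departure.

    With ``unwrap=True`` (default) the range is the azimuthally unwrapped
    loxodromic displacement, which keeps accumulating through a full
    circumpolar lap instead of folding back past the antipode — this is how
    3-month ranges beyond the spherical beeline maximum arise for
    circumnavigating birds.  For tracks staying within half a turn of the
    origin it is within a few percent of the great-circle distance;
    ``unwrap=False`` gives the plain haversine beeline.

    Returns ``None`` (insufficient duration / no fix in the window) when no
    fix lies within ``tolerance_days`` of the requested time.  Ties between
    equally near fixes go to the earlier one.
    """
    origin = origin if origin is not None else track.colony
    series_t = track.days_since_departure()
    if series_t is None:
        return None
    dt = np.abs(series_t - t_days)
    dt = np.where(np.isnan(dt), np.inf, dt)
    i = int(np.argmin(dt))  # argmin takes the first (earlier) on ties
    if dt[i] > tolerance_days:
        return None
    if unwrap:
        return float(unwrapped_displacement_km(track, origin)[i])
    return float(haversine_km(GeoPoint(track.lon[i], track.lat[i]), origin))
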