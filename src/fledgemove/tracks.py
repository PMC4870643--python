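"""Track data model, file I/O, filtering, smoothing.

A :class:`Track` holds the timestamped fixes of one individual together
with its natal colony and age class.  Files are UTF-8 delimited text
(comma or tab, autodetected) with a header row and columns
``id, species, age_class, datetime, lon, lat[, lc]``; timestamps are
ISO-8601 and assumed UTC when unzoned.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .geo import GeoPoint, haversine_km, normalize_lon

logger = logging.getLogger(__name__)

__all__ = ["Track", "FilterReport", "read_tracks", "write_tracks",
           "speed_filter", "smooth_track", "sampling_rate"]

_REQUIRED_COLUMNS = ("id", "species", "age_class", "datetime", "lon", "lat")


@dataclass
class Track:
    """Timestamped lon/lat fixes of one individual."""

    individual_id: str
    species_code: str
    age_class: str  # "juvenile" | "adult"
    colony: GeoPoint
    times: np.ndarray  # datetime64[s], strictly increasing
    lon: np.ndarray  # degrees east, [-180, 180)
    lat: np.ndarray  # degrees north
    quality: np.ndarray | None = None  # optional Argos location-class codes
    source: str = "argos"  # "argos" | "gls" | "simulated"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.lon = normalize_lon(np.asarray(self.lon, dtype=float))
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.times) == len(self.lon) == len(self.lat)):
            raise ValueError("times, lon, lat must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times).astype(float) <= 0):
            raise ValueError(f"timestamps of {self.individual_id} not strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    @property
    def duration_days(self) -> float:
        if self.n_fixes < 2:
            return 0.0
        return float((self.times[-1] - self.times[0]).astype(float)) / 86400.0

    def days_since(self, t0: np.datetime64) -> np.ndarray:
        """Fractional days of every fix relative to ``t0``."""
        return (self.times - np.datetime64(t0, "s")).astype(float) / 86400.0

    def distances_from_colony(self) -> np.ndarray:
        n = self.n_fixes
        return np.atleast_1d(haversine_km(
            np.full(n, self.colony.lon), np.full(n, self.colony.lat), self.lon, self.lat))

    def departure_index(self, radius_km: float = config.DEPARTURE_RADIUS_KM) -> int | None:
        """Index of the first fix at least ``radius_km`` from the colony."""
        away = np.nonzero(self.distances_from_colony() >= radius_km)[0]
        return int(away[0]) if len(away) else None

    def days_since_departure(self) -> np.ndarray | None:
        """Fractional days of each fix since departure (NaN before departure)."""
        i0 = self.departure_index()
        if i0 is None:
            return None
        d = self.days_since(self.times[i0])
        d[:i0] = np.nan
        return d

    def point(self, i: int) -> GeoPoint:
        return GeoPoint(float(self.lon[i]), float(self.lat[i]))

    def subset(self, index: np.ndarray) -> "Track":
        q = self.quality[index] if self.quality is not None else None
        return replace(self, times=self.times[index], lon=self.lon[index],
                       lat=self.lat[index], quality=q)


@dataclass
class FilterReport:
    """Bookkeeping of fixes dropped during cleaning; counts are conserved."""

    n_input: int = 0
    n_removed_parse: int = 0
    n_removed_duplicate: int = 0
    n_removed_speed: int = 0

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed_parse - self.n_removed_duplicate - self.n_removed_speed

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.n_input + other.n_input,
            self.n_removed_parse + other.n_removed_parse,
            self.n_removed_duplicate + other.n_removed_duplicate,
            self.n_removed_speed + other.n_removed_speed,
        )

    def to_json(self) -> str:
        return json.dumps({
            "n_input": self.n_input, "n_removed_parse": self.n_removed_parse,
            "n_removed_duplicate": self.n_removed_duplicate,
            "n_removed_speed": self.n_removed_speed, "n_output": self.n_output,
        })


# --- reading / writing -------------------------------------------------------


def read_tracks(path, colonies: Mapping[str, GeoPoint] | GeoPoint | None = None,
                source: str = "argos") -> tuple[list[Track], FilterReport]:
    """Read a delimited track table into one :class:`Track` per individual.

    Parameters
    ----------
    path
        Delimited text file (comma or tab autodetected) with header columns
        ``id, species, age_class, datetime, lon, lat[, lc]``.
    colonies
        Either a single :class:`GeoPoint` used for every individual, or a
        mapping from individual id (falling back to species code) to colony.
        When absent, each track's first fix stands in for its colony.

    Returns
    -------
    (tracks, report)
        Rows with unparseable coordinates or timestamps are dropped and
        counted; duplicated timestamps within an individual keep the first
        occurrence.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    report = FilterReport(n_input=len(df))
    if len(df) == 0:
        logger.warning("%s: empty track file", path)
        return [], report

    times = pd.to_datetime(df["datetime"], errors="coerce", utc=True, format="ISO8601")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = times.notna() & lon.notna() & lat.notna() & lat.abs().le(90)
    report.n_removed_parse = int((~ok).sum())
    df = df.loc[ok].assign(_t=times[ok].dt.tz_localize(None), _lon=lon[ok], _lat=lat[ok])

    tracks: list[Track] = []
    for ind_id, g in df.groupby("id", sort=True):
        g = g.sort_values("_t", kind="stable")
        dup = g["_t"].duplicated(keep="first")
        report.n_removed_duplicate += int(dup.sum())
        g = g.loc[~dup]
        if len(g) < 2:
            logger.warning("individual %s: fewer than 2 usable fixes, skipped", ind_id)
            report.n_removed_parse += len(g)
            continue
        first = GeoPoint(float(g["_lon"].iloc[0]), float(g["_lat"].iloc[0]))
        if isinstance(colonies, GeoPoint):
            colony = colonies
        elif colonies is not None:
            colony = colonies.get(str(ind_id)) or colonies.get(str(g["species"].iloc[0]), first)
        else:
            colony = first
        tracks.append(Track(
            individual_id=str(ind_id),
            species_code=str(g["species"].iloc[0]),
            age_class=str(g["age_class"].iloc[0]),
            colony=colony,
            times=g["_t"].to_numpy(dtype="datetime64[s]"),
            lon=g["_lon"].to_numpy(dtype=float),
            lat=g["_lat"].to_numpy(dtype=float),
            quality=g["lc"].to_numpy() if "lc" in g.columns else None,
            source=source,
        ))
    logger.info("%s: read %d tracks (%s)", path, len(tracks), report.to_json())
    return tracks, report


def write_tracks(tracks: Iterable[Track], path, sep: str = ",") -> None:
    """Write tracks in the same dialect :func:`read_tracks` reads."""
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "id": tr.individual_id, "species": tr.species_code,
            "age_class": tr.age_class,
            "datetime": np.datetime_as_string(tr.times, unit="s"),
            "lon": tr.lon, "lat": tr.lat,
            "lc": tr.quality if tr.quality is not None else "",
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["id", "species", "age_class", "datetime", "lon", "lat", "lc"])
    out.to_csv(path, sep=sep, index=False)


# --- cleaning ----------------------------------------------------------------


def _segment_speeds(track: Track) -> np.ndarray:
    """Ground speed (km/h) of each step between consecutive fixes."""
    d = haversine_km(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    dt_h = np.diff(track.times).astype(float) / 3600.0
    return np.atleast_1d(d) / dt_h


def speed_filter(track: Track, vmax_kmh: float = config.SPEED_FILTER_VMAX_KMH
                 ) -> tuple[Track, FilterReport]:
    """Iteratively remove fixes implying ground speeds above ``vmax_kmh``.

    At each pass the fix with the largest mean speed to its neighbours among
    those adjacent to an over-speed step is removed (ties go to the earlier
    fix), until no step exceeds the ceiling.  Deterministic and idempotent.

    Raises
    ------
    ValueError
        If fewer than 2 fixes would survive.
    """
    if vmax_kmh <= 0:
        raise ValueError("vmax must be positive")
    report = FilterReport(n_input=track.n_fixes)
    current = track
    while current.n_fixes >= 2:
        v = _segment_speeds(current)
        if np.all(v <= vmax_kmh):
            break
        # score each fix by the mean speed of its adjacent steps
        score = np.zeros(current.n_fixes)
        score[0] = v[0]
        score[-1] = v[-1]
        if current.n_fixes > 2:
            score[1:-1] = 0.5 * (v[:-1] + v[1:])
        worst = int(np.argmax(score))
        keep = np.ones(current.n_fixes, dtype=bool)
        keep[worst] = False
        current = current.subset(keep)
        report.n_removed_speed += 1
    if current.n_fixes < 2:
        raise ValueError(f"speed filter removed all fixes of {track.individual_id}")
    return current, report


def smooth_track(track: Track, window_days: float = config.GLS_SMOOTHING_WINDOW_DAYS) -> Track:
    """Average fixes over non-overlapping windows of ``window_days``.

    Used to tame coarse geolocator (GLS) positions.  Each non-empty window
    emits one fix at the arithmetic mean position (longitudes unwrapped
    about the window's first fix, so the antimeridian is safe) timestamped
    at the window centre.
    """
    if window_days <= 0:
        raise ValueError("window must be positive")
    if track.n_fixes == 0:
        return track
    rel = track.days_since(track.times[0])
    bins = np.floor(rel / window_days).astype(int)
    out_t, out_lon, out_lat = [], [], []
    for b in np.unique(bins):
        sel = bins == b
        lon_w = np.radians(track.lon[sel])
        lon_u = np.degrees(np.unwrap(lon_w))
        out_lon.append(normalize_lon(np.mean(lon_u)))
        out_lat.append(np.mean(track.lat[sel]))
        centre = track.times[0] + np.timedelta64(int((b + 0.5) * window_days * 86400), "s")
        out_t.append(centre)
    return replace(track, times=np.array(out_t, dtype="datetime64[s]"),
                   lon=np.array(out_lon, dtype=float), lat=np.array(out_lat, dtype=float),
                   quality=None)


def sampling_rate(track: Track) -> float | None:
    """Locations per day, ``n_fixes / duration``; ``None`` if duration is zero."""
    dur = track.duration_days
    if dur <= 0:
        return None
    return track.n_fixes / dur
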