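"""Environmental annotation: raster lookup and neritic/oceanic habitat classes.

Fixes are annotated by nearest-cell lookup from gridded bathymetry (m,
negative below sea level), sea-surface temperature (degC) and chlorophyll-a
(mg m-3) rasters; the habitat rule is the -3000 m step: water shallower
than 3000 m (lower continental slope to shelf) is *neritic*, anything at or
below -3000 m *oceanic*.  Rasters are regular lon/lat grids read and
written as plain ESRI ASCII grid files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NERITIC_DEPTH_THRESHOLD_M, PERIOD_LENGTH_DAYS
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = ["EnvRaster", "read_ascii_grid", "classify_habitat",
           "annotate_track", "settlement_habitat"]

VARIABLES = ("bathymetry_m", "sst_c", "chla_mg_m3")


@dataclass
class EnvRaster:
    """A regular lon/lat grid of one environmental variable.

    ``values[i, j]`` sits at ``(lat[i], lon[j])``; axes are cell centres in
    ascending order with constant spacing.
    """

    variable: str
    lon: np.ndarray  # cell-centre longitudes, ascending
    lat: np.ndarray  # cell-centre latitudes, ascending
    values: np.ndarray  # shape (len(lat), len(lon))
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values shape must be (n_lat, n_lon)")

    @property
    def cell_deg(self) -> float:
        return float(self.lon[1] - self.lon[0]) if len(self.lon) > 1 else 1.0

    def value_at(self, lon, lat):
        """Nearest-cell values; NaN outside the grid extent or at nodata cells."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        half = self.cell_deg / 2.0
        j = np.clip(np.searchsorted(self.lon, lon), 1, len(self.lon) - 1)
        j = np.where(np.abs(self.lon[j] - lon) < np.abs(self.lon[j - 1] - lon), j, j - 1)
        i = np.clip(np.searchsorted(self.lat, lat), 1, len(self.lat) - 1)
        i = np.where(np.abs(self.lat[i] - lat) < np.abs(self.lat[i - 1] - lat), i, i - 1)
        out = self.values[i, j].astype(float)
        outside = ((lon < self.lon[0] - half) | (lon > self.lon[-1] + half)
                   | (lat < self.lat[0] - half) | (lat > self.lat[-1] + half))
        out = np.where(outside | (out == self.nodata), np.nan, out)
        return float(out) if out.ndim == 0 else out

    # ESRI ASCII grid I/O (plain text; rows run north to south)
    def write_ascii(self, path) -> None:
        half = self.cell_deg / 2.0
        header = (f"ncols {len(self.lon)}\nnrows {len(self.lat)}\n"
                  f"xllcorner {self.lon[0] - half:.6f}\nyllcorner {self.lat[0] - half:.6f}\n"
                  f"cellsize {self.cell_deg:.6f}\nNODATA_value {self.nodata:g}\n")
        body = np.where(np.isnan(self.values), self.nodata, self.values)[::-1]
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.4f")


def read_ascii_grid(path, variable: str | None = None) -> EnvRaster:
    """Read an ESRI ASCII grid file into an :class:`EnvRaster`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    body = np.atleast_2d(body)
    if body.shape != (nrows, ncols):
        raise ValueError(f"{path}: grid body {body.shape} != header ({nrows}, {ncols})")
    lon = header["xllcorner"] + cell * (np.arange(ncols) + 0.5)
    lat = header["yllcorner"] + cell * (np.arange(nrows) + 0.5)
    values = body[::-1]  # file rows are north->south
    values = np.where(values == nodata, np.nan, values)
    return EnvRaster(variable=variable or path.stem, lon=lon, lat=lat,
                     values=values, nodata=nodata)


def classify_habitat(depth_m: float) -> str:
    """Neritic (depth > -3000 m) vs oceanic (depth <= -3000 m) for ocean cells.

    Raises
    ------
    ValueError
        For positive depth (land).
    """
    if depth_m > 0:
        raise ValueError(f"depth {depth_m} m is above sea level (land)")
    return "neritic" if depth_m > NERITIC_DEPTH_THRESHOLD_M else "oceanic"


def annotate_track(track: Track, rasters: dict[str, EnvRaster]) -> pd.DataFrame:
    """Per-fix environmental values by nearest-cell lookup.

    Returns one row per fix with a column per raster variable plus a
    ``<var>_missing`` reason column (``out_of_extent``, ``land`` for
    positive bathymetry, or empty).  A requested variable with no raster
    raises a configuration error.
    """
    if not rasters:
        raise ValueError("no rasters configured")
    out = pd.DataFrame({
        "individual_id": track.individual_id,
        "datetime": track.times, "lon": track.lon, "lat": track.lat,
    })
    for name, ras in rasters.items():
        vals = np.atleast_1d(ras.value_at(track.lon, track.lat))
        reason = np.where(np.isnan(vals), "out_of_extent", "")
        if name == "bathymetry_m":
            land = ~np.isnan(vals) & (vals > 0)
            reason = np.where(land, "land", reason)
            vals = np.where(land, np.nan, vals)
        out[name] = vals
        out[f"{name}_missing"] = reason
    return out


def settlement_habitat(track: Track, rasters: dict[str, EnvRaster],
                       window_days: float = PERIOD_LENGTH_DAYS
                       ) -> tuple[str | None, float | None]:
    """Habitat class of the final ``window_days`` of a track.

    Classifies every last-window fix from bathymetry and returns the
    majority class (ties go to neritic, the shallower class) with its
    fraction, or ``(None, None)`` when no fix has usable bathymetry.
    """
    if "bathymetry_m" not in rasters:
        raise ValueError("settlement habitat requires a bathymetry raster")
    end = track.times[-1]
    rel = (end - track.times).astype(float) / 86400.0
    sub = track.subset(np.nonzero(rel <= window_days)[0])
    depths = np.atleast_1d(rasters["bathymetry_m"].value_at(sub.lon, sub.lat))
    depths = depths[~np.isnan(depths) & (depths <= 0)]
    if len(depths) == 0:
        return None, None
    frac_neritic = float(np.mean(depths > NERITIC_DEPTH_THRESHOLD_M))
    if frac_neritic >= 0.5:
        return "neritic", frac_neritic
    return "oceanic", 1.0 - frac_neritic
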