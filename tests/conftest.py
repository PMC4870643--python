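"""Shared fixtures: track factories and small simulated cohorts."""
from __future__ import annotations

import numpy as np
import pytest

from fledgemove.geo import GeoPoint, destination_point
from fledgemove.tracks import Track

COLONY = GeoPoint(52.4, -46.2)  # Crozet


@pytest.fixture
def make_track():
    """Factory: build a Track from (hours, lon, lat) arrays."""

    def _make(lon, lat, hours=None, colony=COLONY, individual_id="t1",
              species="TST", age_class="juvenile", source="simulated"):
        lon = np.asarray(lon, dtype=float)
        if hours is None:
            hours = np.arange(len(lon), dtype=float)
        times = (np.datetime64("2014-01-10T00:00:00", "s")
                 + (np.asarray(hours) * 3600).astype("timedelta64[s]"))
        return Track(individual_id=individual_id, species_code=species,
                     age_class=age_class, colony=colony, times=times,
                     lon=lon, lat=np.asarray(lat, dtype=float), source=source)

    return _make


@pytest.fixture
def straight_track(make_track):
    """Factory: constant-heading constant-speed track from the colony."""

    def _make(bearing_rad=0.0, speed_kmday=100.0, duration_days=90.0,
              fixes_per_day=24, colony=COLONY, **kw):
        n = int(duration_days * fixes_per_day) + 1
        hours = np.arange(n) * (24.0 / fixes_per_day)
        dists = speed_kmday * hours / 24.0
        lon = np.empty(n)
        lat = np.empty(n)
        for i, d in enumerate(dists):
            p = destination_point(colony, bearing_rad, float(d))
            lon[i], lat[i] = p.lon, p.lat
        return make_track(lon, lat, hours=hours, colony=colony, **kw)

    return _make
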