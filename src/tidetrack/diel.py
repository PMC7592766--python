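"""Sunrise/sunset computation and day/night/crepuscular labelling.

Solar events come from the NOAA solar-position equations (zenith 90.833
degrees, i.e. official sunrise/sunset with standard refraction), evaluated
in UTC.  A configurable buffer (default one hour) is applied inward of both
events so that crepuscular samples are excluded from day/night statistics.
The night belongs to the evening's civil day: sunset of day d pairs with
sunrise of day d+1, keeping each 24-h classification cycle self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

SUNRISE_SUNSET_ZENITH = 90.833  # degrees; geometric horizon + refraction


def _noaa_solar_minutes(d: date, lat: float, lon: float,
                        zenith: float = SUNRISE_SUNSET_ZENITH,
                        ) -> Optional[tuple[float, float]]:
    """(sunrise, sunset) in minutes after 00:00 UTC, or None on polar days.

    NOAA (Meeus-based) low-precision ephemeris evaluated at solar noon of
    the civil day; accuracy is well under a minute at temperate latitudes.
    """
    jd = d.toordinal() + 1721424.5 + 0.5  # noon UTC
    jc = (jd - 2451545.0) / 36525.0

    gml = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    gma_r = math.radians(gma)
    eq_center = (math.sin(gma_r) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
                 + math.sin(2 * gma_r) * (0.019993 - 0.000101 * jc)
                 + math.sin(3 * gma_r) * 0.000289)
    true_long = gml + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059
                 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    obliq_r = math.radians(obliq)
    app_long_r = math.radians(app_long)
    declination = math.asin(math.sin(obliq_r) * math.sin(app_long_r))

    var_y = math.tan(obliq_r / 2.0) ** 2
    gml_r = math.radians(gml)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * gml_r)
        - 2.0 * ecc * math.sin(gma_r)
        + 4.0 * ecc * var_y * math.sin(gma_r) * math.cos(2 * gml_r)
        - 0.5 * var_y ** 2 * math.sin(4 * gml_r)
        - 1.25 * ecc ** 2 * math.sin(2 * gma_r))

    lat_r = math.radians(lat)
    cos_ha = (math.cos(math.radians(zenith)) / (math.cos(lat_r)
              * math.cos(declination)) - math.tan(lat_r) * math.tan(declination))
    if not -1.0 <= cos_ha <= 1.0:
        return None  # polar day or polar night
    ha_deg = math.degrees(math.acos(cos_ha))
    solar_noon = 720.0 - 4.0 * lon - eq_time
    return solar_noon - 4.0 * ha_deg, solar_noon + 4.0 * ha_deg


def solar_events(d: date, lat: float, lon: float,
                 zenith: float = SUNRISE_SUNSET_ZENITH,
                 ) -> Optional[tuple[pd.Timestamp, pd.Timestamp]]:
    """UTC sunrise and sunset for a civil day, or None on polar day/night."""
    if not -90.0 <= lat <= 90.0:
        raise ValueError("latitude out of range")
    mins = _noaa_solar_minutes(d, lat, lon, zenith)
    if mins is None:
        return None
    midnight = pd.Timestamp(d, tz="UTC")
    return (midnight + pd.Timedelta(minutes=mins[0]),
            midnight + pd.Timedelta(minutes=mins[1]))


@dataclass
class DielWindow:
    """Buffered day and night intervals for one 24-h cycle.

    ``day_interval`` is ``[sunrise + buffer, sunset - buffer)``;
    ``night_interval`` is ``[sunset + buffer, next sunrise - buffer)``, the
    next sunrise computed at the same position.  Either interval may be
    empty when the buffered bounds cross; ``usable`` is False on days with
    no solar events (polar day/night).
    """

    date: date
    sunrise: Optional[pd.Timestamp]
    sunset: Optional[pd.Timestamp]
    day_interval: Optional[tuple[pd.Timestamp, pd.Timestamp]]
    night_interval: Optional[tuple[pd.Timestamp, pd.Timestamp]]
    buffer: pd.Timedelta

    @property
    def usable(self) -> bool:
        return self.sunrise is not None


def diel_windows(d: date, lat: float, lon: float,
                 buffer_h: float = 1.0) -> DielWindow:
    """Compute the buffered day and night intervals for one civil day."""
    buf = pd.Timedelta(hours=buffer_h)
    events = solar_events(d, lat, lon)
    next_events = solar_events(d + timedelta(days=1), lat, lon)
    if events is None or next_events is None:
        return DielWindow(d, None, None, None, None, buf)
    sunrise, sunset = events
    next_sunrise = next_events[0]
    day_iv = (sunrise + buf, sunset - buf)
    night_iv = (sunset + buf, next_sunrise - buf)
    if day_iv[0] >= day_iv[1]:
        day_iv = None
    if night_iv[0] >= night_iv[1]:
        night_iv = None
    return DielWindow(d, sunrise, sunset, day_iv, night_iv, buf)


def label_samples(samples: pd.DataFrame, positions: pd.DataFrame,
                  buffer_h: float = 1.0) -> pd.DataFrame:
    """Label each sample day / night / crepuscular / unusable.

    ``samples`` needs a tz-aware ``timestamp`` column; ``positions`` maps
    civil dates to (lat, lon) — the geolocated daily position when
    available, otherwise the release position.  The returned copy gains
    ``diel_label`` and ``cycle_date`` columns; night samples carry the
    evening's civil date as their cycle.  Samples on days with no position
    or no solar events are ``unusable``.
    """
    ts = samples["timestamp"]
    pos = {pd.Timestamp(r["date"]).date(): (float(r["lat"]), float(r["lon"]))
           for _, r in positions.iterrows()}

    out = samples.copy()
    label = np.full(len(out), "unusable", dtype=object)
    own_date = ts.dt.date
    cycle = np.array(own_date, dtype=object)

    days = sorted(set(own_date))
    # include the previous day so pre-dawn samples can join its night cycle
    for d in sorted(set(days) | {d - timedelta(days=1) for d in days}):
        if d not in pos:
            continue
        lat, lon = pos[d]
        win = diel_windows(d, lat, lon, buffer_h)
        if not win.usable:
            continue
        if win.day_interval is not None:
            lo, hi = win.day_interval
            m = (ts >= lo) & (ts < hi)
            label[m] = "day"
            cycle[m] = d
        if win.night_interval is not None:
            lo, hi = win.night_interval
            m = ((ts >= lo) & (ts < hi)).to_numpy() & (label == "unusable")
            label[m] = "night"
            cycle[m] = d
    # remaining samples on usable days are crepuscular
    for d in days:
        if d not in pos:
            continue
        if solar_events(d, *pos[d]) is None:
            continue
        m = (own_date == d).to_numpy() & (label == "unusable")
        label[m] = "crepuscular"
    out["diel_label"] = label
    out["cycle_date"] = cycle
    return out
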