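"""Mark-recapture dispersal statistics and track distances.

Displacement is the great-circle ("straight-line") distance between release
and recapture positions — a minimum bound on the distance actually swum.
Distances use the haversine formula on a sphere of radius 6371.0088 km;
the ellipsoidal error is below 0.5 % at shelf-sea scales.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .dst_io import TagDeployment

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    s = (math.sin((lat2 - lat1) / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def make_dispersal_records(deployments: Iterable[TagDeployment],
                           ) -> tuple[pd.DataFrame, int]:
    """One row per recaptured tag: distance, days at liberty, sex, condition.

    Returns the records plus the count of returned tags excluded for
    missing recapture position or date.
    """
    rows, excluded = [], 0
    for d in deployments:
        if d.recapture is None:
            continue
        rlat, rlon, _ = d.release
        clat, clon, _ = d.recapture
        if any(v is None for v in (clat, clon)):
            excluded += 1
            continue
        rows.append({
            "tag_id": d.tag_id,
            "distance_km": great_circle_km((rlat, rlon), (clat, clon)),
            "days_at_liberty": d.days_at_liberty,
            "sex": d.sex,
            "condition": d.condition,
            "release_lat": rlat, "release_lon": rlon,
            "recapture_lat": clat, "recapture_lon": clon,
        })
    cols = ["tag_id", "distance_km", "days_at_liberty", "sex", "condition",
            "release_lat", "release_lon", "recapture_lat", "recapture_lon"]
    return pd.DataFrame(rows, columns=cols), excluded


def recapture_summary(records: pd.DataFrame, group_by: str = "none",
                      ) -> pd.DataFrame:
    """Grouped displacement summary: n, mean/sd/min/max distance (km) and
    mean days at liberty.

    ``group_by`` is ``"none"``, ``"sex"`` or ``"condition"``.  The sd uses
    the n-1 denominator; single-record groups report sd 0 with
    ``sd_defined`` False.  Empty groups are simply absent.
    """
    if group_by not in ("none", "sex", "condition"):
        raise ValueError(f"unknown grouping {group_by!r}")
    if group_by == "none":
        groups = [("all", records)]
    else:
        groups = list(records.groupby(group_by))
    rows = []
    for key, g in groups:
        if g.empty:
            continue
        sd = float(g["distance_km"].std(ddof=1))
        rows.append({
            "group": key,
            "n": int(len(g)),
            "mean_km": float(g["distance_km"].mean()),
            "sd_km": 0.0 if math.isnan(sd) else sd,
            "sd_defined": len(g) > 1,
            "min_km": float(g["distance_km"].min()),
            "max_km": float(g["distance_km"].max()),
            "mean_days": float(g["days_at_liberty"].mean()),
        })
    return pd.DataFrame(rows)


def return_rate(n_returned: int, n_released: int) -> float:
    """Percent of released tags returned, rounded half-up to one decimal."""
    if n_released <= 0:
        raise ValueError("n_released must be > 0")
    if n_returned > n_released:
        raise ValueError("n_returned exceeds n_released")
    pct = Decimal(100 * n_returned) / Decimal(n_released)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def count_releases(deployments: Iterable[TagDeployment]) -> dict[str, int]:
    """Release counts by tag class, plus a ``total``."""
    counts: dict[str, int] = {}
    for d in deployments:
        counts[d.tag_class] = counts.get(d.tag_class, 0) + 1
    counts["total"] = sum(counts.values())
    return counts


def daily_distances(track: pd.DataFrame) -> pd.Series:
    """km/day between successive daily positions of a geolocated track.

    ``track`` needs ``date``, ``lat``, ``lon`` columns, one row per day.
    Intervals spanning a gap of more than one day yield NaN (no
    interpolation); a track of n positions yields n - 1 values.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 positions")
    t = track.reset_index(drop=True)
    out = []
    for i in range(1, len(t)):
        gap = (pd.Timestamp(t.loc[i, "date"]) - pd.Timestamp(t.loc[i - 1, "date"])).days
        if gap == 1:
            out.append(great_circle_km((t.loc[i - 1, "lat"], t.loc[i - 1, "lon"]),
                                       (t.loc[i, "lat"], t.loc[i, "lon"])))
        else:
            out.append(float("nan"))
    return pd.Series(out, name="km_per_day")
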