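"""Reading, validation and conditioning of data-storage-tag (DST) records.

A DST logs depth and temperature internally at a fixed cadence; the record
is recovered only when the tag is physically returned.  Before analysis the
raw series is down-sampled to a common resolution and any trailing days when
the detached tag floated at the surface are removed.  Depth samples at or
above the pressure-sensor ceiling are flagged censored: they are lower
bounds on true depth, not measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["timestamp", "depth", "temperature", "censored"]

#: column aliases accepted on read
_ALIASES = {"depth_m": "depth", "temp_c": "temperature", "temperature_c": "temperature"}


class SeriesValidationError(ValueError):
    """Raised when a DST file or series violates its invariants."""


@dataclass
class DepthTempSeries:
    """A single tag's timestamped depth/temperature record.

    ``samples`` holds columns ``timestamp`` (tz-aware UTC, strictly
    increasing), ``depth`` (m, positive-down, >= 0), ``temperature`` (degC,
    may be NaN) and ``censored`` (bool; depth at the sensor ceiling).
    Nominal intervals are the modal sample spacings in seconds.
    """

    tag_id: str
    samples: pd.DataFrame
    nominal_depth_interval: float
    nominal_temp_interval: float

    def __post_init__(self) -> None:
        df = self.samples
        missing = set(SAMPLE_COLUMNS) - set(df.columns)
        if missing:
            raise SeriesValidationError(f"samples missing columns {sorted(missing)}")
        if len(df):
            ts = df["timestamp"]
            if ts.dt.tz is None:
                raise SeriesValidationError("timestamps must be tz-aware UTC")
            if not ts.is_monotonic_increasing or ts.duplicated().any():
                raise SeriesValidationError("timestamps must be strictly increasing")
            if (df["depth"] < 0).any():
                raise SeriesValidationError("depth must be >= 0 (positive-down)")
        self.samples = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def dates(self) -> pd.Series:
        """Civil (UTC) date of each sample."""
        return self.samples["timestamp"].dt.date

    def day_groups(self):
        return self.samples.groupby(self.dates, sort=True)


@dataclass
class TagDeployment:
    """Release/recapture metadata for one tagged fish."""

    tag_id: str
    tag_class: str  # "mark-recapture" | "electronic"
    length_cm: float
    sex: str = "unknown"  # "F" | "M" | "unknown"
    weight_g: Optional[float] = None
    maturity: Optional[str] = None
    condition: str = "unknown"  # "lively" | "sluggish" | "unknown"
    release: tuple[float, float, date] = None  # (lat, lon, date)
    recapture: Optional[tuple[float, float, date]] = None

    def __post_init__(self) -> None:
        if self.tag_class not in ("mark-recapture", "electronic"):
            raise ValueError(f"unknown tag class {self.tag_class!r}")
        if self.release is None:
            raise ValueError("release position/date required")
        for pos in (self.release, self.recapture):
            if pos is None:
                continue
            lat, lon, _ = pos
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"coordinates out of range: {lat}, {lon}")
        if self.recapture is not None and self.recapture[2] < self.release[2]:
            raise ValueError("recapture date precedes release date")

    @property
    def days_at_liberty(self) -> Optional[int]:
        if self.recapture is None:
            return None
        return (self.recapture[2] - self.release[2]).days


def _modal_gap_seconds(ts: pd.Series) -> float:
    gaps = ts.diff().dropna().dt.total_seconds()
    if gaps.empty:
        return float("nan")
    return float(gaps.mode().iloc[0])


def read_dst_csv(path: str | Path, sensor_ceiling: Optional[float] = None,
                 tag_id: Optional[str] = None) -> DepthTempSeries:
    """Parse a per-tag CSV (timestamp, depth, temperature) into a series.

    Timestamps must be ISO-8601 and are interpreted as UTC.  ``sensor_ceiling``
    (m) marks samples with ``depth >= ceiling`` as censored.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.rename(columns={k: v for k, v in _ALIASES.items() if k in df.columns})
    required = {"timestamp", "depth", "temperature"}
    if missing := required - set(df.columns):
        raise SeriesValidationError(f"{path.name}: missing columns {sorted(missing)}")
    if df.empty:
        raise SeriesValidationError(f"{path.name}: empty file")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax()) + 2  # 1-based, plus header line
        raise SeriesValidationError(f"{path.name}: unparseable timestamp at line {row}")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise SeriesValidationError(f"{path.name}: timestamps not strictly increasing")
    depth = df["depth"].astype(float)
    temp = df["temperature"].astype(float)
    censored = (depth >= sensor_ceiling) if sensor_ceiling is not None \
        else pd.Series(False, index=df.index)
    samples = pd.DataFrame({"timestamp": ts, "depth": depth,
                            "temperature": temp, "censored": censored})
    return DepthTempSeries(
        tag_id=tag_id or path.stem,
        samples=samples,
        nominal_depth_interval=_modal_gap_seconds(ts),
        nominal_temp_interval=_modal_gap_seconds(ts[temp.notna()]),
    )


def write_series_csv(series: DepthTempSeries, path: str | Path) -> None:
    """Write a conditioned series with added ``censored`` and ``day_index`` columns."""
    df = series.samples.copy()
    first_day = df["timestamp"].dt.normalize().iloc[0] if len(df) else None
    df["day_index"] = ((df["timestamp"].dt.normalize() - first_day).dt.days
                       if len(df) else pd.Series(dtype=int))
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    df.to_csv(path, index=False)


def downsample_series(series: DepthTempSeries, resolution: float = 600.0) -> DepthTempSeries:
    """Down-sample to ``resolution`` seconds by keeping the first sample at or
    after each midnight-aligned bin boundary.  No interpolation or averaging;
    empty bins are simply absent.  A 24-h record at 10-minute resolution
    therefore carries 144 samples.
    """
    if resolution < series.nominal_depth_interval:
        raise ValueError(
            f"resolution {resolution}s finer than nominal interval "
            f"{series.nominal_depth_interval}s")
    df = series.samples
    ts = df["timestamp"]
    day = ts.dt.normalize()
    second_of_day = (ts - day).dt.total_seconds()
    bin_idx = np.floor(second_of_day / resolution).astype(int)
    keep = df.groupby([day, bin_idx], sort=True).head(1)
    return replace(series, samples=keep.reset_index(drop=True),
                   nominal_depth_interval=float(resolution))


def _floating_days(series: DepthTempSeries, surface_depth: float,
                   min_frac: float, max_daily_sd: float) -> pd.Series:
    def is_floating(g: pd.DataFrame) -> bool:
        frac = (g["depth"] <= surface_depth).mean()
        # the max-depth guard keeps any day with a genuine dive out of the trim
        return bool(frac >= min_frac
                    and g["depth"].std(ddof=0) <= max_daily_sd
                    and g["depth"].max() <= surface_depth + 3 * max_daily_sd)
    return series.day_groups().apply(is_floating, include_groups=False)


def trim_surface_drift(series: DepthTempSeries, surface_depth: float = 1.0,
                       min_frac: float = 0.95,
                       max_daily_sd: float = 0.25) -> DepthTempSeries:
    """Remove the maximal trailing run of days when the tag floated at the surface.

    A civil day is "floating" iff at least ``min_frac`` of its samples are at
    ``depth <= surface_depth`` and its depth standard deviation is at most
    ``max_daily_sd``.  Interior floating days are never removed — only the
    post-detachment tail.  If every day is floating, an empty series is
    returned with a warning.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    floating = _floating_days(series, surface_depth, min_frac, max_daily_sd)
    n_trailing = 0
    for val in floating.iloc[::-1]:
        if not val:
            break
        n_trailing += 1
    if n_trailing == len(floating):
        warnings.warn(f"tag {series.tag_id}: all days classified floating; "
                      "returning empty series")
        return replace(series, samples=series.samples.iloc[0:0])
    if n_trailing == 0:
        return series
    keep_days = set(floating.index[:len(floating) - n_trailing])
    mask = series.dates.isin(keep_days)
    return replace(series, samples=series.samples[mask].reset_index(drop=True))


def flag_sensor_saturation(series: DepthTempSeries) -> tuple[float, pd.Series]:
    """Fraction of censored samples overall, and censored counts per civil day.

    A censored daily maximum depth must be treated downstream as a lower
    bound on true depth, not an estimate of it.
    """
    if len(series) == 0:
        return 0.0, pd.Series(dtype=int)
    frac = float(series.samples["censored"].mean())
    per_day = series.samples.groupby(series.dates)["censored"].sum().astype(int)
    return frac, per_day


# -- deployment metadata -------------------------------------------------

_DEPLOY_COLUMNS = ["tag_id", "tag_class", "length_cm", "weight_g", "sex",
                   "maturity", "condition", "release_lat", "release_lon",
                   "release_date", "recapture_lat", "recapture_lon",
                   "recapture_date"]


def read_deployments_csv(path: str | Path) -> list[TagDeployment]:
    """Read one-row-per-tag deployment metadata."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        release = (float(row["release_lat"]), float(row["release_lon"]),
                   pd.Timestamp(row["release_date"]).date())
        recapture = None
        if pd.notna(row.get("recapture_lat")) and pd.notna(row.get("recapture_date")):
            recapture = (float(row["recapture_lat"]), float(row["recapture_lon"]),
                         pd.Timestamp(row["recapture_date"]).date())
        out.append(TagDeployment(
            tag_id=str(row["tag_id"]), tag_class=str(row["tag_class"]),
            length_cm=float(row["length_cm"]),
            weight_g=float(row["weight_g"]) if pd.notna(row.get("weight_g")) else None,
            sex=str(row.get("sex", "unknown")),
            maturity=str(row["maturity"]) if pd.notna(row.get("maturity")) else None,
            condition=str(row.get("condition", "unknown")),
            release=release, recapture=recapture))
    return out


def write_deployments_csv(deployments: list[TagDeployment], path: str | Path) -> None:
    rows = []
    for d in deployments:
        rec = d.recapture or (None, None, None)
        rows.append({
            "tag_id": d.tag_id, "tag_class": d.tag_class, "length_cm": d.length_cm,
            "weight_g": d.weight_g, "sex": d.sex, "maturity": d.maturity,
            "condition": d.condition,
            "release_lat": d.release[0], "release_lon": d.release[1],
            "release_date": d.release[2],
            "recapture_lat": rec[0], "recapture_lon": rec[1],
            "recapture_date": rec[2]})
    pd.DataFrame(rows, columns=_DEPLOY_COLUMNS).to_csv(path, index=False)
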