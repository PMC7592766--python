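"""Synthetic environment, movement and tag-record generators.

Everything downstream of raw data — conditioning, diel labelling, vertical
metrics, geolocation, dispersal — is exercised against worlds built here.
The generators emulate the statistical structure the analysis assumes:

* a coastal shelf sea (depths to ~130 m) with an M2 tidal field whose
  amplitude and phase vary smoothly in space, and a seasonal temperature
  field peaking in August;
* two-state (resident / transiting) daily movement, each state a Brownian
  walk with its own diffusivity;
* a demersal depth record: bouts of rest on the seabed carrying the tidal
  pressure sinusoid, alternating with off-bottom excursions, with night
  depths shallower by a planted diel offset;
* mark-recapture deployments with sex-specific Rayleigh dispersal.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dst_io import DepthTempSeries, TagDeployment
from .environment import (DAYS_PER_YEAR, KM_PER_DEG_LAT, M2_PERIOD_HOURS,
                          EnvironmentGrid)

_M2_OMEGA = 2 * np.pi / (M2_PERIOD_HOURS * 3600.0)  # rad / s


@dataclass
class TrueTrack:
    """Ground-truth daily positions and behavioural states."""

    positions: pd.DataFrame  # columns: date, lat, lon, state

    def __post_init__(self) -> None:
        required = {"date", "lat", "lon", "state"}
        if missing := required - set(self.positions.columns):
            raise ValueError(f"track missing columns {sorted(missing)}")
        self.positions = self.positions.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def release(self) -> tuple[float, float, date]:
        r = self.positions.iloc[0]
        return float(r["lat"]), float(r["lon"]), r["date"]

    @property
    def recapture(self) -> tuple[float, float, date]:
        r = self.positions.iloc[-1]
        return float(r["lat"]), float(r["lon"]), r["date"]


@dataclass
class BehaviourSpec:
    """Within-day vertical-behaviour parameters for the DST simulator.

    ``dvm_offset`` is the planted day-minus-night mean depth difference (m);
    all night samples are shifted shallower by this amount, so with equal
    day/night rest fractions the realised mean difference is exactly the
    offset in expectation.  ``excursion_scale`` is the mean of the
    exponential off-bottom excursion depth (m).  ``active_wander_sd`` is the
    standard deviation (m per 10-minute step) of the within-bout random walk
    during active swimming; it is what distinguishes active bouts from
    seabed rest in the depth record.
    """

    rest_fraction_day: float = 0.55
    rest_fraction_night: float = 0.55
    dvm_offset: float = 15.0
    excursion_scale: float = 10.0
    depth_noise_sd: float = 0.2
    temp_noise_sd: float = 0.3
    sampling_interval: float = 600.0  # s
    bout_mean_active_h: float = 2.0
    active_wander_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("rest_fraction_day", "rest_fraction_night"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("dvm_offset", "excursion_scale", "depth_noise_sd",
                     "temp_noise_sd", "active_wander_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_environment(seed: int, nx: int = 25, ny: int = 25,
                     extent: tuple[float, float, float, float] = (-5.0, -1.0, 49.0, 52.0),
                     ) -> EnvironmentGrid:
    """Build a smooth random shelf-sea grid.

    Bathymetry is a low-order 2-D cosine series scaled to roughly 0-130 m,
    with a strip of land along the western edge.  Tidal amplitude rises
    monotonically west-to-east from 0.3 to 3 m; phase rotates smoothly
    across the domain.  Temperature combines a latitudinal gradient (warmer
    south) with a seasonal sinusoid peaking in mid-August, spanning roughly
    7-22 degC over the year.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate extent")
    if nx < 8 or ny < 8:
        raise ValueError("grid must be at least 8x8")
    rng = np.random.default_rng(seed)
    lon = np.linspace(lon_min, lon_max, nx)
    lat = np.linspace(lat_min, lat_max, ny)
    xh = (lon - lon_min) / (lon_max - lon_min)  # 0..1 west->east
    yh = (lat - lat_min) / (lat_max - lat_min)
    X, Y = np.meshgrid(xh, yh)

    fld = np.zeros((ny, nx))
    for k in range(4):
        for l in range(4):
            if k == 0 and l == 0:
                continue
            c = rng.normal(scale=1.0 / (1.0 + k + l))
            fld += c * np.cos(np.pi * k * X + rng.uniform(0, np.pi)) \
                     * np.cos(np.pi * l * Y + rng.uniform(0, np.pi))
    fld = (fld - fld.min()) / (fld.max() - fld.min())
    bathy = 8.0 + 122.0 * fld
    # land strip along the western edge
    coast = np.clip((0.08 - X) / 0.08, 0.0, None)
    bathy = bathy - 300.0 * coast

    amplitude = 0.3 + 2.7 * X
    phase = np.mod(2 * np.pi * (0.25 * X + 0.75 * Y), 2 * np.pi)
    temp_mean = 14.5 - 1.0 * (lat[:, None] - np.mean(lat)) + 0.0 * X
    temp_amp = np.full((ny, nx), 7.0)
    return EnvironmentGrid(lon_centers=lon, lat_centers=lat, bathymetry=bathy,
                           tide_amplitude=np.clip(amplitude, 0, None),
                           tide_phase=phase, temp_mean=temp_mean,
                           temp_seasonal_amplitude=temp_amp)


DEFAULT_SWITCH = np.array([[0.9, 0.1], [0.1, 0.9]])


def default_release(env: EnvironmentGrid) -> tuple[float, float]:
    """A sea cell centre near the middle of the grid."""
    ci, cj = env.ny // 2, env.nx // 2
    sea_i, sea_j = np.nonzero(env.sea)
    k = int(np.argmin((sea_i - ci) ** 2 + (sea_j - cj) ** 2))
    return env.cell_center(int(sea_i[k]), int(sea_j[k]))


def simulate_track(env: EnvironmentGrid,
                   diffusivities: Sequence[float] = (30.0, 750.0),
                   switch_matrix: np.ndarray = DEFAULT_SWITCH,
                   seed: int = 0, n_days: int = 90,
                   release: Optional[tuple[float, float]] = None,
                   start_date: date = date(2018, 7, 1)) -> TrueTrack:
    """Two-state Brownian walk on the sea portion of the grid.

    Daily displacement is isotropic Gaussian with per-axis variance
    ``2 * D_state`` (km^2, dt = 1 day).  Proposals landing on land or off
    the grid are resampled up to 100 times, after which the animal stays put.
    """
    diffusivities = np.asarray(diffusivities, dtype=float)
    if np.any(diffusivities < 0):
        raise ValueError("diffusivities must be >= 0")
    A = np.asarray(switch_matrix, dtype=float)
    if A.shape != (2, 2) or not np.allclose(A.sum(axis=1), 1.0) or np.any(A < 0):
        raise ValueError("switch matrix must be 2x2 row-stochastic")
    rng = np.random.default_rng(seed)
    if release is None:
        release = default_release(env)
    lat, lon = release
    if not env.is_sea(lat, lon):
        raise ValueError("release position is on land or off-grid")

    state = int(rng.integers(2))
    rows = [{"date": start_date, "lat": lat, "lon": lon, "state": state}]
    for d in range(1, n_days):
        state = int(rng.choice(2, p=A[state]))
        sd_km = math.sqrt(2.0 * diffusivities[state])
        for _ in range(100):
            dlat = rng.normal(0, sd_km) / KM_PER_DEG_LAT
            dlon = rng.normal(0, sd_km) / (KM_PER_DEG_LAT * math.cos(math.radians(lat)))
            if env.is_sea(lat + dlat, lon + dlon):
                lat, lon = lat + dlat, lon + dlon
                break
        rows.append({"date": start_date + timedelta(days=d),
                     "lat": lat, "lon": lon, "state": state})
    return TrueTrack(positions=pd.DataFrame(rows))


def _bout_boundaries(rng: np.random.Generator, seg_start: float, seg_end: float,
                     rest_frac: float, mean_active_s: float):
    """Alternating (start, end, is_rest) bouts filling [seg_start, seg_end)."""
    if rest_frac >= 1.0:
        return [(seg_start, seg_end, True)]
    if rest_frac <= 0.0:
        return [(seg_start, seg_end, False)]
    mean_rest_s = mean_active_s * rest_frac / (1.0 - rest_frac)
    bouts, t = [], seg_start
    is_rest = bool(rng.random() < rest_frac)
    while t < seg_end:
        dur = rng.exponential(mean_rest_s if is_rest else mean_active_s)
        bouts.append((t, min(t + dur, seg_end), is_rest))
        t += dur
        is_rest = not is_rest
    return bouts


def simulate_dst(track: TrueTrack, env: EnvironmentGrid,
                 spec: BehaviourSpec = BehaviourSpec(), seed: int = 0,
                 tag_id: str = "sim",
                 sensor_ceiling: Optional[float] = None) -> DepthTempSeries:
    """Generate the depth/temperature record a DST would log along a track.

    Each day is partitioned into rest and active bouts.  At rest the depth
    is the local seabed plus the M2 tidal sinusoid
    ``amplitude * cos(omega * t - phase)`` (t in seconds since the Unix
    epoch, so the phase is spatially meaningful across days).  Active depth
    is the seabed minus an exponential excursion plus a within-bout random
    walk.  Night samples (18:00-06:00 UTC) are shifted shallower by
    ``dvm_offset``.  Depths are clipped to
    ``[0, bathymetry + amplitude + 4 * depth_noise_sd]``.
    """
    rng = np.random.default_rng(seed)
    dt = float(spec.sampling_interval)
    night_segments = [(0.0, 6 * 3600.0), (18 * 3600.0, 86400.0)]
    day_segment = (6 * 3600.0, 18 * 3600.0)

    frames = []
    for _, row in track.positions.iterrows():
        i, j = env.cell_index(row["lat"], row["lon"])
        bathy = float(env.bathymetry[i, j])
        amp = float(env.tide_amplitude[i, j])
        phase = float(env.tide_phase[i, j])
        day0 = pd.Timestamp(row["date"], tz="UTC")
        doy = day0.dayofyear
        temp_cell = float(env.temperature(doy)[i, j])

        sod = np.arange(0.0, 86400.0, dt)
        t_abs = day0.timestamp() + sod
        night = (sod < night_segments[0][1]) | (sod >= night_segments[1][0])

        segments = [(*night_segments[0], spec.rest_fraction_night),
                    (*day_segment, spec.rest_fraction_day),
                    (*night_segments[1], spec.rest_fraction_night)]
        depth = np.empty_like(sod)
        wander_step = spec.active_wander_sd * math.sqrt(dt / 600.0)
        for s0, s1, rf in segments:
            for b0, b1, is_rest in _bout_boundaries(rng, s0, s1, rf,
                                                    spec.bout_mean_active_h * 3600.0):
                m = (sod >= b0) & (sod < b1)
                if not m.any():
                    continue
                if is_rest:
                    depth[m] = bathy + amp * np.cos(_M2_OMEGA * t_abs[m] - phase)
                else:
                    exc = rng.exponential(spec.excursion_scale)
                    wander = np.cumsum(rng.normal(0, wander_step, m.sum()))
                    depth[m] = bathy - exc + wander
        depth = depth - spec.dvm_offset * night
        depth = depth + rng.normal(0, spec.depth_noise_sd, len(sod))
        depth = np.clip(depth, 0.0, bathy + amp + 4 * spec.depth_noise_sd)
        temp = temp_cell + rng.normal(0, spec.temp_noise_sd, len(sod))
        frames.append(pd.DataFrame({
            "timestamp": day0 + pd.to_timedelta(sod, unit="s"),
            "depth": depth, "temperature": temp}))

    samples = pd.concat(frames, ignore_index=True)
    samples["censored"] = ((samples["depth"] >= sensor_ceiling)
                           if sensor_ceiling is not None else False)
    return DepthTempSeries(tag_id=tag_id, samples=samples,
                           nominal_depth_interval=dt, nominal_temp_interval=dt)


def simulate_diel_sample(seed: int, dvm_offset: float, within_sd: float,
                         n_per_period: int = 60, base_depth: float = 50.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic 24-h cycle of day and night depth samples with a planted
    day-minus-night offset — the minimal input for behaviour classification."""
    rng = np.random.default_rng(seed)
    day = rng.normal(base_depth, within_sd, n_per_period)
    night = rng.normal(base_depth - dvm_offset, within_sd, n_per_period)
    return np.clip(day, 0, None), np.clip(night, 0, None)


def simulate_mark_recapture(env: EnvironmentGrid, n: int = 500,
                            sex_ratio: float = 0.61,
                            disp_scale_f: float = 162.0,
                            disp_scale_m: float = 118.1,
                            p_recapture: float = 0.3, seed: int = 0,
                            mean_days_at_liberty: float = 191.0,
                            p_lively: float = 0.73,
                            start_date: date = date(2018, 7, 1),
                            ) -> list[TagDeployment]:
    """Simulate conventional tagging: releases uniform over a central tagging
    box, displacement magnitude Rayleigh with a sex-specific scale (km),
    direction uniform, recapture Bernoulli, days at liberty geometric.

    Default Rayleigh scales give mean female and male displacements of about
    203 km and 148 km (``scale * sqrt(pi / 2)``), matching field-scale
    sex-biased dispersal in coastal sharks.
    """
    if disp_scale_f <= 0 or disp_scale_m <= 0:
        raise ValueError("dispersal scales must be > 0")
    rng = np.random.default_rng(seed)
    lon0, lon1 = env.lon_centers[0], env.lon_centers[-1]
    lat0, lat1 = env.lat_centers[0], env.lat_centers[-1]
    # inner 60 % of the domain as the tagging box
    lon_lo, lon_hi = lon0 + 0.2 * (lon1 - lon0), lon1 - 0.2 * (lon1 - lon0)
    lat_lo, lat_hi = lat0 + 0.2 * (lat1 - lat0), lat1 - 0.2 * (lat1 - lat0)

    out = []
    for k in range(n):
        for _ in range(100):
            rlat = rng.uniform(lat_lo, lat_hi)
            rlon = rng.uniform(lon_lo, lon_hi)
            if env.is_sea(rlat, rlon):
                break
        sex = "F" if rng.random() < sex_ratio else "M"
        length = float(np.clip(rng.normal(86.0, 15.0), 45.0, 140.0))
        condition = "lively" if rng.random() < p_lively else "sluggish"
        rel_date = start_date + timedelta(days=int(rng.integers(0, 90)))
        recapture = None
        if rng.random() < p_recapture:
            scale = disp_scale_f if sex == "F" else disp_scale_m
            dist_km = rng.rayleigh(scale)
            theta = rng.uniform(0, 2 * np.pi)
            dlat = dist_km * math.sin(theta) / KM_PER_DEG_LAT
            dlon = dist_km * math.cos(theta) / (KM_PER_DEG_LAT
                                                * math.cos(math.radians(rlat)))
            days = int(rng.geometric(1.0 / mean_days_at_liberty))
            recapture = (float(np.clip(rlat + dlat, -90, 90)),
                         float(((rlon + dlon + 180) % 360) - 180),
                         rel_date + timedelta(days=days))
        out.append(TagDeployment(
            tag_id=f"MR{k:05d}", tag_class="mark-recapture", length_cm=length,
            sex=sex, condition=condition,
            release=(float(rlat), float(rlon), rel_date), recapture=recapture))
    return out
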