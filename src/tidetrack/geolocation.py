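"""Grid-based two-state hidden Markov geolocation from DST records.

Each day at liberty is summarised into a :class:`DailyObservation` — the
maximum depth, mean temperature, detected seabed-rest windows and, where a
long enough rest window exists, a least-squares M2 harmonic fit (amplitude,
phase) to the tidal pressure sinusoid the tag records while the fish lies
on the seabed.  The hidden state is the joint (grid cell, behavioural
state); behaviour is resident or transiting, each with its own diffusivity
D (km^2/day), and the daily position transition is the analytic solution of
the isotropic diffusion (Fokker-Planck) step: convolution with a Gaussian
kernel of per-axis variance ``2 * D * dt``.  Emission likelihoods combine
independent bathymetric, seabed-contact, tidal (amplitude + phase) and
temperature terms per sea cell.  Forward filtering plus backward smoothing
yields a per-day posterior probability surface over the grid, from which a
most-probable daily position and a positional-spread radius are read off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import i0e

from .dst_io import DepthTempSeries
from .environment import (KM_PER_DEG_LAT, M2_PERIOD_HOURS, EnvironmentGrid)

_M2_OMEGA = 2 * np.pi / (M2_PERIOD_HOURS * 3600.0)  # rad / s


class TidalFit(NamedTuple):
    amplitude: float  # m
    phase: float      # rad in [0, 2*pi)
    rmse: float       # m


@dataclass
class HMMConfig:
    """Model parameters for the geolocation HMM.

    ``diffusivities`` are (resident, transiting) in km^2/day and must be
    ordered low < high; ``switch_matrix`` is the row-stochastic behaviour
    transition matrix.  The sigma_* values are emission error scales:
    bathymetric exceedance (m), seabed contact (m), tidal amplitude (m),
    temperature (degC); ``kappa_phase`` is the von Mises concentration of
    the tidal phase term.  Rest windows are detected with sliding windows
    of ``min_rest_hours`` whose harmonic-fit residual must stay below
    ``rest_rmse_max`` (m) and ``rest_speed_max`` (m/min).
    """

    diffusivities: tuple[float, float] = (30.0, 750.0)
    switch_matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, 0.1], [0.1, 0.9]]))
    sigma_bathy: float = 4.0
    sigma_contact: float = 5.0
    sigma_amp: float = 0.3
    kappa_phase: float = 20.0
    sigma_temp: float = 1.0
    min_rest_hours: float = 3.0
    rest_rmse_max: float = 0.75
    rest_speed_max: float = 0.1  # m/min, after removing the fitted sinusoid
    components: tuple[str, ...] = ("bathy", "contact", "tide", "temp")

    def __post_init__(self) -> None:
        d_low, d_high = self.diffusivities
        if not 0 < d_low < d_high:
            raise ValueError("diffusivities must satisfy 0 < D_low < D_high")
        A = np.asarray(self.switch_matrix, dtype=float)
        if A.shape != (2, 2) or np.any(A < 0) or not np.allclose(A.sum(axis=1), 1):
            raise ValueError("switch_matrix must be 2x2 row-stochastic")
        self.switch_matrix = A
        for name in ("sigma_bathy", "sigma_contact", "sigma_amp",
                     "kappa_phase", "sigma_temp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        unknown = set(self.components) - {"bathy", "contact", "tide", "temp"}
        if unknown:
            raise ValueError(f"unknown emission components {sorted(unknown)}")


@dataclass
class DailyObservation:
    """One day's evidence for the emission model."""

    date: date
    max_depth: float
    max_depth_censored: bool
    mean_temp: float
    rest_windows: list[tuple[pd.Timestamp, pd.Timestamp]]
    tidal_fit: Optional[TidalFit]
    n_samples: int
    low_coverage: bool = False


# -- tidal harmonic ------------------------------------------------------

def _epoch_seconds(times) -> np.ndarray:
    t = np.asarray(times)
    if np.issubdtype(t.dtype, np.number):
        return t.astype(float)
    ts = pd.DatetimeIndex(times)
    return ts.view("int64").astype(float) / 1e9


def _harmonic_lstsq(t_sec: np.ndarray, depths: np.ndarray,
                    period_h: float) -> tuple[float, float, float, np.ndarray]:
    """Least-squares fit of depth = c + a*cos(wt) + b*sin(wt).

    Returns (amplitude, phase, rmse, residuals); phase mapped to [0, 2*pi).
    """
    omega = 2 * np.pi / (period_h * 3600.0)
    wt = omega * t_sec
    X = np.column_stack([np.ones_like(wt), np.cos(wt), np.sin(wt)])
    coef, *_ = np.linalg.lstsq(X, depths, rcond=None)
    resid = depths - X @ coef
    amp = float(np.hypot(coef[1], coef[2]))
    phase = float(np.mod(np.arctan2(coef[2], coef[1]), 2 * np.pi))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return amp, phase, rmse, resid


def _harmonic_lstsq_grouped(t_sec: np.ndarray, depths: np.ndarray,
                            groups: np.ndarray, period_h: float) -> TidalFit:
    """Shared-harmonic fit across several rest windows of one day.

    Amplitude and phase are common; each window gets its own intercept,
    absorbing level shifts between windows (e.g. the diel offset between a
    daytime and a night-time rest bout).
    """
    omega = 2 * np.pi / (period_h * 3600.0)
    wt = omega * t_sec
    cols = [np.cos(wt), np.sin(wt)]
    for gid in np.unique(groups):
        cols.append((groups == gid).astype(float))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, depths, rcond=None)
    resid = depths - X @ coef
    amp = float(np.hypot(coef[0], coef[1]))
    phase = float(np.mod(np.arctan2(coef[1], coef[0]), 2 * np.pi))
    return TidalFit(amp, phase, float(np.sqrt(np.mean(resid ** 2))))


def fit_tidal_harmonic(times, depths, period_h: float = M2_PERIOD_HOURS) -> TidalFit:
    """Fit the tidal sinusoid to a rest-window depth record.

    ``times`` may be timestamps or seconds.  Requires at least 8 samples
    spanning at least half a tidal period (shorter spans cannot constrain
    the amplitude), and a non-degenerate time axis.
    """
    t = _epoch_seconds(times)
    d = np.asarray(depths, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 samples for a tidal fit")
    span_h = (t.max() - t.min()) / 3600.0
    if span_h < period_h / 2:
        raise ValueError(f"window span {span_h:.2f} h shorter than half a period")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all times equal")
    amp, phase, rmse, _ = _harmonic_lstsq(t, d, period_h)
    return TidalFit(amp, phase, rmse)


# -- rest-window detection ----------------------------------------------

def detect_rest_windows(day_samples: pd.DataFrame, cfg: HMMConfig,
                        period_h: float = M2_PERIOD_HOURS,
                        ) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Find seabed-rest windows within one civil day of samples.

    Sliding windows of ``cfg.min_rest_hours`` (step 30 min) qualify as rest
    when the M2 harmonic fit to their depths has rmse at most
    ``cfg.rest_rmse_max`` and the fitted-curve-removed vertical speed never
    exceeds ``cfg.rest_speed_max`` m/min.  Overlapping windows are merged.
    """
    if len(day_samples) < 12:
        return []
    ts = day_samples["timestamp"]
    t_sec = _epoch_seconds(ts)
    depths = day_samples["depth"].to_numpy(dtype=float)
    day_start = ts.iloc[0].normalize()
    t0 = day_start.timestamp()
    win_len, step = cfg.min_rest_hours * 3600.0, 1800.0

    accepted: list[tuple[float, float]] = []
    start = t0
    while start + win_len <= t0 + 86400.0 + 1e-6:
        m = (t_sec >= start) & (t_sec < start + win_len)
        if m.sum() >= 8:
            tw, dw = t_sec[m], depths[m]
            _, _, rmse, resid = _harmonic_lstsq(tw, dw, period_h)
            if rmse <= cfg.rest_rmse_max:
                dt_min = np.diff(tw) / 60.0
                speeds = np.abs(np.diff(resid)) / dt_min
                if not len(speeds) or speeds.max() <= cfg.rest_speed_max:
                    accepted.append((start, start + win_len))
        start += step

    merged: list[list[float]] = []
    for a, b in accepted:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(pd.Timestamp(a, unit="s", tz="UTC"), pd.Timestamp(b, unit="s", tz="UTC"))
            for a, b in merged]


def summarise_day(series: DepthTempSeries, cfg: HMMConfig) -> list[DailyObservation]:
    """Collapse a conditioned series into one observation per civil day.

    The tidal fit pools the samples of every rest window in the day — the
    phase is coherent across windows at a fixed daily position — provided
    the pooled samples span at least half an M2 period (shorter spans
    cannot separate amplitude from offset) with at least 8 samples.  Days
    with under 25 % of the expected sample count are flagged low-coverage
    and fall back to temperature-only evidence downstream.
    """
    expected = 86400.0 / series.nominal_depth_interval
    out = []
    for d, g in series.day_groups():
        depths = g["depth"].to_numpy(dtype=float)
        imax = int(np.argmax(depths))
        censored = bool(g["censored"].to_numpy()[imax])
        low = len(g) < 0.25 * expected
        windows = detect_rest_windows(g, cfg) if not low else []
        fit = None
        if windows:
            m = pd.Series(False, index=g.index)
            group = np.full(len(g), -1)
            for k, (a, b) in enumerate(windows):
                inside = (g["timestamp"] >= a) & (g["timestamp"] < b)
                m |= inside
                group[inside.to_numpy()] = k
            tsel = g.loc[m, "timestamp"]
            span_h = (tsel.max() - tsel.min()).total_seconds() / 3600.0
            if m.sum() >= 8 and span_h >= M2_PERIOD_HOURS / 2:
                fit = _harmonic_lstsq_grouped(
                    _epoch_seconds(tsel), g.loc[m, "depth"].to_numpy(dtype=float),
                    group[m.to_numpy()], M2_PERIOD_HOURS)
        out.append(DailyObservation(
            date=d, max_depth=float(depths[imax]), max_depth_censored=censored,
            mean_temp=float(np.nanmean(g["temperature"].to_numpy(dtype=float))),
            rest_windows=windows, tidal_fit=fit, n_samples=len(g),
            low_coverage=low))
    return out


# -- emission ------------------------------------------------------------

_LOG_2PI = math.log(2 * math.pi)


def emission_log_surface(obs: DailyObservation, env: EnvironmentGrid,
                         cfg: HMMConfig) -> np.ndarray:
    """Per-cell log-likelihood of one day's evidence; land cells are -inf.

    Independent terms: (i) bathymetric — the seabed cannot be shallower
    than the day's maximum depth, so cells with ``bathy < max_depth`` incur
    a half-normal penalty (a censored max depth contributes only this
    exceedance direction); (ii) seabed contact, when rest was detected —
    Gaussian in ``bathy - max_depth``; (iii) tidal — Gaussian in amplitude
    difference plus von Mises in phase difference; (iv) temperature —
    Gaussian in the daily mean.  Low-coverage days use (iv) only.  If every
    sea cell is impossible the surface is replaced by a uniform one with a
    warning.
    """
    sea = env.sea
    logL = np.zeros((env.ny, env.nx))
    use = (("temp",) if obs.low_coverage
           else tuple(cfg.components))
    bathy = env.bathymetry

    if "bathy" in use and np.isfinite(obs.max_depth):
        exceed = obs.max_depth - bathy
        pen = np.where(exceed > 0, -(exceed ** 2) / (2 * cfg.sigma_bathy ** 2), 0.0)
        logL += pen
    if ("contact" in use and obs.rest_windows and not obs.max_depth_censored
            and np.isfinite(obs.max_depth)):
        diff = bathy - obs.max_depth
        logL += (-(diff ** 2) / (2 * cfg.sigma_contact ** 2)
                 - 0.5 * _LOG_2PI - math.log(cfg.sigma_contact))
    if "tide" in use and obs.tidal_fit is not None:
        da = env.tide_amplitude - obs.tidal_fit.amplitude
        logL += (-(da ** 2) / (2 * cfg.sigma_amp ** 2)
                 - 0.5 * _LOG_2PI - math.log(cfg.sigma_amp))
        k = cfg.kappa_phase
        dphi = env.tide_phase - obs.tidal_fit.phase
        logL += k * np.cos(dphi) - (math.log(2 * math.pi) + math.log(i0e(k)) + k)
    if "temp" in use and np.isfinite(obs.mean_temp):
        doy = pd.Timestamp(obs.date).dayofyear
        dT = env.temperature(doy) - obs.mean_temp
        logL += (-(dT ** 2) / (2 * cfg.sigma_temp ** 2)
                 - 0.5 * _LOG_2PI - math.log(cfg.sigma_temp))

    logL[~sea] = -np.inf
    # impossible everywhere: even the best sea cell's likelihood underflows
    if np.max(logL[sea]) < -745.0:
        warnings.warn(f"{obs.date}: observation impossible everywhere; "
                      "using a uniform surface")
        logL = np.where(sea, -math.log(int(sea.sum())), -np.inf)
    return logL


# -- diffusion -----------------------------------------------------------

def _sigma_cells(D: float, env: EnvironmentGrid, dt_days: float = 1.0,
                 ) -> tuple[float, float]:
    sigma_km = math.sqrt(2.0 * D * dt_days)
    return (sigma_km / (KM_PER_DEG_LAT * env.dlat),
            sigma_km / (env.km_per_deg_lon * env.dlon))


def diffuse(surface: np.ndarray, D: float, env: EnvironmentGrid,
            dt_days: float = 1.0) -> np.ndarray:
    """One Fokker-Planck step: Gaussian convolution with per-axis standard
    deviation ``sqrt(2 * D * dt)`` (converted to cell units), truncated at
    4 sd, with mass landing on land redistributed by renormalising over sea
    cells.  The output carries the same total mass as the input.
    """
    if D < 0:
        raise ValueError("diffusivity must be >= 0")
    if D == 0:
        return surface.copy()
    sy, sx = _sigma_cells(D, env, dt_days)
    if 4 * max(sy, sx) > min(env.ny, env.nx):
        raise ValueError("diffusion kernel wider than the grid; grid too "
                         f"small for D={D}")
    out = gaussian_filter(surface, sigma=(sy, sx), mode="constant",
                          cval=0.0, truncate=4.0)
    out[~env.sea] = 0.0
    total_in, total_out = surface.sum(), out.sum()
    if total_out <= 0:
        raise ValueError("all probability mass lost to land")
    return out * (total_in / total_out)


# -- forward filter / backward smoother ---------------------------------

@dataclass
class FilterResult:
    dates: list[date]
    filtered: list[np.ndarray]        # (2, ny, nx) per day, each sums to 1
    emissions: list[np.ndarray]       # linear, max-normalised, per day
    log_evidence: float
    release_cell: tuple[int, int]
    recapture_cell: Optional[tuple[int, int]]


def _lin_emission(logL: np.ndarray, sea: np.ndarray) -> tuple[np.ndarray, float]:
    m = float(np.max(logL[sea]))
    e = np.zeros_like(logL)
    e[sea] = np.exp(logL[sea] - m)
    return e, m


def forward_filter(obs_seq: Sequence[DailyObservation], env: EnvironmentGrid,
                   cfg: HMMConfig, release: tuple[float, float],
                   recapture: Optional[tuple[float, float]] = None,
                   ) -> FilterResult:
    """Forward pass over the joint (cell, behaviour) state space.

    The day-0 prior is a delta at the release cell with equal behaviour
    weights; each subsequent day applies the behaviour switch, a per-state
    diffusion step, and the day's emission, renormalising and accumulating
    the log normaliser into the model log-evidence.  If a recapture
    position is given, the final day's emission is restricted to it.
    """
    if not obs_seq:
        raise ValueError("empty observation sequence")
    sea = env.sea
    ri, rj = env.cell_index(*release)
    if not sea[ri, rj]:
        raise ValueError("release cell is on land")
    rec_cell = None
    if recapture is not None:
        rec_cell = env.cell_index(*recapture)

    A = cfg.switch_matrix
    D = cfg.diffusivities
    T = len(obs_seq)
    filtered, emissions = [], []
    log_ev = 0.0
    alpha = np.zeros((2, env.ny, env.nx))
    alpha[:, ri, rj] = 0.5

    for t, obs in enumerate(obs_seq):
        if t > 0:
            mix0 = A[0, 0] * alpha[0] + A[1, 0] * alpha[1]
            mix1 = A[0, 1] * alpha[0] + A[1, 1] * alpha[1]
            alpha = np.stack([diffuse(mix0, D[0], env),
                              diffuse(mix1, D[1], env)])
        e, m = _lin_emission(emission_log_surface(obs, env, cfg), sea)
        if t == T - 1 and rec_cell is not None:
            mask = np.zeros_like(e)
            mask[rec_cell] = 1.0
            e = e * mask
        alpha = alpha * e[None]
        c = float(alpha.sum())
        if c <= 0:
            raise RuntimeError(f"zero filtering normaliser on day {t} "
                               f"({obs.date})")
        alpha /= c
        log_ev += math.log(c) + m
        filtered.append(alpha.copy())
        emissions.append(e)
    return FilterResult(dates=[o.date for o in obs_seq], filtered=filtered,
                        emissions=emissions, log_evidence=log_ev,
                        release_cell=(ri, rj), recapture_cell=rec_cell)


def _grid_gc_km(env: EnvironmentGrid, lat0: float, lon0: float) -> np.ndarray:
    """Great-circle km from (lat0, lon0) to every cell centre."""
    lat = np.radians(env.lat_centers)[:, None]
    lon = np.radians(env.lon_centers)[None, :]
    la0, lo0 = math.radians(lat0), math.radians(lon0)
    s = (np.sin((lat - la0) / 2) ** 2
         + math.cos(la0) * np.cos(lat) * np.sin((lon - lo0) / 2) ** 2)
    return 2 * 6371.0088 * np.arcsin(np.minimum(1.0, np.sqrt(s)))


@dataclass
class PosteriorTrack:
    """Smoothed per-day posteriors and the point track derived from them."""

    dates: list[date]
    position_marginals: list[np.ndarray]  # (ny, nx), each sums to 1
    state_probs: np.ndarray               # (T, 2)
    track: pd.DataFrame                   # date, lat, lon, spread_km, p_state_high
    log_evidence: float


def backward_smooth(fr: FilterResult, env: EnvironmentGrid,
                    cfg: HMMConfig) -> PosteriorTrack:
    """Backward smoothing over the joint space, and the point-track summary.

    The most-probable daily position is the argmax cell of the smoothed
    position marginal; the positional spread is the root-mean-square
    great-circle distance from the posterior-mean position.
    """
    sea = env.sea
    A = cfg.switch_matrix
    D = cfg.diffusivities
    T = len(fr.filtered)
    smoothed = [None] * T
    smoothed[T - 1] = fr.filtered[T - 1].copy()
    beta = np.ones((2, env.ny, env.nx))
    for t in range(T - 1, 0, -1):
        h = fr.emissions[t][None] * beta
        h[:, ~sea] = 0.0
        conv = []
        for s in range(2):
            sy, sx = _sigma_cells(D[s], env)
            conv.append(gaussian_filter(h[s], sigma=(sy, sx),
                                        mode="constant", cval=0.0, truncate=4.0))
        beta = np.stack([A[0, 0] * conv[0] + A[0, 1] * conv[1],
                         A[1, 0] * conv[0] + A[1, 1] * conv[1]])
        beta[:, ~sea] = 0.0
        peak = beta.max()
        if peak <= 0:
            raise RuntimeError(f"zero backward message at day {t}")
        beta /= peak
        sm = fr.filtered[t - 1] * beta
        smoothed[t - 1] = sm / sm.sum()

    marginals, rows = [], []
    state_probs = np.zeros((T, 2))
    for t in range(T):
        state_probs[t] = smoothed[t].sum(axis=(1, 2))
        marg = smoothed[t].sum(axis=0)
        marginals.append(marg)
        i, j = np.unravel_index(int(np.argmax(marg)), marg.shape)
        lat_hat, lon_hat = env.cell_center(int(i), int(j))
        mean_lat = float(np.sum(marg * env.lat_centers[:, None]))
        mean_lon = float(np.sum(marg * env.lon_centers[None, :]))
        d2 = _grid_gc_km(env, mean_lat, mean_lon) ** 2
        spread = float(np.sqrt(np.sum(marg * d2)))
        rows.append({"date": fr.dates[t], "lat": lat_hat, "lon": lon_hat,
                     "spread_km": spread, "p_state_high": float(state_probs[t, 1])})
    return PosteriorTrack(dates=list(fr.dates), position_marginals=marginals,
                          state_probs=state_probs,
                          track=pd.DataFrame(rows), log_evidence=fr.log_evidence)


def geolocate(obs_seq: Sequence[DailyObservation], env: EnvironmentGrid,
              cfg: HMMConfig, release: tuple[float, float],
              recapture: Optional[tuple[float, float]] = None) -> PosteriorTrack:
    """Forward filter + backward smooth in one call."""
    return backward_smooth(forward_filter(obs_seq, env, cfg, release, recapture),
                           env, cfg)


def select_diffusivities(obs_seq: Sequence[DailyObservation],
                         env: EnvironmentGrid, cfg: HMMConfig,
                         candidates: Sequence[tuple[float, float]],
                         release: tuple[float, float],
                         recapture: Optional[tuple[float, float]] = None,
                         ) -> tuple[tuple[float, float], pd.DataFrame]:
    """Pick the (D_low, D_high) pair maximising the forward log-evidence.

    Exhaustive evaluation over the candidate grid; returns the argmax pair
    and the full evidence table.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    rows = []
    for d_low, d_high in candidates:
        cand_cfg = replace(cfg, diffusivities=(d_low, d_high))
        fr = forward_filter(obs_seq, env, cand_cfg, release, recapture)
        rows.append({"d_low": d_low, "d_high": d_high,
                     "log_evidence": fr.log_evidence})
    table = pd.DataFrame(rows)
    best = table.loc[table["log_evidence"].idxmax()]
    return (float(best["d_low"]), float(best["d_high"])), table


def viterbi_path(obs_seq: Sequence[DailyObservation], env: EnvironmentGrid,
                 cfg: HMMConfig, release: tuple[float, float],
                 recapture: Optional[tuple[float, float]] = None) -> pd.DataFrame:
    """Jointly most-probable (cell, state) path — the alternative "most
    probable movement path" estimator, distinct from the per-day argmax of
    the smoothed marginals.

    Uses a dense Gaussian transition kernel over sea cells (no truncation).
    Returns a DataFrame with date, lat, lon and behaviour state.
    """
    sea = env.sea
    si, sj = np.nonzero(sea)
    n = len(si)
    lat_km = env.lat_centers[si] * KM_PER_DEG_LAT
    lon_km = env.lon_centers[sj] * env.km_per_deg_lon
    d2 = ((lat_km[:, None] - lat_km[None, :]) ** 2
          + (lon_km[:, None] - lon_km[None, :]) ** 2)
    logK = [  # logK[s][to, from]
        -d2 / (4.0 * D) for D in cfg.diffusivities]  # var = 2 D per axis
    logA = np.log(cfg.switch_matrix)

    ri, rj = env.cell_index(*release)
    rel_flat = int(np.nonzero((si == ri) & (sj == rj))[0][0])
    T = len(obs_seq)
    emis = []
    for t, obs in enumerate(obs_seq):
        e = emission_log_surface(obs, env, cfg)[si, sj]
        if t == T - 1 and recapture is not None:
            qi, qj = env.cell_index(*recapture)
            mask = np.full(n, -np.inf)
            mask[(si == qi) & (sj == qj)] = 0.0
            e = e + mask
        emis.append(e)

    delta = np.full((2, n), -np.inf)
    delta[:, rel_flat] = math.log(0.5) + emis[0][rel_flat]
    back_state = np.zeros((T, 2, n), dtype=np.int8)
    back_cell = np.zeros((T, 2, n), dtype=np.int32)
    for t in range(1, T):
        new = np.full((2, n), -np.inf)
        for s in range(2):
            # best previous state per source cell
            via = delta + logA[:, s][:, None]          # (2, n_from)
            s_prev = np.argmax(via, axis=0)            # (n_from,)
            score_from = via[s_prev, np.arange(n)]     # (n_from,)
            tot = logK[s] + score_from[None, :]        # (n_to, n_from)
            c_prev = np.argmax(tot, axis=1)
            new[s] = tot[np.arange(n), c_prev] + emis[t]
            back_state[t, s] = s_prev[c_prev]
            back_cell[t, s] = c_prev
        delta = new

    path = np.zeros((T, 2), dtype=int)
    s_t = int(np.argmax(np.max(delta, axis=1)))
    c_t = int(np.argmax(delta[s_t]))
    path[T - 1] = (s_t, c_t)
    for t in range(T - 1, 0, -1):
        s_t, c_t = int(back_state[t, s_t, c_t]), int(back_cell[t, s_t, c_t])
        path[t - 1] = (s_t, c_t)
    rows = [{"date": obs_seq[t].date,
             "lat": float(env.lat_centers[si[path[t, 1]]]),
             "lon": float(env.lon_centers[sj[path[t, 1]]]),
             "state": int(path[t, 0])} for t in range(T)]
    return pd.DataFrame(rows)
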