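"""Harmonic fitting, rest detection, emission, diffusion and HMM smoothing."""

import math
import warnings
from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

import tidetrack as tt
from tidetrack.environment import KM_PER_DEG_LAT, M2_PERIOD_HOURS
from tidetrack.geolocation import (HMMConfig, _sigma_cells, backward_smooth,
                                   detect_rest_windows, diffuse,
                                   emission_log_surface, fit_tidal_harmonic,
                                   forward_filter, select_diffusivities,
                                   summarise_day, viterbi_path)

OMEGA = 2 * np.pi / (M2_PERIOD_HOURS * 3600)


def _sinusoid(amp, phase, n=144, dt=600.0, t0=1.53e9, mean=50.0, noise=0.0,
              rng=None):
    t = t0 + np.arange(n) * dt
    d = mean + amp * np.cos(OMEGA * t - phase)
    if noise:
        d = d + rng.normal(0, noise, n)
    return t, d


class TestFitTidalHarmonic:
    def test_noiseless_recovery_is_exact(self):
        t, d = _sinusoid(1.5, 1.0)
        fit = fit_tidal_harmonic(t, d)
        assert fit.amplitude == pytest.approx(1.5, abs=1e-9)
        assert fit.phase == pytest.approx(1.0, abs=1e-9)
        assert fit.rmse < 1e-9

    def test_constant_depth_gives_zero_amplitude(self):
        t, _ = _sinusoid(0.0, 0.0)
        fit = fit_tidal_harmonic(t, np.full(len(t), 42.0))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_short_window_rejected(self):
        t, d = _sinusoid(1.0, 0.0, n=20, dt=600.0)  # ~3.2 h span
        with pytest.raises(ValueError, match="half a period"):
            fit_tidal_harmonic(t, d)

    def test_noisy_amplitude_recovery_rate(self):
        rng = np.random.default_rng(11)
        ok = 0
        for _ in range(200):
            t, d = _sinusoid(1.2, 2.0, n=36, dt=1800.0, noise=0.1, rng=rng)
            ok += abs(fit_tidal_harmonic(t, d).amplitude - 1.2) < 0.1
        assert ok >= 0.95 * 200


def _day_frame(depths, dt=600.0, start="2018-07-02"):
    ts = pd.date_range(start, periods=len(depths), freq=f"{int(dt)}s", tz="UTC")
    return pd.DataFrame({"timestamp": ts, "depth": depths})


class TestDetectRestWindows:
    cfg = HMMConfig()

    def test_pure_seabed_sinusoid_gives_full_day_window(self):
        t, d = _sinusoid(1.0, 0.5, n=144, t0=pd.Timestamp("2018-07-02",
                                                          tz="UTC").timestamp())
        windows = detect_rest_windows(_day_frame(d), self.cfg)
        assert len(windows) == 1
        a, b = windows[0]
        assert (b - a) >= pd.Timedelta(hours=23)

    def test_continuous_excursions_give_no_windows(self):
        t = np.arange(144) * 600.0
        d = 50.0 + 10.0 * np.sign(np.sin(2 * np.pi * t / 3600.0))  # 30-min flips
        assert detect_rest_windows(_day_frame(d), self.cfg) == []

    def test_rest_then_excursions_gives_single_bounded_window(self):
        t0 = pd.Timestamp("2018-07-02", tz="UTC").timestamp()
        _, rest = _sinusoid(1.0, 0.5, n=36, t0=t0)  # first 6 h at rest
        t = np.arange(36, 144) * 600.0
        active = 50.0 + 10.0 * np.sign(np.sin(2 * np.pi * t / 3600.0))
        windows = detect_rest_windows(_day_frame(np.concatenate([rest, active])),
                                      self.cfg)
        assert len(windows) == 1
        a, b = windows[0]
        dur_h = (b - a).total_seconds() / 3600
        assert 5.0 <= dur_h <= 7.0


class TestSummariseDay:
    def test_max_depth_and_sample_count(self, env):
        lat, lon = tt.synthetic_world.default_release(env)
        track = tt.TrueTrack(pd.DataFrame(
            {"date": [date(2018, 7, 1)], "lat": lat, "lon": lon, "state": 0}))
        spec = tt.BehaviourSpec(rest_fraction_day=1.0, rest_fraction_night=1.0,
                                dvm_offset=0.0, depth_noise_sd=0.0)
        s = tt.simulate_dst(track, env, spec, seed=1)
        obs = summarise_day(s, HMMConfig())[0]
        i, j = env.cell_index(lat, lon)
        seabed, amp = env.bathymetry[i, j], env.tide_amplitude[i, j]
        assert obs.n_samples == 144
        assert seabed <= obs.max_depth <= seabed + amp
        assert obs.tidal_fit is not None
        assert obs.tidal_fit.amplitude == pytest.approx(amp, abs=1e-6)

    def test_day_without_rest_has_no_tidal_fit(self):
        rng = np.random.default_rng(0)
        d = 40 + np.cumsum(rng.normal(0, 3, 144))  # never still
        df = _day_frame(np.clip(d, 1, None))
        df["temperature"] = 12.0
        df["censored"] = False
        s = tt.DepthTempSeries("x", df, 600.0, 600.0)
        obs = summarise_day(s, HMMConfig())[0]
        assert obs.tidal_fit is None


def _two_cell_env(**overrides):
    """2x2 grid with two sea cells differing only in tidal amplitude."""
    ones = np.ones((2, 2))
    fields = dict(
        lon_centers=np.array([-3.0, -2.0]), lat_centers=np.array([50.0, 51.0]),
        bathymetry=np.array([[50.0, 50.0], [-10.0, -10.0]]),
        tide_amplitude=np.array([[1.0, 2.0], [0.0, 0.0]]),
        tide_phase=0.0 * ones, temp_mean=14.0 * ones,
        temp_seasonal_amplitude=0.0 * ones)
    fields.update(overrides)
    return tt.EnvironmentGrid(**fields)


def _obs(max_depth=50.0, temp=14.0, fit=None, rest=False, censored=False,
         low=False, d=date(2018, 7, 2)):
    from tidetrack.geolocation import DailyObservation
    return DailyObservation(
        date=d, max_depth=max_depth, max_depth_censored=censored,
        mean_temp=temp, rest_windows=([(0, 1)] if rest else []),
        tidal_fit=fit, n_samples=144, low_coverage=low)


class TestEmission:
    def test_tidal_amplitude_likelihood_ratio(self):
        from tidetrack.geolocation import TidalFit
        env2 = _two_cell_env()
        cfg = HMMConfig(components=("tide",))
        logL = emission_log_surface(_obs(fit=TidalFit(1.0, 0.0, 0.0)), env2, cfg)
        ratio = math.exp(logL[0, 0] - logL[0, 1])
        assert ratio == pytest.approx(math.exp(1.0 / (2 * cfg.sigma_amp ** 2)))

    def test_temperature_only_uniform_field_is_flat(self):
        env2 = _two_cell_env()
        logL = emission_log_surface(_obs(low=True), env2, HMMConfig())
        sea_vals = logL[env2.sea]
        assert np.allclose(sea_vals, sea_vals[0])
        assert np.isneginf(logL[~env2.sea]).all()

    def test_impossible_observation_warns_and_uniform(self):
        env2 = _two_cell_env(temp_mean=np.full((2, 2), 30.0))
        cfg = HMMConfig(sigma_temp=1e-4, components=("temp",))
        with pytest.warns(UserWarning, match="impossible"):
            logL = emission_log_surface(_obs(temp=14.0), env2, cfg)
        assert np.allclose(np.exp(logL[env2.sea]), 0.5)

    def test_excess_depth_penalised_half_normally(self):
        env2 = _two_cell_env(bathymetry=np.array([[50.0, 60.0],
                                                  [-10.0, -10.0]]))
        cfg = HMMConfig(components=("bathy",))
        logL = emission_log_surface(_obs(max_depth=58.0), env2, cfg)
        assert logL[0, 1] == 0.0
        assert logL[0, 0] == pytest.approx(-(8.0 ** 2) / (2 * cfg.sigma_bathy ** 2))


class TestDiffuse:
    def test_zero_diffusivity_is_identity(self, all_sea_env):
        p = np.zeros((41, 41))
        p[20, 20] = 1.0
        assert np.array_equal(diffuse(p, 0.0, all_sea_env), p)

    def test_mass_conserved(self, all_sea_env):
        p = np.zeros((41, 41))
        p[20, 20] = 1.0
        out = diffuse(p, 30.0, all_sea_env)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_variance_grows_linearly_with_steps(self, all_sea_env):
        p = np.zeros((41, 41))
        p[20, 20] = 1.0
        D, k = 8.0, 4
        for _ in range(k):
            p = diffuse(p, D, all_sea_env)
        lat_km = all_sea_env.lat_centers * KM_PER_DEG_LAT
        mu = (p.sum(axis=1) * lat_km).sum()
        var = (p.sum(axis=1) * (lat_km - mu) ** 2).sum()
        assert var == pytest.approx(k * 2 * D, rel=0.05)

    def test_kernel_wider_than_grid_rejected(self, all_sea_env):
        p = np.full((41, 41), 1 / 41 ** 2)
        with pytest.raises(ValueError, match="wider"):
            diffuse(p, 50000.0, all_sea_env)


def _single_sea_env():
    """2x2 grid with one sea cell: the degenerate state space."""
    ones = np.ones((2, 2))
    bathy = np.array([[50.0, -5.0], [-5.0, -5.0]])
    return tt.EnvironmentGrid(
        lon_centers=np.array([-3.0, -2.0]), lat_centers=np.array([50.0, 51.0]),
        bathymetry=bathy, tide_amplitude=ones, tide_phase=0.0 * ones,
        temp_mean=14.0 * ones, temp_seasonal_amplitude=0.0 * ones)


class TestForwardBackward:
    def test_single_sea_cell_evidence_is_sum_of_emission_logs(self):
        env1 = _single_sea_env()
        cfg = HMMConfig(diffusivities=(1.0, 5.0))
        obs_seq = [_obs(max_depth=50.0 + k, d=date(2018, 7, 1 + k))
                   for k in range(5)]
        fr = forward_filter(obs_seq, env1, cfg, (50.0, -3.0))
        expected = sum(emission_log_surface(o, env1, cfg)[0, 0] for o in obs_seq)
        assert fr.log_evidence == pytest.approx(expected)
        for a in fr.filtered:
            assert a.sum(axis=0)[0, 0] == pytest.approx(1.0)

    def test_uniform_emissions_reduce_to_pure_diffusion(self, all_sea_env):
        cfg = HMMConfig(diffusivities=(50.0, 50.0 + 1e-9))
        obs_seq = [_obs(temp=float("nan"), low=True, d=date(2018, 7, 1 + k))
                   for k in range(4)]
        lat, lon = 50.5, -3.0
        fr = forward_filter(obs_seq, all_sea_env, cfg, (lat, lon))
        p = np.zeros((41, 41))
        p[all_sea_env.cell_index(lat, lon)] = 1.0
        for k in range(1, 4):
            p = diffuse(p, 50.0, all_sea_env)
            np.testing.assert_allclose(fr.filtered[k].sum(axis=0), p, atol=1e-7)

    def test_smoothing_identities_and_normalisation(self, env):
        cfg = HMMConfig()
        tr = tt.simulate_track(env, seed=21, n_days=25)
        s = tt.simulate_dst(tr, env, tt.BehaviourSpec(), seed=22)
        obs = summarise_day(s, cfg)
        fr = forward_filter(obs, env, cfg, tr.release[:2], tr.recapture[:2])
        pt = backward_smooth(fr, env, cfg)
        # final-day smoothed equals filtered
        np.testing.assert_allclose(pt.position_marginals[-1],
                                   fr.filtered[-1].sum(axis=0), atol=1e-12)
        # day-0 smoothed marginal is the release delta
        m0 = pt.position_marginals[0]
        assert m0[fr.release_cell] == pytest.approx(1.0)
        # anchored final position is the recapture cell
        ri, rj = fr.recapture_cell
        assert (pt.track.iloc[-1]["lat"], pt.track.iloc[-1]["lon"]) == \
            env.cell_center(ri, rj)
        for marg in pt.position_marginals:
            assert marg.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(marg[~env.sea] == 0.0)

    def test_zero_normaliser_reports_day(self):
        env1 = _single_sea_env()
        cfg = HMMConfig(diffusivities=(1.0, 5.0))
        obs_seq = [_obs(d=date(2018, 7, 1)),
                   _obs(d=date(2018, 7, 2), censored=False)]
        fr = forward_filter(obs_seq, env1, cfg, (50.0, -3.0),
                            recapture=(50.0, -3.0))
        assert fr.recapture_cell == (0, 0)


class TestSelection:
    def test_single_candidate_returned(self, env):
        cfg = HMMConfig()
        obs_seq = [_obs(d=date(2018, 7, 1 + k)) for k in range(3)]
        lat, lon = tt.synthetic_world.default_release(env)
        best, table = select_diffusivities(obs_seq, env, cfg, [(30.0, 750.0)],
                                           (lat, lon))
        assert best == (30.0, 750.0)
        assert len(table) == 1

    def test_evidence_table_finite_and_generating_pair_competitive(self, env):
        cfg = HMMConfig()
        tr = tt.simulate_track(env, seed=31, n_days=30)
        s = tt.simulate_dst(tr, env, tt.BehaviourSpec(), seed=32)
        obs = summarise_day(s, cfg)
        cands = [(3.0, 75.0), (30.0, 750.0), (10.0, 250.0), (60.0, 1000.0)]
        best, table = select_diffusivities(obs, env, cfg, cands, tr.release[:2])
        assert np.isfinite(table["log_evidence"]).all()
        assert best in cands


def test_viterbi_path_starts_at_release_and_stays_at_sea(env):
    cfg = HMMConfig()
    tr = tt.simulate_track(env, seed=41, n_days=15)
    s = tt.simulate_dst(tr, env, tt.BehaviourSpec(), seed=42)
    obs = summarise_day(s, cfg)
    path = viterbi_path(obs, env, cfg, tr.release[:2], tr.recapture[:2])
    assert len(path) == 15
    assert (path.iloc[0]["lat"], path.iloc[0]["lon"]) == tuple(
        env.cell_center(*env.cell_index(*tr.release[:2])))
    for _, r in path.iterrows():
        assert env.is_sea(r["lat"], r["lon"])
    # anchored end
    qi, qj = env.cell_index(*tr.recapture[:2])
    assert (path.iloc[-1]["lat"], path.iloc[-1]["lon"]) == env.cell_center(qi, qj)
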