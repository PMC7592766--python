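"""Vertical speed, seabed proximity, DVM classification, Welch tests."""

import itertools
import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import tidetrack as tt
from tidetrack.vertical_metrics import (_exact_rank_p, monthly_summaries,
                                        cross_fish_monthly, rank_sum_p)

from conftest import make_series


def oracle_rank_p(x, y):
    """Brute-force two-sided rank-sum p: enumerate every way of assigning
    the pooled multiset to the two groups and count rank sums at least as
    deviant as observed."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    mu = n1 * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    combos = np.array(list(itertools.combinations(range(len(pooled)), n1)))
    sums = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(sums - mu) >= obs - 1e-9))


class TestVerticalSpeeds:
    def test_definition_on_simple_steps(self):
        s = make_series([10.0, 13.0], interval_s=30.0)
        assert tt.vertical_speeds(s)[1] == pytest.approx(6.0)

    def test_constant_depth_gives_zero(self):
        s = make_series(np.full(10, 25.0))
        assert np.nansum(tt.vertical_speeds(s)) == 0.0

    def test_ten_minute_sampling_example(self):
        s = make_series([20.0, 26.0, 23.0], interval_s=600.0)
        speeds = tt.vertical_speeds(s)
        assert np.isnan(speeds[0])
        assert speeds[1] == pytest.approx(0.6)
        assert speeds[2] == pytest.approx(0.3)

    def test_gap_longer_than_three_intervals_yields_no_speed(self):
        df = make_series([10.0, 11.0, 12.0], interval_s=600.0).samples
        df.loc[2, "timestamp"] += pd.Timedelta(hours=2)
        s = tt.DepthTempSeries("g", df, 600.0, 600.0)
        speeds = tt.vertical_speeds(s)
        assert np.isnan(speeds[2]) and not np.isnan(speeds[1])


def _labeled_cycle(day_depths, night_depths, d=date(2018, 7, 2)):
    """Minimal labelled frame: one cycle with given day and night depths."""
    nd, nn = len(day_depths), len(night_depths)
    f_day = min(600, int(10 * 3600 / max(nd, 1)))
    f_night = min(600, int(2 * 3600 / max(nn, 1)))
    ts_day = pd.date_range(f"{d}T09:00:00Z", periods=nd, freq=f"{f_day}s")
    ts_night = pd.date_range(f"{d}T21:00:00Z", periods=nn, freq=f"{f_night}s")
    df = pd.DataFrame({
        "timestamp": ts_day.append(ts_night),
        "depth": np.concatenate([day_depths, night_depths]),
        "temperature": 12.0,
        "censored": False,
        "diel_label": ["day"] * nd + ["night"] * nn,
        "cycle_date": d,
    })
    return df.sort_values("timestamp").reset_index(drop=True)


class TestSeabedProximity:
    def _metrics(self, labeled, threshold=10.0):
        s = tt.DepthTempSeries("t", labeled[["timestamp", "depth",
                                             "temperature", "censored"]],
                               600.0, 600.0)
        return tt.compute_daily_metrics(s, labeled, threshold)

    def test_constant_depth_day_gives_full_proximity(self):
        dm = self._metrics(_labeled_cycle([30.0] * 20, [30.0] * 20))
        assert dm.loc[0, "prox_day"] == 1.0
        assert dm.loc[0, "prox_night"] == 1.0

    def test_threshold_boundary_is_inclusive(self):
        dm = self._metrics(_labeled_cycle([50.0, 40.0, 20.0], [20.0] * 3))
        # proxy 50; 40 is near (boundary), 20 is not
        assert dm.loc[0, "seabed_proxy"] == 50.0
        assert dm.loc[0, "prox_day"] == pytest.approx(2 / 3)

    def test_counted_fraction_matches_construction(self):
        depths = np.concatenate([np.full(30, 95.0), np.full(70, 50.0)])
        rng = np.random.default_rng(1)
        rng.shuffle(depths)
        dm = self._metrics(_labeled_cycle(depths, [50.0] * 5))
        assert dm.loc[0, "prox_day"] == pytest.approx(0.30)

    @given(st.floats(-20, 200), st.integers(0, 2 ** 31 - 1))
    def test_proximity_invariant_to_depth_offset(self, shift, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(30, 80, 24)
        shifted = np.clip(base + shift, 0, None)
        if (shifted > 0).all() and shift > -30:  # keep strictly positive depths
            a = self._metrics(_labeled_cycle(base[:12], base[12:]))
            b = self._metrics(_labeled_cycle(shifted[:12], shifted[12:]))
            assert a.loc[0, "prox_day"] == b.loc[0, "prox_day"]
            assert a.loc[0, "prox_night"] == b.loc[0, "prox_night"]

    def test_censored_proxy_flagged_as_lower_bound(self):
        labeled = _labeled_cycle([100.0, 60.0, 50.0], [40.0] * 3)
        labeled.loc[labeled["depth"].idxmax(), "censored"] = True
        dm = self._metrics(labeled)
        assert bool(dm.loc[0, "proxy_censored"])


class TestClassifyDay:
    def test_identical_multisets_are_nvm_with_p_one(self):
        b = tt.classify_day([10, 20, 30, 40, 50], [10, 20, 30, 40, 50])
        assert b.label == "nVM" and b.p_value == 1.0

    def test_separated_groups_give_exact_small_p_and_dvm(self):
        b = tt.classify_day([60, 61, 62, 63, 64], [20, 21, 22, 23, 24])
        assert b.label == "DVM"
        assert b.p_value == pytest.approx(2 / 252)

    def test_swapping_labels_gives_rdvm_with_same_p(self):
        a = tt.classify_day([60, 61, 62, 63, 64], [20, 21, 22, 23, 24])
        b = tt.classify_day([20, 21, 22, 23, 24], [60, 61, 62, 63, 64])
        assert b.label == "rDVM" and b.p_value == a.p_value

    def test_small_samples_are_unclassified(self):
        b = tt.classify_day([60, 61], [20, 21])
        assert b.label == "unclassified" and math.isnan(b.p_value)

    def test_exact_p_matches_scipy_when_untied(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(3, 9, 2)
            pooled = rng.permutation(np.arange(40.0))[: n1 + n2]
            x, y = pooled[:n1], pooled[n1:]
            ours = _exact_rank_p(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_exact_p_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1, n2 = rng.integers(2, 7, 2)
            x = rng.integers(1, 9, n1).astype(float)
            y = rng.integers(1, 9, n2).astype(float)
            assert _exact_rank_p(x, y) == pytest.approx(oracle_rank_p(x, y),
                                                        abs=1e-12)

    def test_asymptotic_branch_used_for_large_samples(self):
        rng = np.random.default_rng(2)
        x = rng.normal(50, 5, 60)
        y = rng.normal(35, 5, 60)
        p = rank_sum_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestMonthlySummaries:
    def _frames(self, labels, metric_value=0.2):
        days = [date(2018, 7, k + 1) for k in range(len(labels))]
        dm = pd.DataFrame({
            "date": days, "seabed_proxy": 50.0, "proxy_censored": False,
            **{c: metric_value for c in ("vspeed_day", "vspeed_night",
                                         "prox_day", "prox_night", "depth_day",
                                         "depth_night", "temp_day", "temp_night")},
            "n_day": 30, "n_night": 30})
        db = pd.DataFrame({"date": days, "label": labels, "p_value": 0.01,
                           "median_day_depth": 50.0, "median_night_depth": 40.0})
        return dm, db

    def test_constant_metric_gives_mean_and_zero_sd(self):
        dm, db = self._frames(["DVM"] * 10, metric_value=0.37)
        ms = monthly_summaries(dm, db, "T1")
        assert ms.loc[0, "prox_day_mean"] == pytest.approx(0.37)
        assert ms.loc[0, "prox_day_sd"] == 0.0

    def test_behaviour_proportions(self):
        dm, db = self._frames(["DVM"] * 16 + ["rDVM"] * 3 + ["nVM"])
        ms = monthly_summaries(dm, db, "T1")
        assert ms.loc[0, "prop_dvm"] == pytest.approx(0.80)
        assert ms.loc[0, "prop_rdvm"] == pytest.approx(0.15)
        assert ms.loc[0, "prop_nvm"] == pytest.approx(0.05)

    def test_unclassified_days_excluded_from_proportions(self):
        dm, db = self._frames(["DVM"] * 3 + ["unclassified"] * 7)
        ms = monthly_summaries(dm, db, "T1")
        assert ms.loc[0, "prop_dvm"] == 1.0

    def test_cross_fish_mean_is_unweighted(self):
        dm1, db1 = self._frames(["DVM"] * 5, metric_value=0.1)
        dm2, db2 = self._frames(["DVM"] * 25, metric_value=0.3)
        ms = pd.concat([monthly_summaries(dm1, db1, "A"),
                        monthly_summaries(dm2, db2, "B")], ignore_index=True)
        cf = cross_fish_monthly(ms)
        assert cf.loc[0, "prox_day_mean"] == pytest.approx(0.2)

    def test_monthly_speed_mean_bounded_by_max_sample_speed(self):
        rng = np.random.default_rng(3)
        depths = np.abs(np.cumsum(rng.normal(0, 2, 5 * 144))) + 10
        s = make_series(depths, interval_s=600.0)
        speeds = tt.vertical_speeds(s)
        labeled = s.samples.copy()
        labeled["diel_label"] = np.where(np.arange(len(labeled)) % 2, "day", "night")
        labeled["cycle_date"] = labeled["timestamp"].dt.date
        dm = tt.compute_daily_metrics(s, labeled)
        assert dm[["vspeed_day", "vspeed_night"]].max().max() <= np.nanmax(speeds)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = tt.welch_day_night_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_shifted_equal_variance_closed_form(self):
        t, df, p = tt.welch_day_night_test([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert abs(t) == pytest.approx(10 / math.sqrt(2 / 3))
        assert df == pytest.approx(4.0)

    def test_fractional_degrees_of_freedom(self):
        # unequal variances, n1 = n2 = 31: Welch df is fractional, < 60
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1.0, 31)
        y = rng.normal(0, 2.5, 31)
        t, df, p = tt.welch_day_night_test(x, y)
        vx, vy = x.var(ddof=1) / 31, y.var(ddof=1) / 31
        df_oracle = (vx + vy) ** 2 / (vx ** 2 / 30 + vy ** 2 / 30)
        assert df == pytest.approx(df_oracle)
        assert df != int(df)

    def test_requires_two_values_per_group(self):
        with pytest.raises(ValueError):
            tt.welch_day_night_test([1.0], [1.0, 2.0])
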