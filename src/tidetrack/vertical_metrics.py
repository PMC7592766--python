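"""Per-day vertical-behaviour metrics and day-vs-night statistics.

The seabed is not observed directly by an archival tag, so each 24-h
cycle's maximum recorded depth serves as a seabed proxy; "time near the
seabed" is the fraction of samples within a threshold (default 10 m) of
that proxy.  Each cycle is classified DVM / rDVM / nVM by a two-sample
rank-sum test between its day-labelled and night-labelled depths:
significantly deeper by day is diel vertical migration (DVM), the reverse
is rDVM, and a non-significant test is nVM.  Headline day-vs-night
contrasts on fish-month means use Welch's unequal-variance t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dst_io import DepthTempSeries

#: largest per-group size for which the exact permutation null is used
EXACT_MAX_N = 12


def vertical_speeds(series: DepthTempSeries) -> np.ndarray:
    """Per-sample vertical speed (m/min): |depth step| / elapsed minutes.

    The speed is attached to the later sample of each pair; the first
    sample, and any sample following a gap longer than 3x the nominal
    interval, gets NaN.
    """
    df = series.samples
    if len(df) < 2:
        raise ValueError("need at least 2 samples")
    dt_min = df["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
    dd = np.abs(df["depth"].diff().to_numpy())
    speed = dd / dt_min
    gap_limit = 3.0 * series.nominal_depth_interval / 60.0
    speed[dt_min > gap_limit] = np.nan
    return speed


@dataclass
class DailyBehaviour:
    """One cycle's vertical-migration classification."""

    date: Optional[date]
    label: str  # "DVM" | "rDVM" | "nVM" | "unclassified"
    p_value: float
    median_day_depth: float
    median_night_depth: float


def _exact_rank_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum statistic.

    Enumerates the permutation null of the group-1 rank sum over all
    ways of splitting the pooled (possibly tied) multiset, via a
    subset-sum dynamic programme over doubled midranks, and returns
    P(|R1 - E[R1]| >= observed).  Handles ties exactly.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    r2 = np.rint(stats.rankdata(pooled) * 2).astype(int)  # doubled midranks
    r1_obs = int(r2[:n1].sum())
    # counts[k][s] = number of size-k subsets with doubled-rank-sum s
    counts: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    counts[0][0] = 1
    for v in r2:
        for k in range(min(n1, len(counts) - 1) - 1, -1, -1):
            tgt = counts[k + 1]
            for s, c in counts[k].items():
                tgt[s + v] = tgt.get(s + v, 0) + c
    dist = counts[n1]
    total = sum(dist.values())
    mu2 = n1 * (n1 + n2 + 1)  # doubled E[R1]
    dev = abs(r1_obs - mu2)
    hits = sum(c for s, c in dist.items() if abs(s - mu2) >= dev)
    return hits / total


def rank_sum_p(day_depths: Sequence[float], night_depths: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p: exact permutation null when both groups
    have at most 12 samples, else the tie-corrected normal approximation
    with continuity correction."""
    x = np.asarray(day_depths, dtype=float)
    y = np.asarray(night_depths, dtype=float)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_rank_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else min(p, 1.0)


def classify_day(day_depths: Sequence[float], night_depths: Sequence[float],
                 alpha: float = 0.05, min_n: int = 5,
                 day: Optional[date] = None) -> DailyBehaviour:
    """Classify one 24-h cycle as DVM, rDVM or nVM.

    ``p <= alpha`` with the day median deeper than the night median is DVM;
    the reverse is rDVM; a non-significant test is nVM.  Cycles with fewer
    than ``min_n`` samples in either period — or the degenerate case of a
    significant test with equal medians — are left unclassified rather than
    silently counted as nVM.
    """
    x = np.asarray(day_depths, dtype=float)
    y = np.asarray(night_depths, dtype=float)
    med_d = float(np.median(x)) if len(x) else float("nan")
    med_n = float(np.median(y)) if len(y) else float("nan")
    if len(x) < min_n or len(y) < min_n:
        return DailyBehaviour(day, "unclassified", float("nan"), med_d, med_n)
    p = rank_sum_p(x, y)
    if p > alpha:
        label = "nVM"
    elif med_d > med_n:
        label = "DVM"
    elif med_d < med_n:
        label = "rDVM"
    else:
        label = "unclassified"
    return DailyBehaviour(day, label, p, med_d, med_n)


def compute_daily_metrics(series: DepthTempSeries, labeled: pd.DataFrame,
                          threshold: float = 10.0) -> pd.DataFrame:
    """Per-cycle metrics: seabed proxy, day/night vertical-speed means,
    day/night near-seabed fractions, day/night depth and temperature means.

    ``labeled`` is the output of :func:`tidetrack.diel.label_samples` on
    this series.  The seabed proxy is the maximum depth over the civil day
    (all samples, crepuscular included); it is flagged as a lower bound when
    the deepest sample is censored.  Day/night statistics use only the
    day- and night-labelled samples of the cycle, and a sample is "near the
    seabed" iff ``proxy - depth <= threshold`` (inclusive).
    """
    df = labeled.copy()
    df["speed"] = vertical_speeds(series)
    civil = df["timestamp"].dt.date
    proxy = df.groupby(civil)["depth"].max()
    cens_at_max = df.groupby(civil).apply(
        lambda g: bool(g.loc[g["depth"].idxmax(), "censored"]),
        include_groups=False)

    rows = []
    for d in sorted(set(df["cycle_date"])):
        if d not in proxy.index:
            continue  # cycle with no samples on its own civil day
        px = float(proxy[d])
        cyc = df[df["cycle_date"] == d]
        day_s = cyc[cyc["diel_label"] == "day"]
        night_s = cyc[cyc["diel_label"] == "night"]
        near_day = (px - day_s["depth"]) <= threshold
        near_night = (px - night_s["depth"]) <= threshold
        rows.append({
            "date": d,
            "seabed_proxy": px,
            "proxy_censored": bool(cens_at_max[d]),
            "vspeed_day": float(day_s["speed"].mean()),
            "vspeed_night": float(night_s["speed"].mean()),
            "prox_day": float(near_day.mean()) if len(day_s) else float("nan"),
            "prox_night": float(near_night.mean()) if len(night_s) else float("nan"),
            "depth_day": float(day_s["depth"].mean()),
            "depth_night": float(night_s["depth"].mean()),
            "temp_day": float(day_s["temperature"].mean()),
            "temp_night": float(night_s["temperature"].mean()),
            "n_day": int(len(day_s)),
            "n_night": int(len(night_s)),
        })
    return pd.DataFrame(rows)


def compute_daily_behaviour(labeled: pd.DataFrame, alpha: float = 0.05,
                            min_n: int = 5) -> pd.DataFrame:
    """Classify every cycle in a labelled series; one row per cycle date."""
    rows = []
    for d in sorted(set(labeled["cycle_date"])):
        cyc = labeled[labeled["cycle_date"] == d]
        b = classify_day(cyc.loc[cyc["diel_label"] == "day", "depth"].to_numpy(),
                         cyc.loc[cyc["diel_label"] == "night", "depth"].to_numpy(),
                         alpha=alpha, min_n=min_n, day=d)
        rows.append({"date": d, "label": b.label, "p_value": b.p_value,
                     "median_day_depth": b.median_day_depth,
                     "median_night_depth": b.median_night_depth})
    return pd.DataFrame(rows)


_METRICS = ("depth_day", "depth_night", "temp_day", "temp_night",
            "vspeed_day", "vspeed_night", "prox_day", "prox_night")


def monthly_summaries(daily_metrics: pd.DataFrame, daily_behaviour: pd.DataFrame,
                      tag_id: str) -> pd.DataFrame:
    """Per-tag per-calendar-month means and sds of each metric, plus
    behaviour-label proportions over the month's classified days.

    Months with zero classified days get missing proportions rather than
    zeros.
    """
    dm = daily_metrics.copy()
    dm["month"] = pd.PeriodIndex([pd.Timestamp(d) for d in dm["date"]], freq="M")
    db = daily_behaviour.copy()
    db["month"] = pd.PeriodIndex([pd.Timestamp(d) for d in db["date"]], freq="M")

    rows = []
    for month, g in dm.groupby("month"):
        row = {"tag_id": tag_id, "month": str(month), "n_days": len(g)}
        for m in _METRICS:
            row[f"{m}_mean"] = float(g[m].mean())
            row[f"{m}_sd"] = float(g[m].std(ddof=1))
        gb = db[db["month"] == month]
        classified = gb[gb["label"].isin(["DVM", "rDVM", "nVM"])]
        if len(classified):
            for lbl, col in (("DVM", "prop_dvm"), ("rDVM", "prop_rdvm"),
                             ("nVM", "prop_nvm")):
                row[col] = float((classified["label"] == lbl).mean())
        else:
            row.update(prop_dvm=float("nan"), prop_rdvm=float("nan"),
                       prop_nvm=float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def cross_fish_monthly(summaries: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over fish present in each month (the cross-fish
    monthly figure)."""
    value_cols = [c for c in summaries.columns if c not in ("tag_id", "month")]
    return (summaries.groupby("month")[value_cols]
            .mean().reset_index())


def welch_day_night_test(day_values: Sequence[float],
                         night_values: Sequence[float],
                         ) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test on fish-month means.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite fractional degrees
    of freedom and a two-sided p.  Both-groups-constant with equal means
    yields ``(0, n1 + n2 - 2, 1)``.
    """
    x = np.asarray(day_values, dtype=float)
    y = np.asarray(night_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, float(len(x) + len(y) - 2), 1.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
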