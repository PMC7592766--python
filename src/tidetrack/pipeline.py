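"""End-to-end orchestration: synthetic world -> conditioning -> geolocation
-> diel labelling -> vertical metrics -> dispersal, with a run manifest.

A run is fully described by a :class:`RunConfig` (YAML-loadable) and a
seed; given both, every output file is reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dst_io import (DepthTempSeries, downsample_series, flag_sensor_saturation,
                     read_deployments_csv, read_dst_csv, trim_surface_drift,
                     write_deployments_csv, write_series_csv)
from .diel import label_samples
from .dispersal import (daily_distances, make_dispersal_records,
                        recapture_summary, return_rate)
from .environment import EnvironmentGrid
from .geolocation import HMMConfig, geolocate, summarise_day
from .synthetic_world import (BehaviourSpec, make_environment,
                              simulate_dst, simulate_mark_recapture,
                              simulate_track)
from .vertical_metrics import (compute_daily_behaviour, compute_daily_metrics,
                               cross_fish_monthly, monthly_summaries,
                               welch_day_night_test)

log = logging.getLogger("tidetrack")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world used when no real inputs are given."""

    nx: int = 25
    ny: int = 25
    extent: tuple[float, float, float, float] = (-5.0, -1.0, 49.0, 52.0)
    n_tags: int = 2
    n_days: int = 60
    n_mark_recapture: int = 300
    p_recapture: float = 0.3
    sampling_interval: float = 600.0


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic`` or real-input paths (``dst_paths`` +
    ``deployments_path`` + ``env_dir``) must be provided; the seed is
    mandatory for synthetic runs.
    """

    seed: int = 0
    output_dir: str = "tidetrack_out"
    synthetic: Optional[SyntheticSpec] = None
    dst_paths: list[str] = field(default_factory=list)
    deployments_path: Optional[str] = None
    env_dir: Optional[str] = None
    sensor_ceiling: Optional[float] = 100.0
    resolution_s: float = 600.0
    diel_buffer_h: float = 1.0
    proximity_threshold_m: float = 10.0
    alpha: float = 0.05
    min_n: int = 5
    hmm: HMMConfig = field(default_factory=HMMConfig)
    behaviour: BehaviourSpec = field(default_factory=BehaviourSpec)
    anchor_recapture: bool = True

    def validate(self) -> None:
        has_real = bool(self.dst_paths or self.deployments_path or self.env_dir)
        if self.synthetic is not None and has_real:
            raise ValueError("config must give either synthetic parameters or "
                             "real input paths, not both")
        if self.synthetic is None and not has_real:
            raise ValueError("config gives neither synthetic parameters nor "
                             "real input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "extent" in syn:
                syn["extent"] = tuple(syn["extent"])
            raw["synthetic"] = SyntheticSpec(**syn)
        if "hmm" in raw:
            hmm = dict(raw["hmm"])
            if "diffusivities" in hmm:
                hmm["diffusivities"] = tuple(hmm["diffusivities"])
            if "switch_matrix" in hmm:
                hmm["switch_matrix"] = np.asarray(hmm["switch_matrix"], dtype=float)
            if "components" in hmm:
                hmm["components"] = tuple(hmm["components"])
            raw["hmm"] = HMMConfig(**hmm)
        if "behaviour" in raw:
            raw["behaviour"] = BehaviourSpec(**raw["behaviour"])
        return cls(**raw)


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    hmm = d["hmm"]
    hmm["switch_matrix"] = np.asarray(hmm["switch_matrix"]).tolist()
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all outputs plus a run manifest.

    Returns the manifest (also written to ``manifest.json``).  Stage
    failures abort with the stage name in the exception message.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    manifest: dict = {
        "tidetrack_version": __version__,
        "python": platform.python_version(),
        "seed": rng_seed,
        "config": _config_echo(config),
        "stages": {},
    }

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.synthetic is not None:
            syn = config.synthetic
            env = make_environment(rng_seed, nx=syn.nx, ny=syn.ny,
                                   extent=syn.extent)
            env.to_dir(out / "environment")
            spec = BehaviourSpec(**{**asdict(config.behaviour),
                                    "sampling_interval": syn.sampling_interval})
            tags: dict[str, DepthTempSeries] = {}
            tracks = {}
            for k in range(syn.n_tags):
                tag_id = f"DST{k:03d}"
                track = simulate_track(env, config.hmm.diffusivities,
                                       config.hmm.switch_matrix,
                                       seed=rng_seed + 1000 + k,
                                       n_days=syn.n_days)
                series = simulate_dst(track, env, spec, seed=rng_seed + 2000 + k,
                                      tag_id=tag_id,
                                      sensor_ceiling=config.sensor_ceiling)
                tags[tag_id] = series
                tracks[tag_id] = track
            deployments = simulate_mark_recapture(
                env, n=syn.n_mark_recapture, p_recapture=syn.p_recapture,
                seed=rng_seed + 3000)
            write_deployments_csv(deployments, out / "deployments.csv")
        else:
            env = EnvironmentGrid.from_dir(config.env_dir) if config.env_dir else None
            tags = {Path(p).stem: read_dst_csv(p, config.sensor_ceiling)
                    for p in config.dst_paths}
            tracks = {}
            deployments = (read_deployments_csv(config.deployments_path)
                           if config.deployments_path else [])
        manifest["stages"][stage] = {"n_tags": len(tags),
                                     "n_deployments": len(deployments)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: conditioning ------------------------------------------
    stage = "conditioning"
    try:
        conditioned: dict[str, DepthTempSeries] = {}
        for tag_id, series in tags.items():
            s = downsample_series(series, config.resolution_s)
            s = trim_surface_drift(s)
            frac, _ = flag_sensor_saturation(s)
            write_series_csv(s, out / f"{tag_id}_conditioned.csv")
            conditioned[tag_id] = s
            log.info("tag %s: %d samples, censored fraction %.4f",
                     tag_id, len(s), frac)
        manifest["stages"][stage] = {
            tag: len(s) for tag, s in conditioned.items()}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: geolocation -------------------------------------------
    stage = "geolocation"
    posterior_tracks = {}
    try:
        if env is not None:
            for tag_id, s in conditioned.items():
                if len(s) == 0:
                    continue
                obs = summarise_day(s, config.hmm)
                if config.synthetic is not None:
                    release = tracks[tag_id].release[:2]
                    recapture = (tracks[tag_id].recapture[:2]
                                 if config.anchor_recapture else None)
                else:
                    dep = next((d for d in deployments if d.tag_id == tag_id), None)
                    if dep is None:
                        continue
                    release = dep.release[:2]
                    recapture = (dep.recapture[:2]
                                 if config.anchor_recapture and dep.recapture
                                 else None)
                pt = geolocate(obs, env, config.hmm, release, recapture)
                posterior_tracks[tag_id] = pt
                pt.track.to_csv(out / f"{tag_id}_track.csv", index=False)
                _write_geojson(pt.track, out / f"{tag_id}_track.geojson")
        manifest["stages"][stage] = {
            tag: {"n_days": len(pt.track),
                  "log_evidence": pt.log_evidence,
                  "mean_spread_km": float(pt.track["spread_km"].mean())}
            for tag, pt in posterior_tracks.items()}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: behaviour ---------------------------------------------
    stage = "behaviour"
    try:
        all_metrics, all_behaviour, all_monthly = [], [], []
        for tag_id, s in conditioned.items():
            if len(s) < 2:
                continue
            if tag_id in posterior_tracks:
                positions = posterior_tracks[tag_id].track[["date", "lat", "lon"]]
            elif config.synthetic is not None:
                positions = tracks[tag_id].positions[["date", "lat", "lon"]]
            else:
                dep = next((d for d in deployments if d.tag_id == tag_id), None)
                if dep is None:
                    continue
                dates = sorted(set(s.dates))
                positions = pd.DataFrame(
                    {"date": dates, "lat": dep.release[0], "lon": dep.release[1]})
            labeled = label_samples(s.samples, positions, config.diel_buffer_h)
            dm = compute_daily_metrics(s, labeled, config.proximity_threshold_m)
            db = compute_daily_behaviour(labeled, config.alpha, config.min_n)
            dm["tag_id"] = tag_id
            db["tag_id"] = tag_id
            all_metrics.append(dm)
            all_behaviour.append(db)
            all_monthly.append(monthly_summaries(dm, db, tag_id))
        metrics_df = pd.concat(all_metrics, ignore_index=True) if all_metrics \
            else pd.DataFrame()
        behaviour_df = pd.concat(all_behaviour, ignore_index=True) if all_behaviour \
            else pd.DataFrame()
        monthly_df = pd.concat(all_monthly, ignore_index=True) if all_monthly \
            else pd.DataFrame()
        metrics_df.to_csv(out / "daily_metrics.csv", index=False)
        behaviour_df.to_csv(out / "daily_behaviour.csv", index=False)
        monthly_df.to_csv(out / "monthly_summary.csv", index=False)
        if len(monthly_df):
            cross_fish_monthly(monthly_df).to_csv(out / "monthly_cross_fish.csv",
                                                  index=False)
        tests = []
        for metric in ("depth", "temp", "vspeed", "prox"):
            day_col, night_col = f"{metric}_day_mean", f"{metric}_night_mean"
            if len(monthly_df) and day_col in monthly_df:
                d = monthly_df[day_col].dropna()
                n = monthly_df[night_col].dropna()
                if len(d) >= 2 and len(n) >= 2:
                    t, df_, p = welch_day_night_test(d, n)
                    tests.append({"metric": metric, "t": t, "df": df_, "p": p})
        pd.DataFrame(tests).to_csv(out / "tests.csv", index=False)
        manifest["stages"][stage] = {
            "n_cycles": int(len(behaviour_df)),
            "n_monthly_rows": int(len(monthly_df)),
            "behaviour_counts": (behaviour_df["label"].value_counts().to_dict()
                                 if len(behaviour_df) else {}),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: dispersal ---------------------------------------------
    stage = "dispersal"
    try:
        records, excluded = make_dispersal_records(deployments)
        records.to_csv(out / "dispersal.csv", index=False)
        summaries = []
        for grouping in ("none", "sex", "condition"):
            g = recapture_summary(records, grouping)
            g.insert(0, "grouping", grouping)
            summaries.append(g)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "group_summary.csv", index=False)
        n_released = len(deployments)
        n_returned = int(len(records)) + excluded
        daily = {}
        for tag_id, pt in posterior_tracks.items():
            dd = daily_distances(pt.track)
            daily[tag_id] = float(dd.mean())
        manifest["stages"][stage] = {
            "n_released": n_released,
            "n_returned": n_returned,
            "return_rate_pct": (return_rate(n_returned, n_released)
                                if n_released else None),
            "excluded_no_position": excluded,
            "mean_daily_distance_km": daily,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def _write_geojson(track: pd.DataFrame, path: Path) -> None:
    coords = [[float(r["lon"]), float(r["lat"])] for _, r in track.iterrows()]
    gj = {"type": "Feature",
          "geometry": {"type": "LineString", "coordinates": coords},
          "properties": {"dates": [str(d) for d in track["date"]]}}
    path.write_text(json.dumps(gj))


def demo_config(seed: int = 1, output_dir: str = "tidetrack_demo") -> RunConfig:
    """A small synthetic run that exercises every stage in well under five
    minutes."""
    return RunConfig(seed=seed, output_dir=output_dir,
                     synthetic=SyntheticSpec(n_tags=2, n_days=45,
                                             n_mark_recapture=300))
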