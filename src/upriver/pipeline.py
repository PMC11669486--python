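"""Config-driven orchestration of the full migration analysis.

Stages (in dependency order): ``synth`` → ``project`` → ``fates`` →
``survival`` / ``breakfit`` / ``trajectory`` → ``thermo``.  A single
top-level seed feeds named substreams per stage; every output is stamped
with the seed and a hash of the configuration, and the run manifest logs
the sample accounting at each filter so exclusions are auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fates as fates_mod
from . import segmented as seg_mod
from . import survival as surv_mod
from . import synth as synth_mod
from . import thermal as thermal_mod
from . import trajectory as traj_mod
from ._utils import config_hash
from .river import RiverNetwork, snap_track

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("upriver.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "upriver_out",
    "stages": {
        "synth": True,
        "project": True,
        "fates": True,
        "survival": True,
        "breakfit": True,
        "trajectory": True,
        "thermo": True,
    },
    "synth": {},  # SynthConfig field overrides
    "paths": {},  # river/tracks/temperatures for real-data runs
    "curve": {"T_opt": 17.6, "window_lower": 12.8, "window_upper": 20.8, "q": 0.9},
    "rmr": {"a": 0.707, "d": 0.088, "oxycal": 14.1},
    "scenario": {
        "departures": ["10-01", "10-06", "10-11", "10-16"],
        "duration_days": 10.0,
        "deltas": [0.0, 2.0, 4.0],
    },
    "trajectory": {"targets_km": [21.0, 54.0, 100.0]},
}


class PipelineConfig(dict):
    """Pipeline configuration; a dict with YAML loading and deep defaults."""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.with_defaults(yaml.safe_load(fh) or {})

    @classmethod
    def with_defaults(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = _deep_merge(DEFAULT_CONFIG, overrides or {})
        return cls(cfg)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the enabled stages and return the run manifest."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    else:
        config = PipelineConfig.with_defaults(config)
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    hashable = {k: v for k, v in config.items() if k != "outdir"}
    stamp = {"seed": seed, "config_hash": config_hash(hashable)}
    manifest: dict = {**stamp, "stages": {}, "counts": {}, "outputs": []}
    stages = config["stages"]
    state: dict = {}

    def emit_json(name: str, payload) -> None:
        with open(outdir / name, "w") as fh:
            json.dump({**stamp, **payload}, fh, indent=1, default=_jsonable)
        manifest["outputs"].append(name)

    def emit_csv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(outdir / name, index=False)
        manifest["outputs"].append(name)

    def require(stage: str, key: str):
        if key not in state:
            raise RuntimeError(
                f"stage '{stage}' requires output '{key}' from an upstream stage "
                "that did not run"
            )
        return state[key]

    # -- synth ---------------------------------------------------------------
    if stages.get("synth"):
        log.info("stage synth: generating river, temperatures and cohort")
        scfg = synth_mod.SynthConfig(seed=seed, **config["synth"])
        river = synth_mod.generate_river(scfg)
        years = sorted(
            {pd.Timestamp(d).year for d in scfg.departure_window} | {2016, 2017, 2018, 2019, 2020, 2021}
        )
        temps = synth_mod.generate_temperature_series(years, scfg)
        cohort = synth_mod.generate_cohort(river, temps, scfg)
        state.update(river=river, temps=temps, cohort=cohort, synth_config=scfg)
        river.to_geojson(outdir / "river.geojson")
        synth_mod.write_tracks_csv(cohort.tracks, outdir / "tracks.csv")
        synth_mod.write_temperature_csv(temps, outdir / "temperatures.csv")
        synth_mod.write_truth_json(cohort.truth, outdir / "truth.json")
        manifest["outputs"] += ["river.geojson", "tracks.csv", "temperatures.csv", "truth.json"]
        manifest["counts"]["fish_generated"] = scfg.n_fish
        manifest["stages"]["synth"] = "ok"
    elif config["paths"]:
        paths = config["paths"]
        if "river" in paths:
            state["river"] = RiverNetwork.from_geojson(paths["river"])
        if "tracks" in paths:
            tracks = pd.read_csv(paths["tracks"], parse_dates=["timestamp"])
            state["cohort"] = synth_mod.CohortData(
                tracks=tracks, loggers=pd.DataFrame(), truth=[]
            )
        if "temperatures" in paths:
            tdf = pd.read_csv(paths["temperatures"], parse_dates=["timestamp"])
            state["temps"] = tdf.set_index("timestamp")["temp_c"]

    # -- project -------------------------------------------------------------
    if stages.get("project"):
        river = require("project", "river")
        cohort = require("project", "cohort")
        tracks = cohort.tracks.copy()
        projected = snap_track(tracks, river)
        if "day" not in projected:
            grouped = projected.groupby("fish_id")["timestamp"]
            projected["day"] = (
                projected["timestamp"] - grouped.transform("min")
            ).dt.total_seconds() / 86400.0
        state["projected"] = projected
        emit_csv("projected_fixes.csv", projected.drop(columns=["chainage_obs_km"], errors="ignore"))
        manifest["counts"]["fixes_projected"] = len(projected)
        manifest["stages"]["project"] = "ok"

    # -- fates ---------------------------------------------------------------
    if stages.get("fates"):
        projected = require("fates", "projected")
        records = fates_mod.classify_cohort(projected)
        state["fate_records"] = records
        summary = fates_mod.summarize_fates(records)
        by_cat = summary.category_totals.to_dict()
        log.info("fate classification: %s", by_cat)
        emit_csv(
            "fates.csv",
            pd.DataFrame(
                [
                    {
                        "fish_id": r.fish_id,
                        "category": r.category,
                        "subcategory": r.subcategory,
                        "month": r.month,
                        "last_day": r.last_day,
                        "last_chainage_km": r.last_chainage_km,
                    }
                    for r in records
                ]
            ),
        )
        emit_json(
            "fate_summary.json",
            {
                "category_totals": by_cat,
                "recapture_rate_percent": summary.recapture_rate_percent,
            },
        )
        manifest["counts"]["fates"] = by_cat
        manifest["stages"]["fates"] = "ok"

    # -- survival ------------------------------------------------------------
    if stages.get("survival"):
        records = require("survival", "fate_records")
        time_df, dist_df = fates_mod.censored_sample_from_fates(records)
        state["km_samples"] = (time_df, dist_df)
        out = {}
        for label, df in (("time", time_df), ("distance", dist_df)):
            fitted = {}
            for group, sub in df.groupby("group"):
                res = surv_mod.km_fit(sub["value"], sub["event"], label=group)
                med = res.median()
                fitted[group] = {
                    "n": len(sub),
                    "median": med.median,
                    "ci_lower": med.ci_lower,
                    "ci_upper": med.ci_upper,
                }
                emit_csv(f"km_{label}_{group}.csv", res.summary())
            groups = sorted(df["group"].unique())
            if len(groups) == 2:
                a = df[df["group"] == groups[0]]
                b = df[df["group"] == groups[1]]
                try:
                    lr = surv_mod.logrank_test(a["value"], a["event"], b["value"], b["event"])
                    fitted["logrank"] = {"chi2": lr.chi2, "p": lr.p_value}
                except ValueError as err:
                    fitted["logrank"] = {"error": str(err)}
            out[label] = fitted
        emit_json("survival.json", out)
        manifest["counts"]["km_samples"] = {"time": len(time_df), "distance": len(dist_df)}
        manifest["stages"]["survival"] = "ok"

    # -- breakfit ------------------------------------------------------------
    if stages.get("breakfit"):
        records = require("breakfit", "fate_records")
        pts = [
            (r.last_day, r.last_chainage_km)
            for r in records
            if r.category in (fates_mod.LOCATED, fates_mod.CENSORING)
        ]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        res = seg_mod.fit_segmented(x, y)
        comp = seg_mod.compare_models(x, y)
        payload = {
            "n": int(len(x)),
            "fit": res.summary().to_dict(orient="records"),
            "degenerate": res.degenerate,
            "comparison": comp._asdict(),
        }
        K = min(10, len(x) - 4)
        if comp.preferred_aic == "segmented" and comp.preferred_bic == "segmented" and K >= 2:
            dav = seg_mod.davies_test(x, y, K=K)
            payload["davies"] = {"statistic": dav.statistic, "p_bound": dav.p_bound, "K": dav.K}
        emit_json("breakfit.json", payload)
        state["breakfit"] = res
        manifest["stages"]["breakfit"] = "ok"

    # -- trajectory ----------------------------------------------------------
    if stages.get("trajectory"):
        projected = require("trajectory", "projected")
        records = require("trajectory", "fate_records")
        data = traj_mod.filter_tracking_data(projected, records)
        results = traj_mod.fit_trajectory_model(data)
        state["trajectory"] = results
        grid = np.linspace(0.0, results.model.t_max, 101)
        mean, lo, hi = results.predict(grid, with_ci=True)
        emit_csv(
            "trajectory_prediction.csv",
            pd.DataFrame({"t_days": grid, "distance_km": mean, "ci_lower": lo, "ci_upper": hi}),
        )
        times = {}
        for target in config["trajectory"]["targets_km"]:
            try:
                times[f"{target:g}_km"] = results.time_to_chainage(float(target))
            except ValueError:
                times[f"{target:g}_km"] = None
        emit_json(
            "trajectory.json",
            {
                "n_fish": data.n_fish,
                "phi": results.phi,
                "sigma_resid_km": float(np.sqrt(results.sigma2)),
                "sd_intercept_km": results.sd_intercept,
                "sd_slope_km_day": results.sd_slope,
                "reml_loglik": results.reml_loglik,
                "days_to_target": times,
                "exclusions": data.exclusion_log().to_dict(orient="records"),
            },
        )
        manifest["counts"]["trajectory_fish"] = data.n_fish
        manifest["stages"]["trajectory"] = "ok"

    # -- thermo --------------------------------------------------------------
    if stages.get("thermo"):
        temps = require("thermo", "temps")
        ccfg = config["curve"]
        curve = thermal_mod.calibrate_curve(
            ccfg["T_opt"], ccfg["window_lower"], ccfg["window_upper"], ccfg["q"]
        )
        rmr_model = thermal_mod.RMRModel(**config["rmr"])
        scen = config["scenario"]
        grid_df = thermal_mod.scenario_grid(
            temps,
            scen["departures"],
            scen["duration_days"],
            curve,
            q=ccfg["q"],
            deltas=scen["deltas"],
            rmr_model=rmr_model,
        )
        emit_csv("scenario_grid.csv", grid_df)
        win = thermal_mod.retention_window(curve, ccfg["q"])
        cost = thermal_mod.cost_metrics(rmr_model, win.lower, win.upper)
        payload = {
            "window": {"lower": win.lower, "upper": win.upper, "q": ccfg["q"]},
            "cost_ratio_percent": cost.ratio_percent,
            "cost_daily_diff_kj": cost.daily_diff_kj,
        }
        cohort = state.get("cohort")
        if cohort is not None and len(cohort.loggers):
            loggers = cohort.loggers.set_index("timestamp")
            diffs = []
            for fish_id, sub in loggers.groupby("fish_id"):
                hourly = thermal_mod.downsample_hourly(sub["temp_c"])
                cmp = thermal_mod.compare_logger_vs_river(hourly, temps)
                diffs.append({"fish_id": fish_id, **cmp._asdict()})
            payload["logger_vs_river"] = diffs
        emit_json("thermo.json", payload)
        manifest["stages"]["thermo"] = "ok"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    return str(obj)
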