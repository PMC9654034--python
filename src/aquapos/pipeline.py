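"""End-to-end batch pipeline: simulate -> position -> filter -> smooth ->
evaluate.

The field system streams detections to a server that re-solves positions
every couple of minutes; here that loop is modeled as a single batch run
over a detections table.  A run is fully described by a config mapping
(YAML on disk) and a seed; identical config + seed produces byte-identical
artifacts, each stamped with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, filtering, io, simulator, tdoa
from .ctcrw import CTCRWParams, PredictionGrid, ctcrw_fit, ctcrw_predict
from .geo import GeoPoint, LocalPoint, make_frame

log = logging.getLogger("aquapos")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def default_config(seed: int = 0) -> dict:
    """A complete synthetic towed-test configuration.

    Three receivers on a 270 m equilateral triangle; a 3 s pinger towed
    at 9.2 km/h first criss-crossing the array interior, then heading
    away from its center; 0.1 ms clock jitter.
    """
    return {
        "seed": seed,
        "sound_speed": 1500.0,
        "start_time": "2021-06-04T00:00:00Z",
        "simulate": {
            "origin": {"lat": 42.55, "lon": 9.48},
            "array": {"spacing": 270.0, "n": 3, "hydrophone_depth_m": 4.0},
            "tag": {"tag_id": "pinger-1", "mode": "continuous",
                    "period": 3.0, "depth": 15.0},
            "track": {
                "kind": "waypoint-drift",
                "speed_kmh": 9.2,
                "depth": 15.0,
                "waypoints": [[-110.0, -70.0], [90.0, 50.0], [-60.0, 90.0],
                              [70.0, -85.0], [0.0, 0.0], [330.0, 430.0]],
            },
            "duration": 600.0,
            "range_model": {"reference_distance": 270.0,
                            "reference_probability": 0.75, "steepness": 0.02},
            "clock": {"jitter_sd": 1e-4},
            "false_detection_rate": 0.0,
        },
        "position": {"mode": "2D", "assumed_depth": 15.0, "guard": 0.05},
        "filter": {"radius_m": 200.0, "scope": "any"},
        "smooth": {"interval": 3.0, "measurement_error_sd": 10.0, "fit": True},
        "evaluate": {"method": "spacetime", "window": 30.0,
                     "segment": 21.0, "period": 3.0, "interp_step": 1.0},
    }


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _build_scenario(cfg: dict):
    sim = cfg["simulate"]
    receivers = simulator.equilateral_array(
        spacing=sim["array"]["spacing"], n=sim["array"]["n"],
        depth=sim["array"].get("hydrophone_depth_m", 0.0),
    )
    origin = GeoPoint(sim["origin"]["lat"], sim["origin"]["lon"])
    frame = make_frame(origin)
    tagc = sim["tag"]
    tag = simulator.TransmitterSpec(
        tag_id=tagc.get("tag_id", "tag-1"), mode=tagc.get("mode", "continuous"),
        period=tagc.get("period", 3.0),
        delay_min=tagc.get("delay_min", 30.0), delay_max=tagc.get("delay_max", 90.0),
        depth=tagc.get("depth", 0.0),
    )
    trc = sim["track"]
    track = simulator.TrackSpec(
        kind=trc.get("kind", "waypoint-drift"),
        speed_kmh=trc.get("speed_kmh", 9.2),
        waypoints=tuple(LocalPoint(x, y, trc.get("depth", 0.0))
                        for x, y in trc.get("waypoints", [])),
        depth=trc.get("depth", 0.0),
    )
    rm = sim.get("range_model", {})
    range_model = simulator.DetectionRangeModel(
        reference_distance=rm.get("reference_distance", 270.0),
        reference_probability=rm.get("reference_probability", 0.75),
        steepness=rm.get("steepness", 0.02),
    )
    clock = simulator.ClockErrorModel(
        jitter_sd=sim.get("clock", {}).get("jitter_sd", 1e-4))
    return simulator.SimConfig(
        receivers=tuple(receivers), transmitters=(tag,), tracks=(track,),
        range_model=range_model, clock_model=clock,
        sound_speed=cfg.get("sound_speed", 1500.0),
        false_detection_rate=sim.get("false_detection_rate", 0.0),
        duration=sim["duration"], seed=cfg.get("seed", 0),
    ), frame


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the full pipeline and write artifacts under ``outdir``.

    Returns the summary dict (also written as summary.json).  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config_hash(cfg), "seed": cfg.get("seed", 0),
                     "stages": {}}
    t_base = float(pd.Timestamp(cfg.get("start_time", "2021-01-01T00:00:00Z"))
                   .timestamp())

    # -- simulate ---------------------------------------------------------
    try:
        sim_config, frame = _build_scenario(cfg)
        result = simulator.simulate_experiment(sim_config)
        detections = result["detections"].copy()
        detections["arrival_time"] += t_base
        receivers = list(sim_config.receivers)
        tag = sim_config.transmitters[0]
        truth = result["truth"][tag.tag_id]
        ref = evaluation.ReferenceTrack(
            truth["times"] + t_base, truth["positions"][:, :2])
        io.write_receivers(receivers, frame, outdir / "receivers.csv")
        io.write_detections(detections, outdir / "detections.csv")
        io.write_reference_track(ref, frame, outdir / "truth_track.csv")
        summary["stages"]["simulate"] = {"n_detections": int(len(detections)),
                                         "n_emissions": int(len(truth["times"]))}
        log.info("simulate: %d detections from %d emissions",
                 len(detections), len(truth["times"]))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", exc) from exc

    # -- position ---------------------------------------------------------
    try:
        pos_cfg = cfg.get("position", {})
        medium = tdoa.MediumModel(cfg.get("sound_speed", 1500.0))
        groups, unassigned = tdoa.group_detections(
            detections, receivers, c=medium.sound_speed,
            guard=pos_cfg.get("guard", 0.05))
        fixes = tdoa.solve_all(
            groups, medium, mode=pos_cfg.get("mode", "2D"),
            assumed_depth=pos_cfg.get("assumed_depth", 0.0))
        positions = io.fixes_to_frame(fixes, frame)
        io.write_positions(positions, outdir / "positions.csv")
        summary["stages"]["position"] = {
            "n_groups": len(groups), "n_unassigned": int(len(unassigned)),
            "n_fixes": len(fixes)}
        log.info("position: %d groups -> %d fixes", len(groups), len(fixes))
    except Exception as exc:
        raise PipelineError("position", exc) from exc

    # -- filter -----------------------------------------------------------
    try:
        fcfg = cfg.get("filter", {})
        policy = filtering.FilterPolicy(radius_m=fcfg.get("radius_m", 200.0),
                                        scope=fcfg.get("scope", "any"))
        retained, removed = filtering.filter_positions(positions, receivers, policy)
        io.write_positions(retained, outdir / "retained.csv")
        io.write_positions(removed, outdir / "removed.csv")
        summary["stages"]["filter"] = {
            "n_raw": int(len(positions)), "n_retained": int(len(retained)),
            "retention_percent": filtering.retention_percent(
                len(positions), len(retained)) if len(positions) else None}
        log.info("filter: %d/%d retained", len(retained), len(positions))
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    # -- smooth -----------------------------------------------------------
    try:
        scfg = cfg.get("smooth", {})
        times = retained["time"].to_numpy(float)
        xy = retained[["x", "y"]].to_numpy(float)
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, xy = times[keep], xy[keep]
        err_sd = scfg.get("measurement_error_sd", 10.0)
        if scfg.get("fit", True) and len(times) >= 20:
            fit = ctcrw_fit(times, xy, measurement_error_sd=err_sd,
                            seed=cfg.get("seed", 0))
            params = fit.params
            summary["stages"]["smooth"] = {"fitted": True,
                                           **asdict(params),
                                           "log_likelihood": fit.log_likelihood}
        else:
            params = CTCRWParams(beta=scfg.get("beta", 0.05),
                                 sigma=scfg.get("sigma", 0.5),
                                 measurement_error_sd=err_sd)
            summary["stages"]["smooth"] = {"fitted": False, **asdict(params)}
        grid = PredictionGrid(interval=scfg.get("interval", 3.0),
                              start=times[0], end=times[-1])
        pred = ctcrw_predict(times, xy, params, grid)
        lat, lon = frame.to_geo_arrays(pred["x"], pred["y"])
        out = pd.DataFrame({
            "time": io.seconds_to_iso(pred["time"].to_numpy()),
            "lat": lat, "lon": lon,
            "se_m": np.hypot(pred["se_x"], pred["se_y"]),
        })
        out.to_csv(outdir / "smoothed.csv", index=False)
        summary["stages"]["smooth"]["n_predicted"] = int(len(pred))
        log.info("smooth: %d regular positions", len(pred))
    except Exception as exc:
        raise PipelineError("smooth", exc) from exc

    # -- evaluate ---------------------------------------------------------
    try:
        ecfg = cfg.get("evaluate")
        if ecfg is None:
            summary["stages"]["evaluate"] = {"skipped": True}
        else:
            method = ecfg.get("method", "spacetime")
            matcher = evaluation.MATCHERS[method]
            kwargs = {"window": ecfg.get("window", 30.0)} if method == "space" else {}
            matches = matcher(retained, ref, **kwargs)
            reports = evaluation.accuracy_report(matches, receivers)
            curve = evaluation.reconstruction_rate(
                retained, ref, receivers,
                period=ecfg.get("period", 3.0), segment=ecfg.get("segment", 21.0),
                interp_step=ecfg.get("interp_step", 1.0))
            curve.to_csv(outdir / "reconstruction_curve.csv", index=False)
            matches.to_csv(outdir / "matches.csv", index=False)
            rep = {k: (asdict(v) if not isinstance(v, int) else v)
                   for k, v in reports.items()}
            thr = evaluation.threshold_distance(curve)
            rep["threshold"] = asdict(thr)
            with open(outdir / "accuracy_report.json", "w") as fh:
                json.dump(rep, fh, indent=2)
            summary["stages"]["evaluate"] = {
                "method": method,
                "overall_mean_error_m": reports["overall"].mean_error_m,
                "inside_mean_error_m": reports["inside"].mean_error_m,
                "outside_mean_error_m": reports["outside"].mean_error_m,
                "threshold_distance_m": thr.distance_m,
            }
            log.info("evaluate: overall error %.2f m",
                     reports["overall"].mean_error_m)
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
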