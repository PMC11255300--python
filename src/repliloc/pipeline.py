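"""Seeded end-to-end orchestration: simulate -> track -> analyze -> report.

Each stage reads and writes the documented CSV tables under the run
directory, so stages can be re-run independently (or fed user-provided
tables in the same schemas).  Given the same config and seed the whole
run is deterministic, byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coords, dynamics, io, pairing, tracking
from .config import PipelineConfig, to_dict
from .model import predicted_replication_area
from .simulate import simulate

__all__ = ["StageError", "run_pipeline", "area_bin_edges", "spatial_bin_edges"]

STAGES = ("simulate", "track", "analyze", "report")


class StageError(RuntimeError):
    """A stage's inputs are missing or a stage name is unknown."""


def area_bin_edges(cfg: PipelineConfig) -> np.ndarray:
    a = cfg.analysis
    n = int(round((a.area_max - a.area_min) / a.area_bin_width))
    return a.area_min + np.arange(n + 1) * a.area_bin_width


def spatial_bin_edges(cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    a = cfg.analysis
    nl = int(round(2 * a.long_half_extent_um / a.spatial_bin_um))
    ns = int(round(2 * a.short_half_extent_um / a.spatial_bin_um))
    long_edges = -a.long_half_extent_um + np.arange(nl + 1) * a.spatial_bin_um
    short_edges = -a.short_half_extent_um + np.arange(ns + 1) * a.spatial_bin_um
    return long_edges, short_edges


def _need(outdir: Path, name: str, kind: str, stage: str) -> pd.DataFrame:
    path = outdir / f"{name}.csv"
    if not path.exists():
        raise StageError(
            f"stage {stage!r} requires {path.name}; run the producing stage "
            f"first or place the table in {outdir}")
    return io.read_table(path, kind)


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    result = simulate(cfg)
    io.write_table(result.cells, outdir / "cells.csv", "cells")
    io.write_table(result.truth, outdir / "truth.csv", "truth")
    io.write_table(result.observations, outdir / "observations.csv", "observations")
    io.write_table(result.events, outdir / "true_events.csv", "events")
    io.write_table(result.divisions, outdir / "divisions.csv", "divisions")
    io.write_table(result.landmarks, outdir / "landmarks.csv", "landmarks")
    (outdir / "config_echo.json").write_text(
        json.dumps(to_dict(cfg), indent=2, sort_keys=True) + "\n")


def _stage_track(cfg: PipelineConfig, outdir: Path) -> None:
    cells = _need(outdir, "cells", "cells", "track")
    obs = _need(outdir, "observations", "observations", "track")
    t = cfg.tracking
    traj = tracking.link_foci(obs, cells, t.max_disp_um, t.max_gap)
    io.write_table(traj, outdir / "trajectories.csv", "trajectories")
    events = tracking.detect_initiation(traj, cells, t.min_lifetime,
                                        t.exclusion_radius_um)
    io.write_table(events, outdir / "detected_events.csv", "detected_events")


def _stage_analyze(cfg: PipelineConfig, outdir: Path) -> None:
    cells = _need(outdir, "cells", "cells", "analyze")
    obs = _need(outdir, "observations", "observations", "analyze")
    traj = _need(outdir, "trajectories", "trajectories", "analyze")
    events = _need(outdir, "detected_events", "detected_events", "analyze")
    landmarks = _need(outdir, "landmarks", "landmarks", "analyze")
    acfg = cfg.analysis
    area_edges = area_bin_edges(cfg)
    long_edges, short_edges = spatial_bin_edges(cfg)
    rng = np.random.default_rng(cfg.seed + 7)

    # Registration: locus channel onto replisome channel.
    transform = pairing.fit_channel_transform(landmarks)
    obs_reg = obs.copy()
    is_loc = obs_reg["channel"] == "locus"
    reg_xy = transform.apply(obs_reg.loc[is_loc, ["x_um", "y_um"]].to_numpy())
    obs_reg.loc[is_loc, ["x_um", "y_um"]] = reg_xy

    # Location histograms and per-cluster Gaussian fits (replisome channel).
    first = obs_reg[obs_reg["tag"] == "first"]
    summary: dict = {"registration": {
        "residual_rms_um": transform.residual_rms_um,
        "n_landmarks": transform.n_landmarks,
        "offset_um": transform.offset.tolist(),
    }}
    for channel in ("replisome", "locus"):
        internal = coords.annotate_internal(first[first["channel"] == channel], cells)
        hist = coords.build_location_histograms(internal, cells, area_edges,
                                                long_edges, short_edges)
        np.savetxt(outdir / f"histogram_{channel}_counts.csv",
                   hist.counts.reshape(hist.counts.shape[0], -1), delimiter=",")
        fits = coords.fit_location_gaussian(internal, area_edges,
                                            acfg.min_fit_count)
        fits.to_csv(outdir / f"gaussian_fits_{channel}.csv", index=False)
        win = fits[(fits["valid"]) & (fits["area_center"] >= 2.0)
                   & (fits["area_center"] <= 3.0)]
        if channel == "replisome" and len(win):
            summary["gaussian_fit"] = {
                "sqrt2_mean_sd_long_um": float(np.sqrt(2) * win["sd_long"].mean()),
                "sqrt2_mean_sd_short_um": float(np.sqrt(2) * win["sd_short"].mean()),
                "n_cluster_bins": int(len(win)),
            }

    # Initiation-aligned, drift-subtracted RMSD of the replisome.
    aligned = dynamics.align_on_initiation(
        traj, events, cells, acfg.rmsd_window_min,
        cfg.schedule.frame_interval_min)
    if len(aligned.trajectory_ids):
        net = dynamics.net_movement_percent(
            aligned, 0.3 * cfg.model.doubling_time)
        corrected = dynamics.subtract_net_drift(aligned)
        curve = dynamics.rmsd_curve(corrected)
        curve.to_csv(outdir / "rmsd_replisome.csv", index=False)
        plateau = dynamics.plateau_estimate(curve, acfg.plateau_lag_min,
                                            acfg.plateau_lag_max)
        summary["rmsd"] = {
            "n_trajectories": int(len(aligned.trajectory_ids)),
            "plateau_long_um": plateau["long"]["plateau_um"],
            "plateau_long_sem_um": plateau["long"]["sem_um"],
            "plateau_short_um": plateau["short"]["plateau_um"],
            "plateau_short_sem_um": plateau["short"]["sem_um"],
        }
        summary["net_movement"] = net
    summary["initiation"] = {
        "n_events": int(len(events)),
        "mean_area_um2": float(events["area_um2"].mean()) if len(events) else np.nan,
        "sem_area_um2": float(events["area_um2"].std(ddof=1)
                              / np.sqrt(len(events))) if len(events) > 1 else np.nan,
    }

    # 1-s displacements: by cell area, in space, and their minima.
    doublets = tracking.link_doublets(obs_reg, cfg.tracking.doublet_gate_um)
    records = dynamics.compute_displacements(doublets, cells)
    records.to_csv(outdir / "displacements.csv", index=False)
    summary["displacements"] = {"n_unpaired_doublets": doublets.attrs["n_unpaired"]}
    for channel in ("replisome", "locus"):
        sub = records[records["channel"] == channel]
        by_area = dynamics.displacement_by_area(sub, area_edges)
        by_area.to_csv(outdir / f"displacement_by_area_{channel}.csv", index=False)
        summary["displacements"][channel] = {
            "n": int(len(sub)),
            "mean_mag_um": float(sub["mag_um"].mean()) if len(sub) else np.nan,
        }
        if channel == "locus" and (by_area["n"] > 0).sum() >= 3:
            est = dynamics.find_displacement_minimum(
                sub, area_edges, smoothing_bins=acfg.smoothing_bins,
                n_bootstrap=acfg.n_bootstrap, rng=rng)
            summary["displacements"]["locus_minimum"] = {
                "area_um2": est.area_um2,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "predicted_um2": predicted_replication_area(
                    cfg.locus.alpha, cfg.model),
                "defined": est.defined,
            }
        smap = dynamics.spatial_displacement_map(
            sub, area_edges, long_edges, short_edges, acfg.min_count_exclusive)
        np.savetxt(outdir / f"spatial_map_{channel}.csv",
                   np.nan_to_num(smap.values, nan=-1.0).reshape(
                       smap.values.shape[0], -1), delimiter=",")

    # Replisome-locus pairing and distance-by-area.
    pairs = pairing.pair_observations(obs, cells, transform,
                                      cfg.tracking.pair_max_distance_um)
    pairs.to_csv(outdir / "pairs.csv", index=False)
    dist = pairing.distance_by_area(pairs, area_edges)
    dist.to_csv(outdir / "distance_by_area.csv", index=False)
    if len(pairs) and (dist["n"] > 0).sum() >= 3:
        est = dynamics.find_displacement_minimum(
            pairs, area_edges, value_col="distance_um",
            smoothing_bins=acfg.smoothing_bins, n_bootstrap=acfg.n_bootstrap,
            rng=rng)
        summary["pairing"] = {
            "n_pairs": int(len(pairs)),
            "distance_minimum_um2": est.area_um2,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "predicted_um2": predicted_replication_area(cfg.locus.alpha, cfg.model),
        }
    (outdir / "analysis_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    path = outdir / "analysis_summary.json"
    if not path.exists():
        raise StageError("stage 'report' requires analysis_summary.json; "
                         "run 'analyze' first")
    summary = json.loads(path.read_text())
    lines = [
        f"repliloc run report (seed {cfg.seed}, locus {cfg.locus.name}, "
        f"alpha {cfg.locus.alpha})",
        "",
    ]
    ini = summary.get("initiation", {})
    lines.append(
        f"initiation: n={ini.get('n_events')} mean area = "
        f"{ini.get('mean_area_um2'):.4g} +/- {ini.get('sem_area_um2'):.2g} um^2 "
        f"(model A_init = {cfg.model.a_init} um^2)")
    if "rmsd" in summary:
        r = summary["rmsd"]
        lines.append(
            f"replisome RMSD plateau: long {r['plateau_long_um']:.4g} +/- "
            f"{r['plateau_long_sem_um']:.2g} um, short {r['plateau_short_um']:.4g} "
            f"+/- {r['plateau_short_sem_um']:.2g} um (n={r['n_trajectories']})")
    if "gaussian_fit" in summary:
        g = summary["gaussian_fit"]
        lines.append(
            f"sqrt(2) x mean location-fit SD (2-3 um^2): long "
            f"{g['sqrt2_mean_sd_long_um']:.4g} um, short "
            f"{g['sqrt2_mean_sd_short_um']:.4g} um")
    if "net_movement" in summary:
        n = summary["net_movement"]
        lines.append(
            f"replisome net movement over {n['window_min']:.3g} min: "
            f"{n['percent_of_length']:.3g} +/- {n['sem_percent']:.2g} % of cell "
            f"length (n={n['n_traj']})")
    d = summary.get("displacements", {})
    if "locus_minimum" in d:
        m = d["locus_minimum"]
        lines.append(
            f"locus 1-s displacement minimum at {m['area_um2']:.4g} um^2 "
            f"[{m['ci_low']:.4g}, {m['ci_high']:.4g}] "
            f"(model predicts {m['predicted_um2']:.4g} um^2)")
    if "pairing" in summary:
        p = summary["pairing"]
        lines.append(
            f"replisome-locus distance minimum at {p['distance_minimum_um2']:.4g} "
            f"um^2 (model predicts {p['predicted_um2']:.4g} um^2, "
            f"n={p['n_pairs']} pairs)")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "track": _stage_track,
    "analyze": _stage_analyze,
    "report": _stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages=STAGES,
                 outdir: str | Path | None = None) -> dict:
    """Run the requested stages in order; returns the analysis summary.

    ``outdir`` defaults to ``cfg.outdir``.  Stage dependencies are checked
    by table presence, so ``analyze`` can run on user-provided tables.
    """
    cfg.validate()
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise StageError(f"unknown stage {stage!r}; valid: {', '.join(STAGES)}")
    for stage in STAGES:  # canonical order regardless of input order
        if stage in stages:
            _STAGE_FUNCS[stage](cfg, outdir)
    summary_path = outdir / "analysis_summary.json"
    return json.loads(summary_path.read_text()) if summary_path.exists() else {}
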