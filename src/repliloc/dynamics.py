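"""Initiation-aligned RMSD and 1-second displacement analyses.

Two complementary views of particle dynamics:

* **RMSD relative to initiation** — replisome trajectories are re-timed to
  their replication-initiation event, the ensemble net average movement
  (the slow outward drift of the quarter-cell homes as the cell grows) is
  subtracted per time point, and the root mean squared displacement from
  the time-0 position is computed per cell axis.  For a confined particle
  the curve plateaus at sqrt(2) times the confinement SD.

* **1-second displacements** — foci linked between the two frames of each
  1-s doublet give the short-time-scale step of a particle.  Steps are
  binned by cell area (the cell-cycle coordinate) and by intracellular
  position; a replicated locus moves with the replisome's small step, so
  its bin-mean profile dips at the predicted replication area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import annotate_internal

__all__ = [
    "AlignedTrajectorySet",
    "align_on_initiation",
    "subtract_net_drift",
    "rmsd_curve",
    "plateau_estimate",
    "net_movement_percent",
    "compute_displacements",
    "displacement_by_area",
    "SpatialDisplacementMap",
    "spatial_displacement_map",
    "MinimumEstimate",
    "find_displacement_minimum",
]


@dataclass
class AlignedTrajectorySet:
    """Trajectories re-indexed to time since initiation.

    ``long`` holds the outward-signed long-axis coordinate (each
    trajectory's long positions are multiplied by the sign of its starting
    half-cell, so outward movement is positive for both clusters);
    ``short`` the short-axis coordinate; ``length`` the containing cell's
    length.  Arrays are (n_trajectories, n_lags), NaN-padded where a
    trajectory has no point.
    """

    lags_min: np.ndarray
    long: np.ndarray
    short: np.ndarray
    length: np.ndarray
    trajectory_ids: np.ndarray
    drift_subtracted: bool = False
    sparse_lags: list = field(default_factory=list)  # lags where drift reused


def align_on_initiation(trajectories: pd.DataFrame, events: pd.DataFrame,
                        cells: pd.DataFrame, window_min: float = 20.0,
                        frame_interval_min: float = 1.0) -> AlignedTrajectorySet:
    """Re-time event-spawned trajectories to lag 0 at their initiation event.

    Each event's spawned trajectories (its ``trajectory_ids``) are aligned
    so that the event frame is lag 0.  Trajectories missing a detection at
    lag 0 are excluded (the RMSD reference point would be undefined), as
    are trajectories not attached to any event.
    """
    traj_to_event: dict[int, int] = {}
    for ev in events.itertuples(index=False):
        for tid in str(ev.trajectory_ids).split(";"):
            if tid:
                traj_to_event[int(tid)] = int(ev.frame)
    n_lags = int(round(window_min / frame_interval_min)) + 1
    lags = np.arange(n_lags) * frame_interval_min
    internal = annotate_internal(trajectories, cells, require_match=True)

    rows_long, rows_short, rows_len, ids = [], [], [], []
    for tid, sub in internal.groupby("trajectory_id"):
        if int(tid) not in traj_to_event:
            continue
        f0 = traj_to_event[int(tid)]
        lag_idx = ((sub["frame"] - f0).to_numpy()).astype(int)
        sel = (lag_idx >= 0) & (lag_idx < n_lags)
        if not np.any((lag_idx == 0) & sel):
            continue
        vl = np.full(n_lags, np.nan)
        vs = np.full(n_lags, np.nan)
        vL = np.full(n_lags, np.nan)
        vl[lag_idx[sel]] = sub["long_um"].to_numpy()[sel]
        vs[lag_idx[sel]] = sub["short_um"].to_numpy()[sel]
        vL[lag_idx[sel]] = sub["length_um"].to_numpy()[sel]
        sign = 1.0 if vl[0] >= 0 else -1.0
        rows_long.append(sign * vl)
        rows_short.append(vs)
        rows_len.append(vL)
        ids.append(int(tid))
    if not rows_long:
        empty = np.empty((0, n_lags))
        return AlignedTrajectorySet(lags, empty, empty.copy(), empty.copy(),
                                    np.array([], dtype=int))
    return AlignedTrajectorySet(lags, np.array(rows_long), np.array(rows_short),
                                np.array(rows_len), np.array(ids))


def subtract_net_drift(aligned: AlignedTrajectorySet) -> AlignedTrajectorySet:
    """Remove the ensemble net average movement per time point.

    For each lag, the across-trajectory mean displacement-from-start is
    subtracted from every trajectory (per axis), leaving zero mean
    displacement-from-start at every lag.  Lags with fewer than two
    trajectories reuse the last valid mean and are flagged in
    ``sparse_lags``.
    """
    out_long = aligned.long.copy()
    out_short = aligned.short.copy()
    sparse = []
    for arr in (out_long, out_short):
        disp = arr - arr[:, [0]]
        last_mean = 0.0
        for j in range(arr.shape[1]):
            col = disp[:, j]
            n = np.isfinite(col).sum()
            if n >= 2:
                m = np.nanmean(col)
                last_mean = m
            else:
                m = last_mean
                if j not in sparse:
                    sparse.append(j)
            arr[:, j] = arr[:, j] - m
    return AlignedTrajectorySet(aligned.lags_min, out_long, out_short,
                                aligned.length, aligned.trajectory_ids,
                                drift_subtracted=True,
                                sparse_lags=[aligned.lags_min[j] for j in sparse])


def rmsd_curve(aligned: AlignedTrajectorySet) -> pd.DataFrame:
    """RMSD(t) per axis relative to each trajectory's lag-0 position.

    RMSD(t) = sqrt(mean_i (x_i(t) - x_i(0))^2).  The SEM is propagated
    from the across-trajectory variance of the squared displacements:
    sem(RMSD) = sem(mean d^2) / (2 RMSD).  Lags with no trajectories are
    omitted.
    """
    rows = []
    for lag_j, lag in enumerate(aligned.lags_min):
        row: dict = {"lag_min": lag}
        n_min = None
        for axis, arr in (("long", aligned.long), ("short", aligned.short)):
            d2 = (arr[:, lag_j] - arr[:, 0]) ** 2
            d2 = d2[np.isfinite(d2)]
            n = d2.size
            if n == 0:
                row = None
                break
            m = d2.mean()
            rmsd = np.sqrt(m)
            sem_m = d2.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            row[f"rmsd_{axis}"] = rmsd
            row[f"sem_{axis}"] = sem_m / (2 * rmsd) if rmsd > 0 else 0.0
            n_min = n if n_min is None else min(n_min, n)
        if row is not None:
            row["n"] = n_min
            rows.append(row)
    return pd.DataFrame(rows)


def plateau_estimate(curve: pd.DataFrame, lag_min: float = 10.0,
                     lag_max: float = 20.0) -> dict:
    """Mean RMSD per axis over a lag window, with (conservative) SEM.

    Adjacent lags of the same trajectories are correlated, so the window
    SEM is the mean of the per-lag SEMs rather than divided by the number
    of lags.
    """
    win = curve[(curve["lag_min"] >= lag_min) & (curve["lag_min"] <= lag_max)]
    if win.empty:
        raise ValueError(f"no RMSD points in lag window [{lag_min}, {lag_max}] min")
    out = {}
    for axis in ("long", "short"):
        out[axis] = {
            "plateau_um": float(win[f"rmsd_{axis}"].mean()),
            "sem_um": float(win[f"sem_{axis}"].mean()),
            "n_traj": int(win["n"].min()),
            "n_lags": int(len(win)),
        }
    return out


def net_movement_percent(aligned: AlignedTrajectorySet,
                         window_min: float) -> dict:
    """Net average outward movement over a window, as percent of cell length.

    The quantity is the ensemble-mean outward-signed long-axis displacement
    between lag 0 and the window end (net average movement, the same
    quantity drift subtraction removes), normalized by the mean cell length
    over the window.  Requires a not-yet-drift-subtracted aligned set.
    """
    if aligned.drift_subtracted:
        raise ValueError("net movement must be measured before drift subtraction")
    j = int(np.argmin(np.abs(aligned.lags_min - window_min)))
    d = aligned.long[:, j] - aligned.long[:, 0]
    ok = np.isfinite(d)
    if not ok.any():
        raise ValueError("no trajectories cover the requested window")
    mean_disp = float(d[ok].mean())
    sem_disp = float(d[ok].std(ddof=1) / np.sqrt(ok.sum()))
    mean_len = float(np.nanmean(aligned.length[ok, : j + 1]))
    pct = 100.0 * abs(mean_disp) / mean_len
    return {
        "percent_of_length": pct,
        "sem_percent": 100.0 * sem_disp / mean_len,
        "mean_disp_um": mean_disp,
        "mean_length_um": mean_len,
        "window_min": float(aligned.lags_min[j]),
        "n_traj": int(ok.sum()),
    }


def compute_displacements(doublet_pairs: pd.DataFrame,
                          cells: pd.DataFrame) -> pd.DataFrame:
    """1-s displacement records in cell-internal coordinates.

    One record per linked doublet pair: the displacement components are
    the lab-frame step rotated into the cell axes of the first frame (the
    cell's geometry is common to both endpoints of a 1-s step), the start
    position is the first point's internal position, and the record is
    annotated with the cell area.
    """
    if doublet_pairs.empty:
        return pd.DataFrame(columns=["channel", "trap", "cell_id", "frame",
                                     "time_min", "long_um", "short_um", "rel_long",
                                     "area_um2", "dlong_um", "dshort_um", "mag_um"])
    start = doublet_pairs.rename(columns={"x1_um": "x_um", "y1_um": "y_um"})
    internal = annotate_internal(
        start[["channel", "trap", "cell_id", "frame", "time_min", "x_um", "y_um"]],
        cells, require_match=True)
    geom = cells.set_index(["cell_id", "frame"])
    theta = geom["orientation_rad"].reindex(
        list(zip(doublet_pairs["cell_id"], doublet_pairs["frame"]))).to_numpy()
    sign = geom["old_pole_sign"].reindex(
        list(zip(doublet_pairs["cell_id"], doublet_pairs["frame"]))).to_numpy()
    dx = (doublet_pairs["x2_um"] - doublet_pairs["x1_um"]).to_numpy()
    dy = (doublet_pairs["y2_um"] - doublet_pairs["y1_um"]).to_numpy()
    dlong = sign * (dx * np.cos(theta) + dy * np.sin(theta))
    dshort = -dx * np.sin(theta) + dy * np.cos(theta)
    out = internal[["channel", "trap", "cell_id", "frame", "time_min",
                    "long_um", "short_um", "rel_long", "area_um2"]].copy()
    out["dlong_um"] = dlong
    out["dshort_um"] = dshort
    out["mag_um"] = np.hypot(dlong, dshort)
    return out


def displacement_by_area(records: pd.DataFrame, area_edges) -> pd.DataFrame:
    """Per-area-bin mean 1-s displacement magnitude and counts.

    Empty bins are reported with ``n = 0`` and NaN mean, not dropped.
    """
    area_edges = np.asarray(area_edges, dtype=float)
    if not np.all(np.diff(area_edges) > 0):
        raise ValueError("area bin edges must be strictly increasing")
    idx = np.digitize(records["area_um2"].to_numpy(), area_edges) - 1
    rows = []
    for b in range(area_edges.size - 1):
        sub = records.loc[idx == b, "mag_um"]
        rows.append({
            "area_bin": b,
            "area_left": area_edges[b],
            "area_right": area_edges[b + 1],
            "area_center": 0.5 * (area_edges[b] + area_edges[b + 1]),
            "n": int(len(sub)),
            "mean_mag_um": float(sub.mean()) if len(sub) else np.nan,
            "sem_mag_um": float(sub.std(ddof=1) / np.sqrt(len(sub)))
            if len(sub) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class SpatialDisplacementMap:
    """Mean 1-s step length on the location-histogram grid, masked by count.

    ``values`` is NaN wherever ``counts <= min_count_exclusive`` (a bin is
    reported only if it holds strictly more steps than the threshold).
    Bin assignment uses the displacement's first point.
    """

    area_edges: np.ndarray
    long_edges: np.ndarray
    short_edges: np.ndarray
    values: np.ndarray      # (n_area, n_long, n_short), NaN = masked
    counts: np.ndarray
    min_count_exclusive: int

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is reported (count > threshold)."""
        return self.counts > self.min_count_exclusive


def spatial_displacement_map(records: pd.DataFrame, area_edges, long_edges,
                             short_edges,
                             min_count_exclusive: int = 4) -> SpatialDisplacementMap:
    """Average 1-s step length per spatial bin, per area bin."""
    area_edges = np.asarray(area_edges, dtype=float)
    long_edges = np.asarray(long_edges, dtype=float)
    short_edges = np.asarray(short_edges, dtype=float)
    shape = (area_edges.size - 1, long_edges.size - 1, short_edges.size - 1)
    counts = np.zeros(shape)
    sums = np.zeros(shape)
    a = np.digitize(records["area_um2"].to_numpy(), area_edges) - 1
    l = np.digitize(records["long_um"].to_numpy(), long_edges) - 1
    s = np.digitize(records["short_um"].to_numpy(), short_edges) - 1
    ok = ((a >= 0) & (a < shape[0]) & (l >= 0) & (l < shape[1])
          & (s >= 0) & (s < shape[2]))
    mag = records["mag_um"].to_numpy()
    np.add.at(counts, (a[ok], l[ok], s[ok]), 1.0)
    np.add.at(sums, (a[ok], l[ok], s[ok]), mag[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / counts
    values[counts <= min_count_exclusive] = np.nan
    return SpatialDisplacementMap(area_edges, long_edges, short_edges, values,
                                  counts.astype(int), min_count_exclusive)


@dataclass
class MinimumEstimate:
    """Location of the minimum of a binned profile, with bootstrap CI."""

    area_um2: float
    ci_low: float
    ci_high: float
    defined: bool
    n_bins_used: int


def _profile_argmin(centers: np.ndarray, means: np.ndarray,
                    smoothing_bins: int) -> float:
    prof = pd.Series(means).rolling(smoothing_bins, center=True,
                                    min_periods=1).mean().to_numpy()
    return float(centers[int(np.nanargmin(prof))])


def find_displacement_minimum(records: pd.DataFrame, area_edges,
                              value_col: str = "mag_um",
                              smoothing_bins: int = 3, n_bootstrap: int = 200,
                              rng: np.random.Generator | None = None) -> MinimumEstimate:
    """Cell area at which the bin-mean profile of ``value_col`` is minimal.

    The per-area-bin means are smoothed with a centered moving average
    before taking the argmin (reported as the bin center).  The CI is the
    percentile interval of the argmin over bootstrap resamples of the
    records within each bin.  Requires at least three non-empty bins; a
    flat (all-equal) profile is flagged undefined.
    """
    rng = rng or np.random.default_rng(0)
    area_edges = np.asarray(area_edges, dtype=float)
    idx = np.digitize(records["area_um2"].to_numpy(), area_edges) - 1
    values = records[value_col].to_numpy()
    nb = area_edges.size - 1
    centers = 0.5 * (area_edges[:-1] + area_edges[1:])
    groups = [values[idx == b] for b in range(nb)]
    nonempty = [b for b in range(nb) if groups[b].size > 0]
    if len(nonempty) < 3:
        raise ValueError(
            f"need >= 3 non-empty area bins, got {len(nonempty)}")
    means = np.array([groups[b].mean() if groups[b].size else np.nan
                      for b in range(nb)])
    finite = means[np.isfinite(means)]
    if np.allclose(finite, finite[0]):
        return MinimumEstimate(np.nan, np.nan, np.nan, False, len(nonempty))
    best = _profile_argmin(centers, means, smoothing_bins)
    boots = []
    for _ in range(n_bootstrap):
        bm = np.array([
            rng.choice(g, g.size, replace=True).mean() if g.size else np.nan
            for g in groups
        ])
        boots.append(_profile_argmin(centers, bm, smoothing_bins))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = best
    return MinimumEstimate(best, float(lo), float(hi), True, len(nonempty))
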