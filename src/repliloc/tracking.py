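"""Foci linking and replication-initiation detection.

The linker is a per-frame optimal-assignment tracker: within each lineage
and fluorescence channel, detections in consecutive frames are matched
one-to-one by minimizing summed squared distance subject to a hard
distance gate, with gap closing over a small number of missed frames.
Replication initiation events are trajectory starts of the replisome
channel that persist for a minimum lifetime and are not explained by a
pre-existing nearby focus (which would indicate a transient splitting of
an already-tracked cluster rather than a new initiation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "lineage_roots",
    "gated_assignment",
    "link_foci",
    "link_doublets",
    "detect_initiation",
]

_BIG = 1e12  # infeasible-link cost; any feasible pairing beats any gated one

TRAJ_COLUMNS = ["trajectory_id", "channel", "trap", "cell_id", "frame",
                "time_min", "x_um", "y_um"]


def lineage_roots(cells: pd.DataFrame) -> dict[int, int]:
    """Map each cell_id to its founder cell via parent links."""
    parent = dict(zip(cells["cell_id"], cells["parent_id"]))

    def find(c: int) -> int:
        seen = {c}
        while parent.get(c, -1) in parent and parent[c] not in seen:
            c = parent[c]
            seen.add(c)
        return c

    return {c: find(c) for c in parent}


def gated_assignment(cost: np.ndarray, gate_cost: float) -> list[tuple[int, int]]:
    """Min-cost one-to-one assignment keeping only pairs with cost <= gate.

    Infeasible entries are replaced by a large constant, so the result is
    the maximum-cardinality feasible matching of minimum total cost.
    """
    if cost.size == 0:
        return []
    work = np.where(cost <= gate_cost, cost, _BIG)
    rows, cols = linear_sum_assignment(work)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] <= gate_cost]


@dataclass
class _OpenTrack:
    trajectory_id: int
    last_xy: np.ndarray
    last_frame: int
    rows: list = field(default_factory=list)


def _link_one_group(obs: pd.DataFrame, max_disp: float, max_gap: int,
                    start_id: int) -> tuple[list, int]:
    all_tracks: list[_OpenTrack] = []
    open_tracks: list[_OpenTrack] = []
    next_id = start_id
    point_cols = ["channel", "trap", "cell_id", "frame", "time_min", "x_um", "y_um"]
    for frame, det in obs.groupby("frame", sort=True):
        frame = int(frame)
        open_tracks = [t for t in open_tracks if frame - t.last_frame <= max_gap + 1]
        xy = det[["x_um", "y_um"]].to_numpy()
        cand = open_tracks
        if cand and len(det):
            prev = np.array([t.last_xy for t in cand])
            d2 = ((prev[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
            pairs = gated_assignment(d2, max_disp ** 2)
        else:
            pairs = []
        matched_det = set()
        for r, c in pairs:
            t = cand[r]
            t.last_xy = xy[c]
            t.last_frame = frame
            t.rows.append((t.trajectory_id, *det.iloc[c][point_cols]))
            matched_det.add(c)
        for c in range(len(det)):
            if c not in matched_det:
                t = _OpenTrack(next_id, xy[c], frame)
                next_id += 1
                t.rows.append((t.trajectory_id, *det.iloc[c][point_cols]))
                open_tracks.append(t)
                all_tracks.append(t)
    rows_out: list = []
    for t in all_tracks:
        rows_out.extend(t.rows)
    return rows_out, next_id


def link_foci(observations: pd.DataFrame, cells: pd.DataFrame,
              max_disp: float = 0.5, max_gap: int = 2) -> pd.DataFrame:
    """Link first-tag detections into trajectories per lineage and channel.

    Returns a long-format table (one row per trajectory point).  A
    trajectory may cross a division into one daughter because linking is
    scoped by lineage, not by cell.
    """
    obs = observations[observations["tag"] == "first"]
    roots = lineage_roots(cells)
    lineage = obs["cell_id"].map(lambda c: roots.get(c, c))
    all_rows: list = []
    next_id = 0
    for (_, _), group in obs.assign(_lin=lineage).groupby(["_lin", "channel"], sort=True):
        rows, next_id = _link_one_group(group, max_disp, max_gap, next_id)
        all_rows.extend(rows)
    traj = pd.DataFrame(all_rows, columns=TRAJ_COLUMNS)
    return traj.sort_values(["trajectory_id", "frame"]).reset_index(drop=True)


def link_doublets(observations: pd.DataFrame, gate: float = 0.3) -> pd.DataFrame:
    """Pair first/second-tag detections of the same frame doublet.

    Assignment is per (trap, channel, frame) with the doublet gate; the
    returned table carries both endpoints.  Unpaired detections are
    counted in the ``attrs['n_unpaired']`` of the result.
    """
    first = observations[observations["tag"] == "first"]
    second = observations[observations["tag"] == "second"]
    rows = []
    n_unpaired = 0
    f_groups = dict(tuple(first.groupby(["trap", "channel", "frame"], sort=True)))
    s_groups = dict(tuple(second.groupby(["trap", "channel", "frame"], sort=True)))
    for key in sorted(f_groups.keys() | s_groups.keys()):
        f = f_groups.get(key)
        s = s_groups.get(key)
        if f is None or s is None:
            n_unpaired += (0 if f is None else len(f)) + (0 if s is None else len(s))
            continue
        fxy = f[["x_um", "y_um"]].to_numpy()
        sxy = s[["x_um", "y_um"]].to_numpy()
        d2 = ((fxy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
        pairs = gated_assignment(d2, gate ** 2)
        n_unpaired += len(f) + len(s) - 2 * len(pairs)
        for r, c in pairs:
            fr, sr = f.iloc[r], s.iloc[c]
            rows.append({
                "trap": key[0], "channel": key[1], "frame": int(key[2]),
                "cell_id": fr["cell_id"], "time_min": fr["time_min"],
                "x1_um": fr["x_um"], "y1_um": fr["y_um"],
                "x2_um": sr["x_um"], "y2_um": sr["y_um"],
                "obs_id_first": fr["obs_id"], "obs_id_second": sr["obs_id"],
            })
    out = pd.DataFrame(rows)
    out.attrs["n_unpaired"] = n_unpaired
    return out


def detect_initiation(trajectories: pd.DataFrame, cells: pd.DataFrame,
                      min_lifetime: int = 5,
                      exclusion_radius: float = 0.5) -> pd.DataFrame:
    """Replication-initiation events from replisome trajectory starts.

    A trajectory start is an initiation candidate if the trajectory spans
    at least ``min_lifetime`` frames and no other replisome trajectory had
    a detection within ``exclusion_radius`` in the preceding frame (which
    would mark the start as a re-detection after transient focus
    splitting).  Candidates starting simultaneously in the same cell (the
    two sister clusters) are merged into one event, and only the earliest
    event per cell is kept (one replication round per cell cycle).  The
    event area is the containing cell's area at the start frame.
    """
    rep = trajectories[trajectories["channel"] == "replisome"]
    if rep.empty:
        return pd.DataFrame(columns=["event_id", "trap", "cell_id", "frame",
                                     "time_min", "area_um2", "trajectory_ids"])
    starts = rep.sort_values("frame").groupby("trajectory_id").first().reset_index()
    ends = rep.groupby("trajectory_id")["frame"].max().rename("end_frame")
    starts = starts.merge(ends, on="trajectory_id")
    starts["span"] = starts["end_frame"] - starts["frame"] + 1

    by_frame = {int(f): g for f, g in rep.groupby("frame")}
    candidates = []
    for row in starts.itertuples(index=False):
        if row.span < min_lifetime:
            continue
        prev = by_frame.get(int(row.frame) - 1)
        if prev is not None:
            others = prev[(prev["trajectory_id"] != row.trajectory_id)
                          & (prev["trap"] == row.trap)]
            if len(others):
                d = np.hypot(others["x_um"] - row.x_um, others["y_um"] - row.y_um)
                if (d <= exclusion_radius).any():
                    continue
        candidates.append(row)
    if not candidates:
        return pd.DataFrame(columns=["event_id", "trap", "cell_id", "frame",
                                     "time_min", "area_um2", "trajectory_ids"])
    cand = pd.DataFrame(candidates)

    area = cells.set_index(["cell_id", "frame"])["area_um2"]
    events = []
    for (cell_id, frame), grp in cand.groupby(["cell_id", "frame"], sort=True):
        events.append({
            "trap": grp["trap"].iloc[0],
            "cell_id": cell_id,
            "frame": int(frame),
            "time_min": grp["time_min"].iloc[0],
            "area_um2": float(area.get((cell_id, frame), np.nan)),
            "trajectory_ids": ";".join(str(t) for t in sorted(grp["trajectory_id"])),
        })
    ev = pd.DataFrame(events).sort_values(["cell_id", "frame"])
    ev = ev.groupby("cell_id", as_index=False).agg({
        "trap": "first", "frame": "first", "time_min": "first",
        "area_um2": "first", "trajectory_ids": "first",
    })
    ev = ev.sort_values(["trap", "frame"]).reset_index(drop=True)
    ev.insert(0, "event_id", np.arange(len(ev)))
    return ev
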