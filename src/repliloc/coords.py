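"""Cell-internal coordinates, location histograms and 2D Normal fits.

Foci detected in the lab frame are rotated/translated into the coordinate
system of their cell: ``long_um`` is the offset from mid-cell along the
long axis with positive values toward the old pole, ``short_um`` the
perpendicular offset, and ``rel_long = long_um / L`` the dimensionless
long-axis position (in [-0.5, 0.5] for in-cell foci).  Cells binned by
area then yield the two-dimensional foci-per-cell histograms and the
per-cluster Gaussian location fits whose standard deviations, times
sqrt(2), predict the RMSD plateau of a confined particle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairingError",
    "internal_position",
    "annotate_internal",
    "LocationHistogram",
    "build_location_histograms",
    "fit_location_gaussian",
    "classify_birth_side",
]

_CELL_GEOM = ["cell_id", "frame", "x_um", "y_um", "orientation_rad",
              "old_pole_sign", "length_um", "area_um2"]


class PairingError(ValueError):
    """Focus and cell rows do not belong together."""


def internal_position(focus, cell) -> tuple[float, float, float]:
    """Project one focus into one cell's frame: (long_um, short_um, rel_long).

    ``focus`` and ``cell`` are mappings (e.g. DataFrame rows) sharing
    ``cell_id`` and ``frame``; a mismatch raises :class:`PairingError`.
    """
    if focus["cell_id"] != cell["cell_id"] or focus["frame"] != cell["frame"]:
        raise PairingError(
            f"focus (cell {focus['cell_id']}, frame {focus['frame']}) does not "
            f"match cell (cell {cell['cell_id']}, frame {cell['frame']})"
        )
    dx = focus["x_um"] - cell["x_um"]
    dy = focus["y_um"] - cell["y_um"]
    theta = cell["orientation_rad"]
    sign = cell["old_pole_sign"]
    long_axis = sign * (dx * np.cos(theta) + dy * np.sin(theta))
    short_axis = -dx * np.sin(theta) + dy * np.cos(theta)
    return float(long_axis), float(short_axis), float(long_axis / cell["length_um"])


def annotate_internal(foci: pd.DataFrame, cells: pd.DataFrame,
                      require_match: bool = True) -> pd.DataFrame:
    """Vectorized projection of a foci table into cell-internal coordinates.

    Merges on (cell_id, frame) and adds ``long_um``, ``short_um``,
    ``rel_long`` and the cell's ``area_um2`` and ``length_um``.  Foci whose
    cell-frame is absent from ``cells`` raise :class:`PairingError` when
    ``require_match`` (default) and are dropped otherwise.
    """
    geom = cells[_CELL_GEOM].rename(
        columns={"x_um": "_cx", "y_um": "_cy"})
    merged = foci.merge(geom, on=["cell_id", "frame"], how="left",
                        suffixes=("", "_cell"))
    missing = merged["_cx"].isna()
    if missing.any():
        if require_match:
            bad = merged.loc[missing, ["cell_id", "frame"]].iloc[0]
            raise PairingError(
                f"no cell geometry for cell {bad['cell_id']} frame {bad['frame']}"
            )
        merged = merged.loc[~missing].copy()
    dx = merged["x_um"] - merged["_cx"]
    dy = merged["y_um"] - merged["_cy"]
    theta = merged["orientation_rad"]
    sign = merged["old_pole_sign"]
    merged["long_um"] = sign * (dx * np.cos(theta) + dy * np.sin(theta))
    merged["short_um"] = -dx * np.sin(theta) + dy * np.cos(theta)
    merged["rel_long"] = merged["long_um"] / merged["length_um"]
    return merged.drop(columns=["_cx", "_cy", "orientation_rad", "old_pole_sign"])


@dataclass
class LocationHistogram:
    """Area-binned 2D foci-per-cell histograms on a fixed spatial grid."""

    area_edges: np.ndarray          # (n_area + 1,)
    long_edges: np.ndarray          # (n_long + 1,) µm
    short_edges: np.ndarray         # (n_short + 1,) µm
    counts: np.ndarray              # (n_area, n_long, n_short) raw focus counts
    cell_counts: np.ndarray         # (n_area,) cell-frames per area bin
    values: np.ndarray              # counts / cell_counts (NaN where no cells)


def _check_edges(edges: np.ndarray, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError(f"{name} bin edges must be strictly increasing")
    return edges


def build_location_histograms(internal: pd.DataFrame, cells: pd.DataFrame,
                              area_edges, long_edges, short_edges) -> LocationHistogram:
    """Foci-per-cell 2D histograms per area bin (left-closed, right-open).

    Normalization: each area bin's 2D array is the raw focus count divided
    by the number of cell-frames whose area falls in the bin, so the array
    sums to foci per cell.  Empty area bins are kept with zero counts.
    """
    area_edges = _check_edges(area_edges, "area")
    long_edges = _check_edges(long_edges, "long")
    short_edges = _check_edges(short_edges, "short")
    n_area = area_edges.size - 1

    cell_area = cells.drop_duplicates(["cell_id", "frame"])["area_um2"].to_numpy()
    cell_counts, _ = np.histogram(cell_area, bins=area_edges)

    counts = np.zeros((n_area, long_edges.size - 1, short_edges.size - 1))
    idx = np.digitize(internal["area_um2"].to_numpy(), area_edges) - 1
    for b in range(n_area):
        sub = internal.loc[idx == b]
        if len(sub):
            counts[b], _, _ = np.histogram2d(
                sub["long_um"], sub["short_um"], bins=[long_edges, short_edges])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = counts / cell_counts[:, None, None]
    values[cell_counts == 0] = np.nan
    return LocationHistogram(area_edges, long_edges, short_edges, counts,
                             cell_counts, values)


def fit_location_gaussian(internal: pd.DataFrame, area_edges,
                          min_count: int = 10) -> pd.DataFrame:
    """Axis-independent 2D Normal fits per replisome cluster and area bin.

    Clusters are the two half-cells (sign of ``rel_long``); the maximum
    likelihood Normal fit per axis is the sample mean and SD.  Bins with
    fewer than ``min_count`` foci are flagged invalid (``valid=False``) so
    they can be excluded from averages.
    """
    area_edges = _check_edges(area_edges, "area")
    df = internal.copy()
    df["_bin"] = np.digitize(df["area_um2"].to_numpy(), area_edges) - 1
    df = df[(df["_bin"] >= 0) & (df["_bin"] < area_edges.size - 1)]
    df["cluster"] = np.where(df["rel_long"] >= 0, "upper", "lower")
    rows = []
    for (b, cluster), sub in df.groupby(["_bin", "cluster"], sort=True):
        n = len(sub)
        rows.append({
            "area_bin": int(b),
            "area_center": 0.5 * (area_edges[b] + area_edges[b + 1]),
            "cluster": cluster,
            "n": n,
            "mean_long": sub["long_um"].mean(),
            "mean_short": sub["short_um"].mean(),
            "sd_long": sub["long_um"].std(ddof=1) if n > 1 else 0.0,
            "sd_short": sub["short_um"].std(ddof=1) if n > 1 else 0.0,
            "valid": n >= min_count,
        })
    return pd.DataFrame(rows)


def classify_birth_side(internal_locus: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Label each cell old-pole/new-pole from its locus position at birth.

    The birth frame is a cell's first frame.  The label is the sign of the
    mean ``rel_long`` of locus foci in that frame (``>= 0`` -> old-pole by
    convention).  Cells with no locus focus at birth are left out.
    """
    birth = cells.groupby("cell_id")["frame"].min().rename("birth_frame")
    df = internal_locus.merge(birth, on="cell_id")
    df = df[df["frame"] == df["birth_frame"]]
    if df.empty:
        return pd.DataFrame(columns=["cell_id", "mean_rel_long", "side"])
    agg = df.groupby("cell_id")["rel_long"].mean().reset_index()
    agg = agg.rename(columns={"rel_long": "mean_rel_long"})
    agg["side"] = np.where(agg["mean_rel_long"] >= 0, "old-pole", "new-pole")
    return agg
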