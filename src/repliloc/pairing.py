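"""Two-channel registration and replisome-locus pairing.

The locus and replisome channels are imaged on different parts of the
camera chip, leaving a small chromatic offset between their coordinate
systems.  An affine transform fitted to fiducial landmarks imaged in both
channels registers the locus channel onto the replisome channel; foci of
the two channels in the same cell and frame are then paired one-to-one by
minimum total distance (each focus paired with at most one focus of the
other channel), and the pair distances, binned by cell area, trace when a
locus colocalizes with the replisome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import gated_assignment

__all__ = [
    "ChannelTransform",
    "fit_channel_transform",
    "match_foci",
    "pair_observations",
    "distance_by_area",
]


@dataclass(frozen=True)
class ChannelTransform:
    """2D affine map from the locus (moving) to the replisome (reference) channel."""

    matrix: np.ndarray        # (2, 2)
    offset: np.ndarray        # (2,)
    residual_rms_um: float    # leave-one-out residual RMS
    n_landmarks: int

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix.T + self.offset

    def inverse(self) -> "ChannelTransform":
        inv = np.linalg.inv(self.matrix)
        return ChannelTransform(inv, -inv @ self.offset, self.residual_rms_um,
                                self.n_landmarks)


def _affine_lstsq(mov: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    design = np.column_stack([mov, np.ones(len(mov))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    return coef[:2].T, coef[2]


def fit_channel_transform(landmarks: pd.DataFrame) -> ChannelTransform:
    """Least-squares affine fit from landmark pairs, with leave-one-out RMS.

    ``landmarks`` needs columns ``x_ref_um, y_ref_um, x_mov_um, y_mov_um``.
    At least three non-collinear pairs are required.
    """
    ref = landmarks[["x_ref_um", "y_ref_um"]].to_numpy(dtype=float)
    mov = landmarks[["x_mov_um", "y_mov_um"]].to_numpy(dtype=float)
    n = len(landmarks)
    if n < 3:
        raise ValueError(f"need >= 3 landmark pairs, got {n}")
    matrix, offset = _affine_lstsq(mov, ref)
    if n > 3:
        res2 = []
        for k in range(n):
            keep = np.arange(n) != k
            try:
                mk, ok = _affine_lstsq(mov[keep], ref[keep])
            except ValueError:
                continue
            pred = mov[k] @ mk.T + ok
            res2.append(((pred - ref[k]) ** 2).sum())
        rms = float(np.sqrt(np.mean(res2))) if res2 else 0.0
    else:
        rms = 0.0  # exact interpolation; no out-of-sample residual
    if not np.isfinite(np.linalg.det(matrix)) or abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("fitted transform is singular")
    return ChannelTransform(matrix, offset, rms, n)


def match_foci(replisome_xy: np.ndarray, locus_xy: np.ndarray,
               transform: ChannelTransform | None = None,
               max_distance: float = 1.0) -> list[tuple[int, int, float]]:
    """One-to-one minimum-total-distance pairing with a distance gate.

    ``locus_xy`` is registered through ``transform`` (if given) first.
    Returns (replisome index, locus index, distance) triples; foci whose
    best partner lies beyond ``max_distance`` stay unpaired.  Among
    maximum-cardinality gated matchings the minimum-total-distance one is
    returned, which subsumes mutual-nearest pairing in the generic case.
    """
    rep = np.atleast_2d(np.asarray(replisome_xy, dtype=float))
    loc = np.atleast_2d(np.asarray(locus_xy, dtype=float))
    if rep.size == 0 or loc.size == 0:
        return []
    if transform is not None:
        loc = transform.apply(loc)
    d = np.sqrt(((rep[:, None, :] - loc[None, :, :]) ** 2).sum(axis=2))
    return [(r, c, float(d[r, c])) for r, c in gated_assignment(d, max_distance)]


def pair_observations(observations: pd.DataFrame, cells: pd.DataFrame,
                      transform: ChannelTransform | None,
                      max_distance: float = 1.0) -> pd.DataFrame:
    """Pair replisome and locus foci per cell and frame (first-tag frames).

    Returns one row per pair with the registered 2D distance and the cell
    area, the input to :func:`distance_by_area`.
    """
    obs = observations[observations["tag"] == "first"]
    area = cells.set_index(["cell_id", "frame"])["area_um2"]
    rows = []
    for (cell_id, frame), sub in obs.groupby(["cell_id", "frame"], sort=True):
        rep = sub[sub["channel"] == "replisome"]
        loc = sub[sub["channel"] == "locus"]
        if rep.empty or loc.empty:
            continue
        pairs = match_foci(rep[["x_um", "y_um"]].to_numpy(),
                           loc[["x_um", "y_um"]].to_numpy(),
                           transform, max_distance)
        for r, c, dist in pairs:
            rows.append({
                "trap": sub["trap"].iloc[0],
                "cell_id": cell_id,
                "frame": int(frame),
                "time_min": rep["time_min"].iloc[r],
                "distance_um": dist,
                "area_um2": float(area.get((cell_id, frame), np.nan)),
                "obs_id_replisome": rep["obs_id"].iloc[r],
                "obs_id_locus": loc["obs_id"].iloc[c],
            })
    return pd.DataFrame(rows, columns=["trap", "cell_id", "frame", "time_min",
                                       "distance_um", "area_um2",
                                       "obs_id_replisome", "obs_id_locus"])


def distance_by_area(pairs: pd.DataFrame, area_edges) -> pd.DataFrame:
    """Per-area-bin mean replisome-locus distance (empty bins kept)."""
    area_edges = np.asarray(area_edges, dtype=float)
    if not np.all(np.diff(area_edges) > 0):
        raise ValueError("area bin edges must be strictly increasing")
    idx = np.digitize(pairs["area_um2"].to_numpy(), area_edges) - 1
    rows = []
    for b in range(area_edges.size - 1):
        sub = pairs.loc[idx == b, "distance_um"]
        rows.append({
            "area_bin": b,
            "area_center": 0.5 * (area_edges[b] + area_edges[b + 1]),
            "n": int(len(sub)),
            "mean_distance_um": float(sub.mean()) if len(sub) else np.nan,
        })
    return pd.DataFrame(rows)
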