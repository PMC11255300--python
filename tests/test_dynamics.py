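"""RMSD pipeline, displacement statistics, spatial maps and minima."""

import math

import numpy as np
import pandas as pd
import pytest

from repliloc.dynamics import (
    AlignedTrajectorySet,
    align_on_initiation,
    compute_displacements,
    displacement_by_area,
    find_displacement_minimum,
    net_movement_percent,
    plateau_estimate,
    rmsd_curve,
    spatial_displacement_map,
    subtract_net_drift,
)
from repliloc.simulate import ou_exact_path


def make_aligned(long, short=None, lags=None, lengths=None):
    long = np.asarray(long, dtype=float)
    short = long.copy() if short is None else np.asarray(short, dtype=float)
    lags = np.arange(long.shape[1], dtype=float) if lags is None else lags
    lengths = np.full_like(long, 2.0) if lengths is None else lengths
    return AlignedTrajectorySet(lags, long, short, lengths,
                                np.arange(long.shape[0]))


class TestAlignOnInitiation:
    def _setup(self, event_frames):
        cells, traj, events = [], [], []
        for i, f0 in enumerate(event_frames):
            cid = i + 1
            for k in range(f0, f0 + 25):
                cells.append({"cell_id": cid, "trap": i, "parent_id": -1,
                              "frame": k, "time_min": float(k), "x_um": 0.0,
                              "y_um": -1.0, "orientation_rad": math.pi / 2,
                              "old_pole_sign": 1, "length_um": 2.0,
                              "width_um": 1.0, "area_um2": 2.0,
                              "birth_time_min": 0.0})
                traj.append({"trajectory_id": i, "channel": "replisome",
                             "trap": i, "cell_id": cid, "frame": k,
                             "time_min": float(k), "x_um": 0.0,
                             "y_um": -1.0 + 0.5 + 0.001 * (k - f0)})
            events.append({"event_id": i, "trap": i, "cell_id": cid,
                           "frame": f0, "time_min": float(f0),
                           "area_um2": 2.0, "trajectory_ids": str(i)})
        return (pd.DataFrame(traj), pd.DataFrame(events), pd.DataFrame(cells))

    def test_lag_grid_and_common_origin(self):
        traj, events, cells = self._setup([10, 17])
        aligned = align_on_initiation(traj, events, cells, window_min=20.0)
        assert aligned.lags_min[0] == 0.0 and aligned.lags_min[-1] == 20.0
        assert aligned.long.shape == (2, 21)
        # both trajectories start at their own event: lag-0 defined for both
        assert np.all(np.isfinite(aligned.long[:, 0]))

    def test_trajectory_without_event_excluded(self):
        traj, events, cells = self._setup([10, 17])
        aligned = align_on_initiation(traj, events.iloc[:1], cells)
        assert aligned.long.shape[0] == 1

    def test_mean_at_lag_zero_is_mean_start(self):
        traj, events, cells = self._setup([10, 12, 14])
        aligned = align_on_initiation(traj, events, cells)
        assert np.nanmean(aligned.long[:, 0]) == pytest.approx(0.5)


class TestDriftSubtraction:
    def test_common_drift_annihilated(self):
        lags = np.arange(21.0)
        drift = 0.03 * lags
        long = np.tile(0.5 + drift, (6, 1))
        corrected = subtract_net_drift(make_aligned(long))
        curve = rmsd_curve(corrected)
        assert np.allclose(curve["rmsd_long"], 0.0, atol=1e-12)
        assert np.allclose(curve["rmsd_short"], 0.0, atol=1e-12)

    def test_zero_mean_displacement_postcondition(self, rng):
        long = rng.normal(0.5, 0.1, (40, 21))
        corrected = subtract_net_drift(make_aligned(long))
        disp = corrected.long - corrected.long[:, [0]]
        assert np.allclose(disp.mean(axis=0), 0.0, atol=1e-12)

    def test_zero_drift_correction_is_small(self, rng):
        n = 400
        long = rng.normal(0.0, 0.1, (n, 21))
        corrected = subtract_net_drift(make_aligned(long.copy()))
        shift = np.abs(corrected.long - (long - long[:, [0]] * 0)).max()
        # correction per point is the mean of n iid values: O(sigma/sqrt(n))
        assert shift < 6 * (0.1 * math.sqrt(2)) / math.sqrt(n)

    def test_sparse_lag_reuses_last_mean(self):
        long = np.array([[0.0, 1.0, np.nan], [0.0, 1.0, np.nan]])
        corrected = subtract_net_drift(make_aligned(long))
        assert 2.0 in corrected.sparse_lags


class TestRMSDCurve:
    def test_frozen_trajectories_zero(self):
        curve = rmsd_curve(make_aligned(np.full((5, 10), 0.3)))
        assert np.allclose(curve["rmsd_long"], 0.0)

    def test_ou_closed_form(self, rng):
        # RMSD(t) = sigma * sqrt(2 (1 - exp(-t/tau))) for the stationary
        # mean-reverting process, checked at t = tau and t = 5 tau.
        sigma, tau, n = 0.15, 3.0, 800
        lags = np.arange(0.0, 21.0)
        paths = np.array([ou_exact_path(lags, sigma, tau, rng) for _ in range(n)])
        curve = rmsd_curve(make_aligned(paths, paths))
        for t in (tau, 5 * tau):
            j = int(t)
            expected = sigma * math.sqrt(2 * (1 - math.exp(-t / tau)))
            row = curve[curve["lag_min"] == lags[j]].iloc[0]
            assert abs(row["rmsd_long"] - expected) < 3 * row["sem_long"]

    def test_omits_empty_lags(self):
        long = np.array([[0.1, 0.2, np.nan]])
        curve = rmsd_curve(make_aligned(long))
        assert list(curve["lag_min"]) == [0.0, 1.0]


class TestPlateau:
    def test_constant_curve(self):
        curve = pd.DataFrame({"lag_min": np.arange(21.0),
                              "rmsd_long": 0.25, "sem_long": 0.01,
                              "rmsd_short": 0.12, "sem_short": 0.01,
                              "n": 100})
        out = plateau_estimate(curve, 10, 20)
        assert out["long"]["plateau_um"] == pytest.approx(0.25)
        assert out["short"]["plateau_um"] == pytest.approx(0.12)

    def test_closed_form_limit_is_sqrt2_sigma(self):
        sigma, tau = 0.177, 3.0
        lags = np.arange(0.0, 21.0)
        rmsd = sigma * np.sqrt(2 * (1 - np.exp(-lags / tau)))
        curve = pd.DataFrame({"lag_min": lags, "rmsd_long": rmsd,
                              "sem_long": 0.0, "rmsd_short": rmsd,
                              "sem_short": 0.0, "n": 1})
        out = plateau_estimate(curve, 10, 20)
        assert out["long"]["plateau_um"] == pytest.approx(
            math.sqrt(2) * sigma, rel=0.01)

    def test_empty_window_raises(self):
        curve = pd.DataFrame({"lag_min": [0.0, 1.0], "rmsd_long": [0, 0],
                              "sem_long": [0, 0], "rmsd_short": [0, 0],
                              "sem_short": [0, 0], "n": [1, 1]})
        with pytest.raises(ValueError):
            plateau_estimate(curve, 10, 20)


class TestNetMovement:
    def test_pure_drift_percent(self):
        lags = np.arange(16.0)
        long = np.tile(0.5 + 0.01 * lags, (10, 1))
        lengths = np.full_like(long, 2.5)
        aligned = make_aligned(long, long * 0, lags, lengths)
        out = net_movement_percent(aligned, 15.0)
        assert out["percent_of_length"] == pytest.approx(100 * 0.15 / 2.5)

    def test_requires_uncorrected_input(self):
        aligned = subtract_net_drift(make_aligned(np.random.default_rng(0)
                                                  .normal(0, 0.1, (5, 16))))
        with pytest.raises(ValueError):
            net_movement_percent(aligned, 15.0)


def doublet_df(rows):
    return pd.DataFrame(rows, columns=["trap", "channel", "frame", "cell_id",
                                       "time_min", "x1_um", "y1_um",
                                       "x2_um", "y2_um",
                                       "obs_id_first", "obs_id_second"])


def one_cell(length=2.0, area=2.0, theta=math.pi / 2, sign=1, n_frames=40):
    return pd.DataFrame([{
        "cell_id": 1, "trap": 0, "parent_id": -1, "frame": k,
        "time_min": float(k), "x_um": 0.0, "y_um": -length / 2,
        "orientation_rad": theta, "old_pole_sign": sign,
        "length_um": length, "width_um": 1.0, "area_um2": area,
        "birth_time_min": 0.0} for k in range(n_frames)])


class TestDisplacements:
    def test_zero_step(self):
        pairs = doublet_df([(0, "locus", 0, 1, 0.0, 0.1, -0.9, 0.1, -0.9, 0, 1)])
        rec = compute_displacements(pairs, one_cell())
        assert rec.iloc[0]["mag_um"] == 0.0

    def test_long_axis_step_components(self):
        # Cell points up: a +0.05 step in y is a +0.05 long-axis step.
        pairs = doublet_df([(0, "locus", 0, 1, 0.0, 0.0, -0.9, 0.0, -0.85, 0, 1)])
        rec = compute_displacements(pairs, one_cell())
        assert rec.iloc[0]["dlong_um"] == pytest.approx(0.05)
        assert rec.iloc[0]["dshort_um"] == pytest.approx(0.0, abs=1e-12)
        assert rec.iloc[0]["mag_um"] == pytest.approx(0.05)

    def test_rayleigh_mean_magnitude(self, rng):
        # Isotropic Gaussian steps of per-axis SD s: mean magnitude s*sqrt(pi/2)
        s, n = 0.04, 20_000
        steps = rng.normal(0.0, s, (n, 2))
        rows = [(0, "locus", k % 40, 1, 0.0, 0.0, -0.9,
                 steps[k, 0], -0.9 + steps[k, 1], 2 * k, 2 * k + 1)
                for k in range(n)]
        rec = compute_displacements(doublet_df(rows), one_cell())
        expected = s * math.sqrt(math.pi / 2)
        se = s * math.sqrt((2 - math.pi / 2) / n)
        assert rec["mag_um"].mean() == pytest.approx(expected, abs=4 * se)

    def test_rotation_invariance_of_magnitude(self, rng):
        steps = rng.normal(0.0, 0.05, (50, 2))
        rows = [(0, "locus", k % 40, 1, 0.0, 0.3, -0.9,
                 0.3 + steps[k, 0], -0.9 + steps[k, 1], 2 * k, 2 * k + 1)
                for k in range(50)]
        rec0 = compute_displacements(doublet_df(rows), one_cell())
        # rotate the whole lab frame by 40 degrees about the origin
        phi = math.radians(40.0)
        c, s = math.cos(phi), math.sin(phi)

        def rot(x, y):
            return c * x - s * y, s * x + c * y

        rows_rot = []
        for (trap, ch, fr, cid, t, x1, y1, x2, y2, o1, o2) in rows:
            rows_rot.append((trap, ch, fr, cid, t, *rot(x1, y1), *rot(x2, y2),
                             o1, o2))
        cells_rot = one_cell(theta=math.pi / 2 + phi)
        cx, cy = rot(0.0, -1.0)
        cells_rot["x_um"] = cx
        cells_rot["y_um"] = cy
        rec1 = compute_displacements(doublet_df(rows_rot), cells_rot)
        assert np.allclose(rec0["mag_um"], rec1["mag_um"], atol=1e-9)
        assert np.allclose(rec0["dlong_um"], rec1["dlong_um"], atol=1e-9)


class TestDisplacementByArea:
    def _records(self, areas, mags):
        return pd.DataFrame({"area_um2": areas, "mag_um": mags,
                             "long_um": 0.0, "short_um": 0.0})

    def test_constant_magnitude(self):
        rec = self._records([2.1, 2.2, 2.6, 2.7], [0.05] * 4)
        out = displacement_by_area(rec, [2.0, 2.5, 3.0])
        assert np.allclose(out["mean_mag_um"], 0.05)

    def test_two_populations_split_by_area(self):
        rec = self._records([2.1] * 10 + [2.9] * 10, [0.02] * 10 + [0.08] * 10)
        out = displacement_by_area(rec, [2.0, 2.5, 3.0])
        assert out.iloc[0]["mean_mag_um"] == pytest.approx(0.02)
        assert out.iloc[1]["mean_mag_um"] == pytest.approx(0.08)

    def test_empty_bins_reported(self):
        rec = self._records([2.1], [0.05])
        out = displacement_by_area(rec, [2.0, 2.5, 3.0])
        assert out.iloc[1]["n"] == 0 and np.isnan(out.iloc[1]["mean_mag_um"])


class TestSpatialMap:
    def _records(self, n, long=0.05, short=0.05, mag=0.07, area=2.1):
        return pd.DataFrame({"area_um2": [area] * n, "long_um": [long] * n,
                             "short_um": [short] * n, "mag_um": [mag] * n})

    def test_exactly_threshold_is_masked(self):
        smap = spatial_displacement_map(self._records(4), [2.0, 2.5],
                                        [0.0, 0.1], [0.0, 0.1],
                                        min_count_exclusive=4)
        assert np.isnan(smap.values[0, 0, 0])
        assert not smap.mask[0, 0, 0]

    def test_above_threshold_reports_mean(self):
        smap = spatial_displacement_map(self._records(5, mag=0.07),
                                        [2.0, 2.5], [0.0, 0.1], [0.0, 0.1],
                                        min_count_exclusive=4)
        assert smap.values[0, 0, 0] == pytest.approx(0.07)
        assert smap.mask[0, 0, 0]

    def test_empty_input_fully_masked(self):
        empty = self._records(0)
        smap = spatial_displacement_map(empty, [2.0, 2.5], [0.0, 0.1, 0.2],
                                        [0.0, 0.1])
        assert not smap.mask.any()

    def test_mask_equals_count_rule_exactly(self, rng):
        rec = pd.DataFrame({
            "area_um2": rng.uniform(2.0, 2.5, 500),
            "long_um": rng.uniform(-0.3, 0.3, 500),
            "short_um": rng.uniform(-0.2, 0.2, 500),
            "mag_um": rng.uniform(0.0, 0.1, 500),
        })
        smap = spatial_displacement_map(rec, [2.0, 2.5],
                                        np.arange(-0.3, 0.31, 0.1),
                                        np.arange(-0.2, 0.21, 0.1), 4)
        assert np.array_equal(smap.mask, smap.counts > 4)
        assert np.all(np.isnan(smap.values[~smap.mask]))


class TestDisplacementMinimum:
    def _records_from_profile(self, centers, means, n_per_bin=50):
        areas, mags = [], []
        for c, m in zip(centers, means):
            areas.extend([c] * n_per_bin)
            mags.extend([m] * n_per_bin)
        return pd.DataFrame({"area_um2": areas, "mag_um": mags})

    def test_v_shape_vertex(self):
        edges = np.arange(2.0, 2.0 + 0.25 * 11 + 1e-9, 0.25)
        centers = 0.5 * (edges[:-1] + edges[1:])
        means = np.abs(np.arange(10) - 7) * 0.01 + 0.02
        rec = self._records_from_profile(centers, means)
        est = find_displacement_minimum(rec, edges, smoothing_bins=1,
                                        n_bootstrap=10)
        assert est.area_um2 == pytest.approx(centers[7])

    def test_quadratic_vertex(self):
        edges = np.arange(1.0, 4.01, 0.25)
        centers = 0.5 * (edges[:-1] + edges[1:])
        means = 0.02 + 0.01 * (centers - 2.6) ** 2
        rec = self._records_from_profile(centers, means)
        est = find_displacement_minimum(rec, edges, smoothing_bins=3,
                                        n_bootstrap=10)
        # analytic vertex at 2.6 -> bin containing it
        assert abs(est.area_um2 - 2.625) < 1e-9

    def test_flat_profile_flagged_undefined(self):
        edges = np.arange(2.0, 3.01, 0.25)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rec = self._records_from_profile(centers, [0.05] * len(centers))
        est = find_displacement_minimum(rec, edges, n_bootstrap=5)
        assert not est.defined

    def test_needs_three_bins(self):
        rec = pd.DataFrame({"area_um2": [2.1] * 5, "mag_um": [0.05] * 5})
        with pytest.raises(ValueError):
            find_displacement_minimum(rec, np.arange(2.0, 3.01, 0.25))
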