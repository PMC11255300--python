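"""Synthetic mother-machine lineages with replisome and locus ground truth.

The generator embodies the picture the analysis pipeline is built to test:
cells grow exponentially and divide by a sizer; replication initiates when
the cell area crosses ``A_init``, spawning two replisome clusters whose
home positions track the +/- quarter points of the long axis for one
C-period; replisomes fluctuate around their homes as a stationary
mean-reverting (Ornstein-Uhlenbeck) process; the labeled chromosomal locus
sits at a pole-proximal home, relocates to the nearest replisome home
shortly before its predicted replication time ``t_init + C*alpha``, moves
with the replisome's small step size while replicated, and then segregates
into the two daughter-cell home positions.  Observations are emitted on
the imaging schedule (one frame per minute plus a paired frame 1 s later)
with isotropic Gaussian localization noise and random detection misses.

All randomness flows from a single root seed through per-trap child
streams, so adding traps does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, PipelineConfig, locus_step_to_sigma
from .model import predicted_replication_area

__all__ = ["SimulationResult", "simulate", "ou_exact_path"]

_FLUSHED_ID_OFFSET = 1_000_000

# Column orders for the emitted tables (the CSV schemas in io.py match).
CELL_COLUMNS = [
    "cell_id", "trap", "parent_id", "frame", "time_min", "x_um", "y_um",
    "orientation_rad", "old_pole_sign", "length_um", "width_um", "area_um2",
    "birth_time_min",
]
TRUTH_COLUMNS = [
    "particle_id", "species", "locus_name", "state", "trap", "cell_id",
    "frame", "tag", "time_min", "x_um", "y_um",
]
OBS_COLUMNS = [
    "obs_id", "channel", "trap", "cell_id", "frame", "tag", "time_min",
    "x_um", "y_um", "loc_sd_um", "truth_particle_id",
]
EVENT_COLUMNS = [
    "event_id", "trap", "cell_id", "frame", "time_min", "t_init_min",
    "area_init_um2", "area_frame_um2",
]
DIVISION_COLUMNS = [
    "trap", "mother_id", "daughter_kept_id", "daughter_flushed_id", "time_min",
]
LANDMARK_COLUMNS = ["landmark_id", "x_ref_um", "y_ref_um", "x_mov_um", "y_mov_um"]


@dataclass
class SimulationResult:
    """Bundle of generator outputs (tables share cell/particle keys)."""

    cells: pd.DataFrame
    truth: pd.DataFrame
    observations: pd.DataFrame
    events: pd.DataFrame
    divisions: pd.DataFrame
    landmarks: pd.DataFrame
    config: PipelineConfig


def ou_exact_path(
    times: np.ndarray,
    sigma: np.ndarray | float,
    tau: np.ndarray | float,
    rng: np.random.Generator,
    x0: float | None = None,
) -> np.ndarray:
    """Sample a mean-reverting fluctuation at arbitrary times, exactly.

    Uses the exact discrete update
    ``x(t+d) = x(t)*exp(-d/tau) + N(0, sigma^2*(1 - exp(-2d/tau)))`` so the
    path has the stationary SD ``sigma`` and correlation time ``tau`` at
    every sampling interval, with no time-step bias.  ``sigma`` and ``tau``
    may be arrays (one value per sample) for piecewise-stationary paths;
    when ``sigma`` changes between samples the carried fluctuation is
    rescaled by the ratio of the new to old SD so the path enters the new
    regime already at stationarity.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    tu = np.broadcast_to(np.asarray(tau, dtype=float), (n,))
    if np.any(sig < 0):
        raise ConfigError("OU sigma must be >= 0")
    if np.any(tu <= 0):
        raise ConfigError("OU tau must be > 0")
    out = np.empty(n)
    if n == 0:
        return out
    x = rng.normal(0.0, sig[0]) if x0 is None else float(x0)
    out[0] = x
    for k in range(1, n):
        if sig[k] != sig[k - 1]:
            x = x * (sig[k] / sig[k - 1]) if sig[k - 1] > 0 else rng.normal(0.0, sig[k])
        d = times[k] - times[k - 1]
        decay = math.exp(-d / tu[k])
        sd = sig[k] * math.sqrt(max(0.0, 1.0 - decay * decay))
        x = x * decay + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        out[k] = x
    return out


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the given mean and coefficient of variation."""
    if cv <= 0:
        return mean
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(math.log(mean) - 0.5 * s2, math.sqrt(s2)))


@dataclass
class _Cycle:
    """One cell cycle of the retained (mother) lineage in a trap."""

    cell_id: int
    parent_id: int
    t_birth: float
    t_div: float
    a_birth: float
    mu: float
    t_init: float | None
    a_init_threshold: float

    def area(self, t) -> np.ndarray | float:
        return self.a_birth * np.exp(self.mu * (np.asarray(t) - self.t_birth))


def _plan_trap(cfg: PipelineConfig, trap: int, rng: np.random.Generator) -> list[_Cycle]:
    g, sched, m = cfg.growth, cfg.schedule, cfg.model
    mu0 = m.mu
    cycles: list[_Cycle] = []
    t = 0.0
    a_birth = _lognormal(rng, g.birth_area_mean, g.division_cv)
    parent = -1
    k = 0
    while t < sched.duration_min:
        mu_c = mu0 * max(0.1, 1.0 + rng.normal(0.0, g.growth_rate_cv))
        a_div = _lognormal(rng, g.division_factor * g.birth_area_mean, g.division_cv)
        a_div = max(a_div, a_birth * 1.05)  # a newborn is never already past the sizer
        t_div = t + math.log(a_div / a_birth) / mu_c
        a_init = _lognormal(rng, m.a_init, g.init_area_cv)
        if a_birth >= a_init:
            t_init: float | None = t
        elif a_init < a_div:
            t_init = t + math.log(a_init / a_birth) / mu_c
        else:
            t_init = None
        cell_id = trap * 1000 + k
        cycles.append(_Cycle(cell_id, parent, t, t_div, a_birth, mu_c, t_init, a_init))
        parent = cell_id
        a_birth = a_div / 2.0
        t = t_div
        k += 1
    return cycles


def _sample_times(cfg: PipelineConfig, t_from: float, t_to: float):
    """Frame/doublet sampling times in [t_from, t_to): (times, frames, tags)."""
    sched = cfg.schedule
    dt = sched.frame_interval_min
    d1s = sched.doublet_offset_s / 60.0
    k0 = max(0, math.ceil((t_from - 1e-9) / dt))
    k1 = math.floor((t_to - 1e-9) / dt)
    times, frames, tags = [], [], []
    n_frames_total = int(math.floor(sched.duration_min / dt))
    for k in range(k0, min(k1, n_frames_total - 1) + 1):
        tk = k * dt
        times.extend([tk, tk + d1s])
        frames.extend([k, k])
        tags.extend(["first", "second"])
    # Doublet second frames may poke past t_to by 1 s; keep them with the
    # cycle that owns the first frame so doublet pairs never straddle cells.
    return np.asarray(times), np.asarray(frames, dtype=int), tags


def _track_rows(rows, particle_id, species, locus_name, states, cyc, trap, cfg,
                times, frames, tags, rel_home, fl_long, fl_short):
    w = cfg.growth.width_um
    length = np.asarray(cyc.area(times)) / w
    x_trap = trap * cfg.schedule.trap_spacing_um
    y = -length / 2.0 + rel_home * length + fl_long
    x = x_trap + fl_short
    for i in range(times.size):
        rows.append((particle_id, species, locus_name, states[i], trap, cyc.cell_id,
                     int(frames[i]), tags[i], float(times[i]), float(x[i]), float(y[i])))


def _simulate_replisomes(cfg, cyc, trap, rng, truth_rows):
    """Two confined clusters homed at +/- L(t)/4 from initiation for one C-period."""
    if cyc.t_init is None:
        return []
    rep = cfg.replisome
    t_end = min(cyc.t_init + cfg.model.c_period, cyc.t_div)
    times, frames, tags = _sample_times(cfg, cyc.t_init, t_end)
    ids = []
    for sign, suffix in ((+1, "P"), (-1, "M")):
        pid = f"c{cyc.cell_id}_rep{suffix}"
        ids.append(pid)
        if times.size == 0:
            continue
        fl_long = ou_exact_path(times, rep.sigma_long, rep.tau_min, rng)
        fl_short = ou_exact_path(times, rep.sigma_short, rep.tau_min, rng)
        states = ["replisome"] * times.size
        _track_rows(truth_rows, pid, "replisome", "", states, cyc, trap, cfg,
                    times, frames, tags, sign * 0.25, fl_long, fl_short)
    return ids


def _locus_state_params(cfg: PipelineConfig):
    """(sigma_long, sigma_short, tau) per locus state, from 1-s step SDs."""
    loc, rep = cfg.locus, cfg.replisome
    d1s = cfg.schedule.doublet_offset_s / 60.0
    slow = locus_step_to_sigma(loc.step_sd_long, loc.tau_min, d1s)
    ssho = locus_step_to_sigma(loc.step_sd_short, loc.tau_min, d1s)
    base = (slow, ssho, loc.tau_min)
    if loc.replicating_step_sd_long is None:
        repl = (rep.sigma_long, rep.sigma_short, rep.tau_min)
    else:
        repl = (
            locus_step_to_sigma(loc.replicating_step_sd_long, loc.tau_min, d1s),
            locus_step_to_sigma(loc.replicating_step_sd_short or 0.0, loc.tau_min, d1s),
            loc.tau_min,
        )
    return {
        "home": base,
        "relocating": base,
        "replicating": repl,
        "segregating": base,
    }


def _simulate_locus(cfg, cyc, trap, rng, truth_rows) -> None:
    """State-machine locus track(s) for one cell cycle."""
    loc = cfg.locus
    params = _locus_state_params(cfg)
    f0 = loc.resolved_home_fraction()
    if loc.home_side == "old":
        f = -f0
    elif loc.home_side == "random":
        f = f0 if rng.random() < 0.5 else -f0
    else:
        f = f0
    r = 0.25 if f > 0 else -0.25  # nearest replisome home

    if cyc.t_init is not None:
        t_rep = cyc.t_init + cfg.model.c_period * loc.alpha
    else:
        t_rep = math.inf
    t_reloc = max(cyc.t_birth, t_rep - loc.lead_time_min)
    t_seg0 = t_rep + loc.dwell_min
    t_seg1 = t_seg0 + loc.segregation_min

    def pre_fork_state(t: float) -> str:
        if t < t_reloc:
            return "home"
        if t < t_rep:
            return "relocating"
        return "replicating"

    def pre_fork_home(t: float) -> float:
        if t < t_reloc:
            return f
        if t < t_rep:
            span = t_rep - t_reloc
            frac = (t - t_reloc) / span if span > 0 else 1.0
            return f + (r - f) * frac
        return r

    t_fork = min(t_seg0, cyc.t_div)
    times, frames, tags = _sample_times(cfg, cyc.t_birth, t_fork)
    states = [pre_fork_state(t) for t in times]
    homes = np.array([pre_fork_home(t) for t in times])
    sig_l = np.array([params[s][0] for s in states])
    sig_s = np.array([params[s][1] for s in states])
    taus = np.array([params[s][2] for s in states])
    fl_long = ou_exact_path(times, sig_l, taus, rng)
    fl_short = ou_exact_path(times, sig_s, taus, rng)
    pid = f"c{cyc.cell_id}_loc"
    _track_rows(truth_rows, pid, "locus", loc.name, states, cyc, trap, cfg,
                times, frames, tags, homes, fl_long, fl_short)

    if t_seg0 >= cyc.t_div:
        return  # replication/segregation did not complete before division

    # Fork: two copies, ramping to the daughter home positions (in mother
    # coordinates) or jointly to mid-cell for an anchored (Ter-like) locus.
    if loc.anchored:
        targets = {"U": 0.0, "D": 0.0}
    else:
        targets = {"U": 0.25 + 0.5 * f, "D": -0.25 + 0.5 * f}
    x_l0 = fl_long[-1] if fl_long.size else None
    x_s0 = fl_short[-1] if fl_short.size else None
    times2, frames2, tags2 = _sample_times(cfg, t_fork, cyc.t_div)
    if times2.size == 0:
        return
    for suffix, target in targets.items():

        def seg_home(t: float) -> float:
            span = t_seg1 - t_seg0
            frac = min(1.0, (t - t_seg0) / span) if span > 0 else 1.0
            return r + (target - r) * frac

        states2 = ["segregating" if t < t_seg1 else "home" for t in times2]
        homes2 = np.array([seg_home(t) for t in times2])
        sig_l2 = np.array([params[s][0] for s in states2])
        sig_s2 = np.array([params[s][1] for s in states2])
        taus2 = np.array([params[s][2] for s in states2])
        fl_l2 = ou_exact_path(times2, sig_l2, taus2, rng, x0=x_l0)
        fl_s2 = ou_exact_path(times2, sig_s2, taus2, rng, x0=x_s0)
        _track_rows(truth_rows, f"{pid}{suffix}", "locus", loc.name, states2, cyc,
                    trap, cfg, times2, frames2, tags2, homes2, fl_l2, fl_s2)


def _render_observations(cfg, truth: pd.DataFrame, rng: np.random.Generator,
                         start_obs_id: int) -> pd.DataFrame:
    """Noisy detections from ground-truth positions (one trap at a time)."""
    noise, reg = cfg.noise, cfg.registration
    n = len(truth)
    keep = rng.random(n) >= noise.miss_prob
    t = truth.loc[keep]
    is_locus = (t["species"] == "locus").to_numpy()
    sd = np.where(is_locus, noise.loc_sd_locus, noise.loc_sd_replisome)
    x = t["x_um"].to_numpy() + rng.normal(0.0, 1.0, keep.sum()) * sd
    y = t["y_um"].to_numpy() + rng.normal(0.0, 1.0, keep.sum()) * sd
    # The locus channel is imaged on a different part of the camera: apply
    # the chromatic offset that landmark registration must later undo.
    x = x + np.where(is_locus, reg.dx_um, 0.0)
    y = y + np.where(is_locus, reg.dy_um, 0.0)
    return pd.DataFrame({
        "obs_id": np.arange(start_obs_id, start_obs_id + keep.sum()),
        "channel": np.where(is_locus, "locus", "replisome"),
        "trap": t["trap"].to_numpy(),
        "cell_id": t["cell_id"].to_numpy(),
        "frame": t["frame"].to_numpy(),
        "tag": t["tag"].to_numpy(),
        "time_min": t["time_min"].to_numpy(),
        "x_um": x,
        "y_um": y,
        "loc_sd_um": sd,
        "truth_particle_id": t["particle_id"].to_numpy(),
    })


def _make_landmarks(cfg: PipelineConfig, rng: np.random.Generator) -> pd.DataFrame:
    reg = cfg.registration
    coords = np.arange(reg.grid_n) * reg.grid_spacing_um
    gx, gy = np.meshgrid(coords, coords)
    gx, gy = gx.ravel(), gy.ravel()
    jr = rng.normal(0.0, reg.jitter_sd_um, (gx.size, 2))
    jm = rng.normal(0.0, reg.jitter_sd_um, (gx.size, 2))
    return pd.DataFrame({
        "landmark_id": np.arange(gx.size),
        "x_ref_um": gx + jr[:, 0],
        "y_ref_um": gy + jr[:, 1],
        "x_mov_um": gx + reg.dx_um + jm[:, 0],
        "y_mov_um": gy + reg.dy_um + jm[:, 1],
    })


def simulate(config: PipelineConfig, seed: int | None = None) -> SimulationResult:
    """Run the generator.  ``seed`` overrides ``config.seed`` when given."""
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    sched, g = config.schedule, config.growth
    dt = sched.frame_interval_min
    n_frames = int(math.floor(sched.duration_min / dt))
    trap_seeds = root.spawn(sched.n_traps + 1)

    cell_rows, truth_rows, event_rows, div_rows = [], [], [], []
    obs_frames = []
    next_obs_id = 0
    for trap in range(sched.n_traps):
        rng = np.random.default_rng(trap_seeds[trap])
        cycles = _plan_trap(config, trap, rng)
        trap_truth_start = len(truth_rows)
        theta = math.pi / 2 if trap % 2 == 0 else -math.pi / 2
        pole_sign = 1 if trap % 2 == 0 else -1
        x_trap = trap * sched.trap_spacing_um
        for cyc in cycles:
            k0 = max(0, math.ceil((cyc.t_birth - 1e-9) / dt))
            k1 = min(math.floor((cyc.t_div - 1e-9) / dt), n_frames - 1)
            for k in range(k0, k1 + 1):
                tk = k * dt
                area = float(cyc.area(tk))
                length = area / g.width_um
                cell_rows.append((cyc.cell_id, trap, cyc.parent_id, k, tk, x_trap,
                                  -length / 2.0, theta, pole_sign, length,
                                  g.width_um, area, cyc.t_birth))
            if cyc.t_init is not None and cyc.t_init < sched.duration_min:
                kf = max(k0, math.ceil((cyc.t_init - 1e-9) / dt))
                if kf <= k1:
                    event_rows.append((len(event_rows), trap, cyc.cell_id, kf, kf * dt,
                                       cyc.t_init, float(cyc.area(cyc.t_init)),
                                       float(cyc.area(kf * dt))))
            _simulate_replisomes(config, cyc, trap, rng, truth_rows)
            _simulate_locus(config, cyc, trap, rng, truth_rows)
            if cyc.t_div < sched.duration_min:
                div_rows.append((trap, cyc.cell_id, cyc.cell_id + 1,
                                 cyc.cell_id + _FLUSHED_ID_OFFSET, cyc.t_div))
        trap_truth = pd.DataFrame(truth_rows[trap_truth_start:], columns=TRUTH_COLUMNS)
        obs = _render_observations(config, trap_truth, rng, next_obs_id)
        next_obs_id += len(obs)
        obs_frames.append(obs)

    landmark_rng = np.random.default_rng(trap_seeds[-1])
    landmarks = _make_landmarks(config, landmark_rng)

    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    observations = (
        pd.concat(obs_frames, ignore_index=True) if obs_frames
        else pd.DataFrame(columns=OBS_COLUMNS)
    )
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    divisions = pd.DataFrame(div_rows, columns=DIVISION_COLUMNS)
    return SimulationResult(cells, truth, observations, events, divisions,
                            landmarks, config)
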