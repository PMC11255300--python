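"""Shared fixtures: small simulation configs and the default-scale run."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from repliloc import dynamics, tracking
from repliloc.config import (
    GrowthConfig,
    LocusConfig,
    NoiseConfig,
    PipelineConfig,
    RegistrationConfig,
    ScheduleConfig,
)
from repliloc.simulate import simulate


def replace(cfg, **sections):
    """dataclasses.replace over nested config sections."""
    return dataclasses.replace(cfg, **sections)


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    """4 traps, 2 h: enough cycles for structural checks, runs in ~1 s."""
    cfg = PipelineConfig()
    return replace(cfg, schedule=dataclasses.replace(
        cfg.schedule, n_traps=4, duration_min=120.0), seed=101)


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate(tiny_config)


@pytest.fixture(scope="session")
def noise_free_config() -> PipelineConfig:
    """Deterministic generator: spec'd sizer example (birth 1.3, divide 2.6)."""
    cfg = PipelineConfig()
    return replace(
        cfg,
        growth=GrowthConfig(birth_area_mean=1.3, growth_rate_cv=0.0,
                            division_cv=0.0, init_area_cv=0.0),
        schedule=dataclasses.replace(cfg.schedule, n_traps=2, duration_min=120.0),
        noise=NoiseConfig(loc_sd_replisome=0.0, loc_sd_locus=0.0, miss_prob=0.0),
        registration=RegistrationConfig(dx_um=0.0, dy_um=0.0, jitter_sd_um=0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_sim(noise_free_config):
    return simulate(noise_free_config)


@pytest.fixture(scope="session")
def default_run():
    """Default-condition run: simulate, link, detect initiation, align.

    This is the package's standard synthetic experiment (56 traps, 5 h at
    1/min imaging), sized to give >= 457 initiation-aligned replisome
    trajectories and >= 300 initiation events.
    """
    cfg = dataclasses.replace(PipelineConfig(), seed=1)
    sim = simulate(cfg)
    t = cfg.tracking
    traj = tracking.link_foci(sim.observations, sim.cells, t.max_disp_um, t.max_gap)
    events = tracking.detect_initiation(traj, sim.cells, t.min_lifetime,
                                        t.exclusion_radius_um)
    aligned = dynamics.align_on_initiation(
        traj, events, sim.cells, cfg.analysis.rmsd_window_min,
        cfg.schedule.frame_interval_min)
    return {"config": cfg, "sim": sim, "trajectories": traj,
            "events": events, "aligned": aligned}


def make_locus_run(alpha: float, seed: int, anchored: bool = False):
    """Single-locus experiment sized so the replication dip in the 1-s step
    profile is several standard errors deep in its area bin."""
    cfg = PipelineConfig()
    cfg = replace(
        cfg,
        schedule=dataclasses.replace(cfg.schedule, n_traps=24, duration_min=360.0),
        locus=LocusConfig(name=f"a{alpha:g}", alpha=alpha, anchored=anchored),
        seed=seed,
    )
    sim = simulate(cfg)
    doublets = tracking.link_doublets(sim.observations,
                                      cfg.tracking.doublet_gate_um)
    records = dynamics.compute_displacements(doublets, sim.cells)
    return cfg, sim, records


@pytest.fixture
def rng():
    return np.random.default_rng(42)
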