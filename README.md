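# repliloc

Analysis pipeline for the question of **where DNA replication happens in
the *E. coli* cell**: do the two replisomes travel along the chromosome
arms, or do they stay spatially confined while the chromosome moves
through them?  The package implements, as a tested and reusable library,
the quantitative analyses by which dual-color mother-machine tracking
data (a replisome label and one FROS-labeled chromosomal locus per
strain) discriminates between the two pictures — together with a
synthetic lineage generator that embodies the confined-replisome picture,
so every stage is testable end to end without microscopy data.

It is written for microscopists and quantitative biologists working with
per-frame focus coordinates and cell outlines (no raw images): the inputs
are plain CSV tables of detected foci, cell geometry, lineage links and
fiducial landmarks.

## What it computes

* **Cell-internal coordinates** (`repliloc.coords`) — foci projected onto
  the long/short axes of their cell, old pole up; area-binned 2D
  foci-per-cell histograms; per-cluster 2D Normal fits whose standard
  deviations σ predict the RMSD plateau of a confined particle as √2·σ.
* **Tracking** (`repliloc.tracking`) — per-frame optimal-assignment foci
  linking with gap closing, and replication-initiation detection as
  filtered replisome-trajectory starts, recording the cell area at
  initiation.
* **Initiation-aligned RMSD** (`repliloc.dynamics`) — trajectories
  re-timed to their initiation event, ensemble net average movement
  subtracted per time point, RMSD per axis

      RMSD(t) = sqrt( mean_i [x_i(t) − x_i(0)]² ),

  which plateaus at √2·σ for confinement SD σ.
* **1-second displacements** (`repliloc.dynamics`) — steps between frame
  doublets acquired 1 s apart, binned by cell area and by intracellular
  position (bins with ≤ 4 steps masked), and the cell area at the step
  minimum with a bootstrap CI.
* **Two-channel registration and pairing** (`repliloc.pairing`) — affine
  landmark registration of the locus channel onto the replisome channel,
  one-to-one minimum-total-distance foci pairing, and replisome–locus
  distance versus cell area.
* **Replication-size model** (`repliloc.model`) — the cell area at which
  a locus at genomic fraction α (distance from *oriC* over half the
  chromosome) is replicated, for exponentially growing cells and a
  constant fork rate:

      A(α) = A_init · exp(µ · C · α),   µ = ln 2 / T_d

  with defaults A_init = 2.05 µm², C = 45 min, T_d = 50 min.
* **Synthetic generator** (`repliloc.simulate`) — mother-machine lineages
  with exponential growth and a sizer division rule; two replisome
  clusters spawned at the ±L/4 long-axis positions at initiation,
  fluctuating around those homes as an exact-discretized
  Ornstein–Uhlenbeck process for one C-period; a locus that relocates to
  the replisome home before its replication time t_init + C·α, steps like
  the replisome while replicated, then segregates; Gaussian localization
  noise, detection misses, chromatic offset and fiducials.

## Worked example

The numbered drivers under `analysis/` run the default synthetic
experiment (56 traps, 5 h at 1/min with 1-s doublets) and print what they
find; tables and figures land under `results/run/`:

```
$ python analysis/01_simulate.py
simulated 362 cells in 56 traps over 300 min
114972 focus observations, 352 true initiation events (mean area at the initiation threshold crossing 2.114 um^2)

$ python analysis/02_track_initiation.py
linked 1792 trajectories; 338 initiation events (generator logged 352)
mean cell area at detected initiation: 2.129 +/- 0.006 um^2 (model A_init = 2.05 um^2)

$ python analysis/04_rmsd.py
642 initiation-aligned replisome trajectories
net outward movement over 15 min (30% of a generation): 4.88 +/- 0.41 % of cell length
long-axis RMSD plateau (lags 10-20 min): 0.2411 +/- 0.0065 um (sqrt(2) x sigma = 0.2503 um)
short-axis RMSD plateau (lags 10-20 min): 0.1211 +/- 0.0034 um (sqrt(2) x sigma = 0.1202 um)
```

Read: initiation is detected within ~4% of the 2.05-µm² threshold (the
small excess is frame discretization plus cells born above threshold);
the replisome wanders only ~5% of a cell length per 30% of a generation,
yet its RMSD plateaus — it is dynamically confined to a region of
~0.25 µm (long axis) by ~0.12 µm (short axis), matching √2 times the
fitted location-distribution SDs.  `03_locations.py`,
`05_displacements.py` and `06_pairing_distance.py` add the location
histograms, the 1-s step minimum of the locus (at the predicted A(α)) and
the replisome–locus distance minimum.

The same pipeline is scriptable end to end:

```
repliloc all --seed 1 --outdir results/run    # or: python -m repliloc.cli
```

and stage by stage (`simulate`, `track`, `analyze`, `report`) with a TOML
config overriding any default (see `repliloc.config`).

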