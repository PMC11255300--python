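# Methods

This note records the models, estimators and design choices behind
`repliloc`, in the order data flows through the pipeline.

## The generative picture

The package tests analyses against a synthetic embodiment of the
confined-replisome model of bacterial DNA replication:

* **Growth and division.** Each mother-machine trap holds one retained
  lineage.  Cell area grows exponentially, A(t) = A_birth·exp(µ_c t),
  with per-cell rate µ_c = µ·(1 + ε), ε ~ N(0, 0.05), µ = ln2/T_d.
  Division is a sizer: the cell divides when its area crosses a threshold
  2·Ā_birth·LN(CV 0.1) drawn per cycle against the population mean birth
  area Ā_birth (a fixed-target sizer keeps birth sizes stationary over
  arbitrarily many generations, which a "2× own birth area" rule does
  not).  The retained daughter keeps the mother's old pole; the other
  daughter is flushed.  Geometry: constant width W = 1 µm (the
  microfluidic channel width), length L = A/W, old pole up.
* **Initiation and replisomes.** When the area crosses
  A_init·LN(CV 0.02) (A_init = 2.05 µm²; cells born above threshold
  initiate at birth), two replisome clusters appear whose *home*
  positions are the ±L(t)/4 long-axis points, and persist for one
  C-period (45 min).  Around the moving home each cluster fluctuates as a
  stationary Ornstein–Uhlenbeck (OU) process per axis, simulated with the
  exact discrete update x(t+Δ) = x(t)·e^(−Δ/τ) + N(0, σ²(1 − e^(−2Δ/τ)))
  at both the 1-min frame grid and the 1-s doublet offsets, so there is
  no time-step bias at either scale.  Defaults σ_long = 0.177 µm,
  σ_short = 0.085 µm (calibrated as plateau/√2 from the ~0.25/~0.12-µm
  RMSD plateaus they should reproduce) and τ = 3 min (not an observable
  of the analyses; chosen so the plateau is reached well inside the
  20-min RMSD window).  Because home = ±L(t)/4, the clusters acquire a
  small outward net drift as the cell grows — ΔL/4 ≈ L·(e^(µ·0.3T_d)−1)/4
  ≈ 5% of a cell length per 30% of a generation — without a separate
  drift parameter.
* **The labeled locus.**  One locus per experiment (as in a FROS strain),
  at genomic fraction α.  Its replication time is t_init + C·α (constant
  fork rate), hence the predicted replication area A(α) =
  A_init·exp(µCα).  A state machine drives the home position: *home* at a
  pole-proximal fraction (default −(0.25 + 0.25α); −0.5 for an anchored,
  Ter-like locus), *relocating* along a linear ramp to the nearest
  replisome home starting 10 min before replication, *replicating* at the
  replisome home for a 4-min dwell, then *segregating* over 10 min as the
  track forks into two copies ramping to the two daughter home positions
  (an anchored locus instead keeps both copies at mid-cell).  Each state
  has a configured per-axis 1-s step SD (home 0.035/0.018 µm;
  replicating defaults to the replisome's implied step), converted to the
  OU stationary SD via step = σ·√(2(1 − e^(−Δ₁ₛ/τ))) with τ = 1 min; the
  carried fluctuation is rescaled at state changes so each regime starts
  at stationarity.  The lead/dwell/segregation durations are not
  observables with printed values; they are order-10-min transition
  choices.  A `home_side` switch (new/old/random) creates the
  two-subpopulation structure seen for mid-replichore loci at slow
  growth.
* **Observation model.**  Every ground-truth position at a scheduled
  frame yields a detection with isotropic Gaussian error (20 nm per
  channel) and a 2% miss probability; each frame has a doublet partner
  1 s later.  The locus channel is shifted by a chromatic offset
  (default (0.03, −0.02) µm) that landmark registration must undo; a
  5×5 fiducial grid with 5-nm jitter is emitted alongside.  No images,
  PSFs, bleaching or blinking are modeled.

What passing tests show — and do not show.  The generator reproduces the
*statistical structure* the analyses consume (confined homes, calibrated
step sizes, schedule, noise), so green tests demonstrate that the
estimators recover known inputs at realistic noise and sample sizes.
They do not validate segmentation, spot detection or localization on real
images (out of scope; the pipeline starts from coordinates), nor do they
test merge/split ambiguity of overlapping foci, sister-locus cohesion, or
multi-round overlapping replication, none of which the generator emits.

## Estimators

* **Internal coordinates.**  Rotation/translation by the cell's centroid
  and orientation; the long-axis sign is fixed by the stored old-pole
  identity so positive always points to the old pole.  Foci that fall
  outside the outline due to noise are kept — clipping would bias the
  fitted SDs.
* **Location histograms** are normalized to foci per cell per bin (counts
  divided by cell-frames in the area bin); all panels share one spatial
  grid (0.1-µm bins; 0.25-µm² area bins — bin sizes are package
  defaults, configurable).  Gaussian location fits are per half-cell
  cluster (sign of rel. long position) and per area bin, axis-independent
  sample mean/SD, flagged invalid under 10 foci.
* **Linker.**  Per lineage and channel, frame-to-frame one-to-one
  assignment minimizing summed squared distance (Hungarian algorithm)
  with a hard 0.5-µm gate and gap closing up to 2 frames; unmatched
  detections found new trajectories.  Full multiple-hypothesis
  merge/split tracking is deliberately out of scope — the data the
  package consumes do not require it.  The 1-s doublets are linked with
  the same assignment under a tighter 0.3-µm gate.
* **Initiation detection.**  A replisome-trajectory start is an event if
  the trajectory spans ≥ 5 frames and no other replisome focus was within
  0.5 µm in the preceding frame (suppressing re-detections after
  transient focus splitting).  Simultaneous starts in one cell merge into
  a single event (the sister clusters spawn ~1 µm apart), and only the
  earliest event per cell is kept, matching the one-round-per-cycle
  regime.  The event area is the cell's area at the start frame; it
  overestimates the threshold slightly (≈ +3%) from frame discretization
  plus cells born above threshold — visible in the worked example.
* **RMSD.**  Trajectories are re-timed to lag 0 at their event; a
  trajectory missing its lag-0 detection is excluded (the reference point
  would be undefined).  The long coordinate is sign-adjusted per cluster
  (outward positive) so the two clusters' common outward drift can be
  removed by one per-lag ensemble mean; after subtraction the mean
  displacement-from-start is identically zero at every lag.  RMSD is
  referenced to the lag-0 position (not consecutive-lag MSD).  SEM is
  propagated from the variance of squared displacements,
  sem(RMSD) = sem(d²)/(2·RMSD); the plateau over lags 10–20 min uses the
  mean of per-lag SEMs without √n reduction because adjacent lags of the
  same trajectories are strongly correlated (a conservative choice).
  Lags with < 2 trajectories reuse the last valid drift mean and are
  flagged.
* **Net movement** is the ensemble-mean outward-signed displacement over
  a 0.3·T_d window divided by the mean cell length — the *net average*
  movement that drift subtraction removes, not the mean absolute
  per-trajectory displacement, which would be dominated by the confined
  fluctuation (√2·σ ≈ 0.25 µm) rather than by transport.
* **Displacement minima.**  Per-area-bin means of the 1-s step length are
  smoothed with a centered 3-bin moving average before the argmin; the
  reported value is a bin center and the CI is a 200-resample
  within-bin bootstrap percentile interval.  With 0.25-µm² bins and a
  replication dwell spanning roughly one bin, the estimate is reliable to
  about one bin.  A flat profile is flagged undefined; fewer than three
  non-empty bins is an error.  Spatial maps report a bin only if it holds
  strictly more than 4 steps (first-point bin assignment).
* **Registration and pairing.**  Least-squares affine fit (moving =
  locus → reference = replisome) with leave-one-out residual RMS;
  < 3 or collinear landmarks are an error.  Foci pairing is one-to-one
  minimum-total-distance with a 1-µm gate (maximum cardinality first);
  this subsumes mutual-nearest pairing in the generic case and resolves
  its conflicts deterministically.  Distances are 2D Euclidean in the
  registered frame.

## Numerical and reproducibility choices

All randomness descends from one root seed through per-trap child
streams (`numpy` `SeedSequence.spawn`), so enlarging the experiment does
not perturb existing traps, and identical config + seed gives
byte-identical CSV output.  Degenerate inputs are defined rather than
accidental: σ = 0 freezes a track on its home; empty frames yield
all-new trajectories; empty bins are reported empty, not dropped; ties in
the birth-side classifier go to the old pole.

Default problem sizes (56 traps × 5 h for the headline run; 24 traps ×
6 h for single-locus minimum recovery) are chosen so the RMSD plateau is
estimated from > 450 trajectories and the replication dip in the 1-s
step profile is several standard errors deep, while a full run stays
under a minute on one CPU.

## Known limitations

The division rule, the locus home map, and the relocation/segregation
ramps are phenomenological; real cells show adder-like size control,
cohesion after replication, and growth-condition-dependent arm
arrangement that the generator does not attempt to capture.  Replisome
focus merging/splitting is handled only through the initiation exclusion
rule.  The terminus anomaly at fast growth (a displacement minimum at
mid-cell after replisome foci have largely disappeared) is not modeled.
Only one replication round per cycle is simulated; overlapping rounds at
fast growth would require multi-fork bookkeeping the analyses here do not
need.
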