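"""1-second displacements over the cell cycle and in space.

Links the 1-s frame doublets, bins the step lengths by cell area and by
intracellular position (bins with <= 4 steps masked), and locates the
locus displacement minimum, which should sit at the predicted
replication area A(alpha) = A_init * exp(mu * C * alpha).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import _common  # noqa: E402

import matplotlib  # noqa: E402

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from repliloc import dynamics, pairing, tracking  # noqa: E402
from repliloc.model import predicted_replication_area  # noqa: E402

cells = _common.load("cells", "cells")
obs = _common.load("observations", "observations")
landmarks = _common.load("landmarks", "landmarks")
cfg = _common.CONFIG

transform = pairing.fit_channel_transform(landmarks)
is_loc = obs["channel"] == "locus"
obs.loc[is_loc, ["x_um", "y_um"]] = transform.apply(
    obs.loc[is_loc, ["x_um", "y_um"]].to_numpy())

doublets = tracking.link_doublets(obs, cfg.tracking.doublet_gate_um)
records = dynamics.compute_displacements(doublets, cells)
records.to_csv(_common.OUTDIR / "displacements.csv", index=False)
print(f"{len(records)} linked 1-s displacements "
      f"({doublets.attrs['n_unpaired']} doublet detections unpaired)")

fig, ax = plt.subplots(figsize=(4.5, 3.2))
for channel, color in (("locus", "tab:orange"), ("replisome", "tab:gray")):
    sub = records[records["channel"] == channel]
    by_area = dynamics.displacement_by_area(sub, _common.AREA_EDGES)
    by_area.to_csv(_common.OUTDIR / f"displacement_by_area_{channel}.csv",
                   index=False)
    ax.errorbar(by_area["area_center"], by_area["mean_mag_um"],
                yerr=by_area["sem_mag_um"], color=color, label=channel)
    print(f"{channel}: mean 1-s step {sub['mag_um'].mean():.4f} um "
          f"over {len(sub)} steps")
    smap = dynamics.spatial_displacement_map(
        sub, _common.AREA_EDGES, _common.LONG_EDGES, _common.SHORT_EDGES,
        cfg.analysis.min_count_exclusive)
    np.savetxt(_common.OUTDIR / f"spatial_map_{channel}.csv",
               np.nan_to_num(smap.values, nan=-1.0).reshape(
                   smap.values.shape[0], -1), delimiter=",")

loc = records[records["channel"] == "locus"]
est = dynamics.find_displacement_minimum(
    loc, _common.AREA_EDGES, smoothing_bins=cfg.analysis.smoothing_bins,
    n_bootstrap=cfg.analysis.n_bootstrap, rng=np.random.default_rng(cfg.seed))
pred = predicted_replication_area(cfg.locus.alpha, cfg.model)
print(f"locus ({cfg.locus.name}, alpha={cfg.locus.alpha}) displacement "
      f"minimum at {est.area_um2:.3f} um^2 "
      f"[{est.ci_low:.3f}, {est.ci_high:.3f}]; model predicts {pred:.3f} um^2")
pred_line = ax.axvline(pred, color="c", ls="--", label="predicted A(alpha)")
ax.set_xlabel("cell area (um^2)")
ax.set_ylabel("mean 1-s displacement (um)")
ax.legend(fontsize=7)
fig.tight_layout()
fig.savefig(_common.OUTDIR / "displacement_by_area.png", dpi=150)
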