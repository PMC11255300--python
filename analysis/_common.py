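"""Shared setup for the numbered analysis drivers.

Every driver operates on the same default synthetic experiment (56
mother-machine traps, 5 h at 1/min imaging with 1-s doublets, replisome
confinement SDs 0.177/0.085 µm, initiation at 2.05 µm²) under
``results/run``.  Run the scripts in order: 01 simulates, 02 tracks, the
rest analyze.
"""

import dataclasses
from pathlib import Path

from repliloc import io
from repliloc.config import PipelineConfig
from repliloc.pipeline import area_bin_edges, spatial_bin_edges

OUTDIR = Path("results/run")
CONFIG = dataclasses.replace(PipelineConfig(), seed=1, outdir=str(OUTDIR))
AREA_EDGES = area_bin_edges(CONFIG)
LONG_EDGES, SHORT_EDGES = spatial_bin_edges(CONFIG)


def load(name: str, kind: str):
    path = OUTDIR / f"{name}.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run the earlier drivers first")
    return io.read_table(path, kind)
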