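"""Exponential replication-size model and genomic-coordinate helpers.

In steadily growing *E. coli*, cell area grows exponentially, A(t) =
A_birth * exp(mu*t), and chromosome replication proceeds at a constant
rate from oriC to ter over the C-period.  A locus at genomic fraction
``alpha`` (its distance from oriC divided by half the chromosome length)
is therefore replicated a time ``C*alpha`` after initiation, i.e. at the
predicted cell area

    A(alpha) = A_init * exp(mu * C * alpha)

with ``mu = ln(2)/T_d`` the growth rate for doubling time ``T_d``.  This
module houses that model and the alpha bookkeeping used everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ReplicationModelParams",
    "LocusLabel",
    "growth_rate_from_doubling",
    "locus_alpha",
    "predicted_replication_area",
    "MG1655_CHROMOSOME_KB",
    "DEFAULT_LOCI",
]

#: E. coli MG1655 chromosome length used to convert kb offsets to alpha.
MG1655_CHROMOSOME_KB = 4642.0


def growth_rate_from_doubling(doubling_time: float) -> float:
    """Growth rate mu = ln(2)/T_d (1/min) for exponential growth.

    Parameters
    ----------
    doubling_time : float
        Average doubling time T_d in minutes; must be positive.
    """
    if not doubling_time > 0:
        raise ValueError(f"doubling_time must be > 0, got {doubling_time}")
    return math.log(2.0) / doubling_time


def locus_alpha(offset_kb: float, chromosome_kb: float = MG1655_CHROMOSOME_KB) -> float:
    """Genomic fraction alpha of a locus from its shorter-arc distance to oriC.

    alpha = offset / (chromosome_length / 2), clipped to [0, 1].  The offset
    must already be the shorter-arc distance along its replichore; values
    beyond half the chromosome are rejected rather than wrapped.
    """
    if not chromosome_kb > 0:
        raise ValueError(f"chromosome_kb must be > 0, got {chromosome_kb}")
    if offset_kb < 0:
        raise ValueError(f"offset_kb must be >= 0, got {offset_kb}")
    half = chromosome_kb / 2.0
    if offset_kb > half:
        raise ValueError(
            f"offset_kb ({offset_kb}) exceeds half the chromosome ({half}); "
            "supply the shorter-arc distance"
        )
    return min(offset_kb / half, 1.0)


@dataclass(frozen=True)
class ReplicationModelParams:
    """Parameters of the replication-size model.

    Attributes
    ----------
    a_init : float
        Cell area at replication initiation (µm²).
    doubling_time : float
        Average doubling time T_d (min).
    c_period : float
        C-period, the duration of chromosome replication (min).
    """

    a_init: float = 2.05
    doubling_time: float = 50.0
    c_period: float = 45.0

    def __post_init__(self) -> None:
        if not self.a_init > 0:
            raise ValueError(f"a_init must be > 0, got {self.a_init}")
        if not self.doubling_time > 0:
            raise ValueError(f"doubling_time must be > 0, got {self.doubling_time}")
        if self.c_period < 0:
            raise ValueError(f"c_period must be >= 0, got {self.c_period}")

    @property
    def mu(self) -> float:
        """Growth rate ln(2)/T_d (1/min)."""
        return growth_rate_from_doubling(self.doubling_time)


def predicted_replication_area(alpha: float, params: ReplicationModelParams) -> float:
    """Cell area (µm²) at which a locus of genomic fraction ``alpha`` replicates.

    A(alpha) = A_init * exp(mu * C * alpha).  Monotone non-decreasing in
    alpha; A(0) equals ``params.a_init`` exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return params.a_init * math.exp(params.mu * params.c_period * alpha)


@dataclass(frozen=True)
class LocusLabel:
    """A labeled chromosomal locus: name, genomic fraction and arm."""

    name: str
    alpha: float
    arm: str = "left"  # left | right | origin | terminus

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.arm not in ("left", "right", "origin", "terminus"):
            raise ValueError(f"unknown arm {self.arm!r}")


def _default_loci() -> tuple[LocusLabel, ...]:
    # Ori label 34 kb from oriC; Ter label 47 kb from dif (dif at the
    # terminus, alpha = 1 - 47/(L/2)); arm loci evenly spaced in alpha.
    ori = LocusLabel("Ori", locus_alpha(34.0), "origin")
    ter = LocusLabel("Ter", 1.0 - locus_alpha(47.0), "terminus")
    arms = []
    for arm, prefix in (("left", "L"), ("right", "R")):
        for i, a in enumerate((0.2, 0.4, 0.6, 0.8), start=1):
            arms.append(LocusLabel(f"{prefix}{i}", a, arm))
    return (ori, *arms, ter)


#: Ori, L1-L4, R1-R4 and Ter with their default genomic fractions.
DEFAULT_LOCI: tuple[LocusLabel, ...] = _default_loci()
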