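"""Four-state classification of light-chain conformers and state populations.

Each conformer is assigned to exactly one of four states on the
(elbow angle theta, VL-CL dimer distance d) plane:

* ``L_B`` — bent (theta <= 2.5 rad), the compact low-energy basin;
* ``G``   — straight (theta > 2.5 rad) and compact (d < 3.4 nm);
* ``L_S`` — straight at intermediate separation (3.4 <= d <= 4.1 nm);
* ``H``   — straight with well-separated dimers (d > 4.1 nm), the
  conformation enriched in amyloidogenic light chains.

State populations are weighted sums of frame weights with block-averaging
errors; two independent replicate ensembles are combined by averaging with a
half-range/propagated-error maximum.  The amyloid fingerprint call compares
the H-state population band (upper error bound) against configurable
thresholds (>= 5% amyloidogenic-like, < 1% myeloma-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import CVRecord
from .reweighting import WeightVector, block_error

__all__ = ["STATES", "StatePartition", "PopulationTable", "classify_state",
           "classify_table", "state_populations", "combine_replicates",
           "fingerprint_call"]

STATES = ("L_B", "L_S", "G", "H")


@dataclass(frozen=True)
class StatePartition:
    """Thresholds of the four-state partition.

    Boundary closure: "straight" is strictly theta > theta_straight; the
    distance boundaries d_low and d_high belong to L_S (closed interval),
    matching the strict inequalities of G (d < d_low) and H (d > d_high).
    """

    theta_straight: float = 2.5   # rad
    d_low: float = 3.4            # nm
    d_high: float = 4.1           # nm

    def __post_init__(self):
        if not (0.0 < self.theta_straight < math.pi):
            raise ValueError("theta_straight must lie in (0, pi)")
        if not (0.0 < self.d_low < self.d_high):
            raise ValueError("need 0 < d_low < d_high")


@dataclass
class PopulationTable:
    """Percent population and standard error per state; percents sum to 100."""

    percent: dict[str, float]
    stderr: dict[str, float]
    partition: StatePartition = field(default_factory=StatePartition)

    def __post_init__(self):
        for s in STATES:
            if s not in self.percent or s not in self.stderr:
                raise ValueError(f"missing state {s}")
            if self.stderr[s] < 0:
                raise ValueError("negative stderr")
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percents sum to {total}, expected 100")

    def as_rows(self) -> list[dict]:
        return [{"state": s, "percent": self.percent[s],
                 "stderr": self.stderr[s]} for s in STATES]


def classify_state(theta: float, d_vc: float,
                   partition: StatePartition | None = None) -> str:
    """Assign one conformer to L_B, L_S, G or H from (theta, d_vc)."""
    p = partition or StatePartition()
    if not (np.isfinite(theta) and np.isfinite(d_vc)):
        raise ValueError("non-finite collective variables")
    if theta <= p.theta_straight:
        return "L_B"
    if d_vc < p.d_low:
        return "G"
    if d_vc > p.d_high:
        return "H"
    return "L_S"


def classify_table(cv_table: list[CVRecord],
                   partition: StatePartition | None = None) -> list[str]:
    """Vectorized per-frame state labels in frame order."""
    p = partition or StatePartition()
    theta = np.array([r.theta for r in cv_table])
    d = np.array([r.d_vc for r in cv_table])
    labels = np.where(theta <= p.theta_straight, "L_B",
                      np.where(d < p.d_low, "G",
                               np.where(d > p.d_high, "H", "L_S")))
    return list(labels)


def state_populations(cv_table: list[CVRecord],
                      partition: StatePartition | None = None,
                      n_blocks: int = 5) -> PopulationTable:
    """Weighted state populations (percent) with block-averaging errors."""
    p = partition or StatePartition()
    if not cv_table:
        raise ValueError("empty CV table")
    labels = np.array(classify_table(cv_table, p))
    w = np.array([r.weight for r in cv_table])
    s = w.sum()
    if s <= 0:
        raise ValueError("total frame weight is zero")
    w = w / s
    percent: dict[str, float] = {}
    stderr: dict[str, float] = {}
    for state in STATES:
        ind = (labels == state).astype(float)
        est, se = block_error(ind, w, n_blocks=n_blocks)
        percent[state] = 100.0 * est
        stderr[state] = 100.0 * se
    # block means are exact partitions of the same weighted sum, but guard
    # against floating-point drift so the invariant holds to 1e-6
    total = sum(percent.values())
    percent = {s_: v * (100.0 / total) for s_, v in percent.items()}
    return PopulationTable(percent, stderr, p)


def combine_replicates(pop_a: PopulationTable,
                       pop_b: PopulationTable) -> PopulationTable:
    """Average two replicate population tables.

    Per state the percent is the mean of the two replicates and the error is
    the larger of (half the absolute difference) and the propagated
    block-averaging error — replicate spread dominates when the two
    independent runs disagree beyond their internal errors.
    """
    if pop_a.partition != pop_b.partition:
        raise ValueError("population tables use different partitions")
    percent: dict[str, float] = {}
    stderr: dict[str, float] = {}
    for s in STATES:
        a, b = pop_a.percent[s], pop_b.percent[s]
        percent[s] = 0.5 * (a + b)
        half_range = 0.5 * abs(a - b)
        propagated = 0.5 * math.hypot(pop_a.stderr[s], pop_b.stderr[s])
        stderr[s] = max(half_range, propagated)
    return PopulationTable(percent, stderr, pop_a.partition)


def fingerprint_call(populations: PopulationTable,
                     al_threshold_percent: float = 5.0,
                     mm_threshold_percent: float = 1.0) -> str:
    """Call an ensemble AL-like, MM-like or indeterminate from its H state.

    The comparison uses the upper error bound H + stderr, so a population
    statistically compatible with the amyloidogenic band (e.g. 4.8 +/- 0.5)
    is still called AL-like, while only ensembles whose whole error band sits
    below the myeloma threshold are called MM-like.
    """
    h = populations.percent["H"]
    se = populations.stderr["H"]
    upper = h + se
    if upper >= al_threshold_percent:
        return "AL-like"
    if upper < mm_threshold_percent:
        return "MM-like"
    return "indeterminate"
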