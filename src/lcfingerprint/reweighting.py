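"""Final-bias reweighting and error estimation for weighted ensembles.

Enhanced-sampling simulations (well-tempered metadynamics) deposit a bias
potential V_i for every stored frame.  Unbiased expectation values are
recovered by giving each frame the weight w_i proportional to exp(+V_i / k_B T)
(last-bias estimator).  Statistical errors of any weighted average are
estimated by contiguous block averaging, which respects the serial
autocorrelation of trajectory frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import KB_KJMOL

__all__ = ["WeightVector", "bias_to_weights", "effective_sample_size",
           "block_error"]


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-frame probabilities with a provenance tag."""

    values: np.ndarray
    source: str = "explicit"  # uniform | bias | explicit

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("weights must be finite and non-negative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {v.sum()!r}, expected 1")

    def __len__(self) -> int:
        return len(self.values)


def bias_to_weights(bias_kJmol, temperature_K: float,
                    sign: float = +1.0) -> WeightVector:
    """Convert final metadynamics bias values to normalized frame weights.

    w_i is proportional to exp(sign * V_i / (k_B T)); the maximum bias is
    subtracted before exponentiation for overflow safety, which leaves the
    normalized weights unchanged.  ``sign=+1`` is the standard last-bias
    convention (high bias marks an oversuppressed, hence up-weighted, frame);
    it is exposed for sensitivity checks.
    """
    bias = np.asarray(bias_kJmol, dtype=float)
    if not np.all(np.isfinite(bias)):
        raise ValueError("non-finite bias value")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    x = sign * bias / (KB_KJMOL * temperature_K)
    x = x - x.max()
    w = np.exp(x)
    return WeightVector(w / w.sum(), source="bias")


def effective_sample_size(weights) -> float:
    """Kish effective sample size 1 / sum(w_i^2) of a weight vector.

    Equals n for uniform weights and approaches 1 as the weight mass
    concentrates on a single frame.
    """
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, float)
    return float(1.0 / np.sum(w ** 2))


def block_error(indicator, weights, n_blocks: int = 5) -> tuple[float, float]:
    """Weighted mean and block-averaging standard error of a per-frame series.

    The series is split into ``n_blocks`` contiguous blocks (frame order, to
    respect autocorrelation).  Each block mean uses block-local weight
    renormalization; the estimate is the block-weight-weighted mean of block
    means and the error is the weighted standard error over blocks.

    Returns ``(estimate, stderr)``.
    """
    x = np.asarray(indicator, dtype=float)
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if len(x) != len(w):
        raise ValueError("indicator and weights differ in length")
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(x) < n_blocks:
        raise ValueError(f"{len(x)} frames cannot fill {n_blocks} blocks")
    xs = np.array_split(x, n_blocks)
    ws = np.array_split(w, n_blocks)
    bw = np.array([wb.sum() for wb in ws])
    if bw.sum() <= 0:
        raise ValueError("total weight is zero")
    # blocks with zero weight contribute nothing to the estimate or error
    occupied = bw > 0
    means = np.array([
        float(np.dot(xb, wb) / wb.sum()) if wb.sum() > 0 else 0.0
        for xb, wb in zip(xs, ws)
    ])
    p = bw / bw.sum()
    estimate = float(np.dot(p, means))
    n_occ = int(occupied.sum())
    if n_occ < 2:
        return estimate, float("nan")
    var_between = float(np.dot(p, (means - estimate) ** 2))
    stderr = float(np.sqrt(var_between / (n_occ - 1)))
    return estimate, stderr
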