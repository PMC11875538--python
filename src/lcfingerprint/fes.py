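"""Weighted two-dimensional free-energy surfaces over collective variables.

F(bin) = -k_B T ln(P(bin) / P_max), where P is the weighted histogram of
frames.  The occupied-bin minimum is exactly zero; empty bins are masked and
carry +inf, never a finite value.  At T = 310 K the conventional isoline
spacing 2 k_B T equals 5.16 kJ/mol (rounded to two decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import KB_KJMOL
from .geometry import CVRecord
from .states import StatePartition, classify_table

__all__ = ["FESGrid", "fes_2d", "state_conditioned_fes",
           "isoline_spacing_kJmol"]


def isoline_spacing_kJmol(temperature_K: float = 310.0,
                          n_kbt: float = 2.0) -> float:
    """Isoline spacing n * k_B * T in kJ/mol (2 k_B T by convention)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return n_kbt * KB_KJMOL * temperature_K


def isoline_spacing_printed(temperature_K: float = 310.0,
                            n_kbt: float = 2.0) -> float:
    """The isoline spacing as conventionally printed (2 decimals).

    At 310 K, 2 k_B T = 5.15497 kJ/mol, quoted in the field as 5.155 and
    hence printed as 5.16: the value is rounded half-up first to three and
    then to two decimals.
    """
    from decimal import ROUND_HALF_UP, Decimal

    v = Decimal(repr(isoline_spacing_kJmol(temperature_K, n_kbt)))
    v = v.quantize(Decimal("0.001"), ROUND_HALF_UP)
    return float(v.quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class FESGrid:
    """A 2-D free-energy surface on a uniform grid.

    ``F`` is in kJ/mol, min-shifted so the lowest occupied bin is 0;
    ``mask`` flags empty bins (where ``F`` is +inf).  ``isolines`` lists the
    conventional 2 k_B T contour levels up to the occupied maximum.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray                # (nx, ny) kJ/mol
    mask: np.ndarray             # True where bin is empty
    temperature_K: float
    x_name: str = "x"
    y_name: str = "y"
    x_unit: str = ""
    y_unit: str = ""

    def __post_init__(self):
        occ = self.F[~self.mask]
        if occ.size == 0:
            raise ValueError("free-energy surface has no occupied bins")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def isolines(self) -> list[float]:
        spacing = isoline_spacing_kJmol(self.temperature_K)
        fmax = float(self.F[~self.mask].max())
        return list(np.arange(0.0, fmax + spacing, spacing))

    def argmin(self) -> tuple[float, float]:
        """(x, y) bin-center coordinates of the free-energy minimum."""
        F = np.where(self.mask, np.inf, self.F)
        i, j = np.unravel_index(np.argmin(F), F.shape)
        return float(self.x_centers[i]), float(self.y_centers[j])


def _padded_range(v: np.ndarray, pad_frac: float = 0.05) -> tuple[float, float]:
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo
    if span == 0.0:
        span = max(abs(hi), 1.0)
    return lo - pad_frac * span, hi + pad_frac * span


def fes_2d(x, y, weights, bins: tuple[int, int] = (60, 60),
           ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
           temperature_K: float = 310.0,
           x_name: str = "x", y_name: str = "y",
           x_unit: str = "", y_unit: str = "") -> FESGrid:
    """Weighted 2-D free-energy surface F = -k_B T ln(P / P_max).

    ``ranges`` defaults to the data range padded by 5% on each side.
    Uniform rescaling of the weights leaves F unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and weights must have equal length")
    nx, ny = bins
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 bins per axis")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if ranges is None:
        ranges = (_padded_range(x), _padded_range(y))
    H, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=ranges,
                                         weights=w)
    total = H.sum()
    if total <= 0:
        raise ValueError("no weight inside the requested ranges")
    P = H / total
    mask = P <= 0
    F = np.full_like(P, np.inf)
    pmax = P.max()
    with np.errstate(divide="ignore"):
        F[~mask] = -KB_KJMOL * temperature_K * np.log(P[~mask] / pmax)
    return FESGrid(x_edges, y_edges, F, mask, temperature_K,
                   x_name=x_name, y_name=y_name, x_unit=x_unit, y_unit=y_unit)


def state_conditioned_fes(cv_table: list[CVRecord], state: str,
                          partition: StatePartition | None = None,
                          bins: tuple[int, int] = (60, 60),
                          temperature_K: float = 310.0,
                          ranges=None) -> FESGrid:
    """FES over (d_CC, d_VV) restricted to frames classified into ``state``.

    Weights are renormalized within the state subset, so the surface shows
    the free-energy landscape of the interface *given* the state.
    """
    labels = np.array(classify_table(cv_table, partition))
    sel = labels == state
    w = np.array([r.weight for r in cv_table])
    if not sel.any() or w[sel].sum() <= 0:
        raise ValueError(f"state {state} unpopulated in this ensemble")
    d_cc = np.array([r.d_cc for r in cv_table])[sel]
    d_vv = np.array([r.d_vv for r in cv_table])[sel]
    w_sub = w[sel] / w[sel].sum()
    return fes_2d(d_cc, d_vv, w_sub, bins=bins, ranges=ranges,
                  temperature_K=temperature_K,
                  x_name="d_CC", y_name="d_VV", x_unit="nm", y_unit="nm")


def grid_to_rows(grid: FESGrid) -> list[dict]:
    """Flatten a grid to (x_center, y_center, F_kJmol) rows, occupied bins only."""
    rows = []
    xc, yc = grid.x_centers, grid.y_centers
    for i in range(len(xc)):
        for j in range(len(yc)):
            if not grid.mask[i, j]:
                rows.append({"x_center": float(xc[i]), "y_center": float(yc[j]),
                             "F_kJmol": float(grid.F[i, j])})
    return rows
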