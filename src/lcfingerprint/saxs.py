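"""SAXS back-calculation, ensemble averaging, chi-square fitting and Guinier R_g.

Scattering intensities are back-calculated from coordinates with the Debye
equation over coarse scattering centers — by default one center per residue
at the residue center of mass, carrying an effective scattering weight equal
to the residue electron count.  This reproduces the global-shape observables
(R_g, low-q intensity) that drive ensemble/experiment comparison; it does not
model the hydration shell, so absolute chi-square values are systematically
different from hydration-aware predictors such as crysol.

The ensemble-averaged curve is the weight-average of per-frame curves.
Agreement with experiment is quantified after a closed-form weighted
least-squares fit of a scale factor (and optionally a flat background), and
the radius of gyration is estimated from the Guinier law
ln I(q) = ln I(0) - q^2 R_g^2 / 3 by an iterative low-q fit that enforces
q_max * R_g below a configurable limit (default 1.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .ensemble_io import ConformerFrame, SAXSCurve, WeightedEnsemble

__all__ = ["GuinierResult", "SAXSFitResult", "debye_intensity",
           "ensemble_intensity", "fit_scale_and_chi2", "guinier_rg", "kratky"]

# electrons per peptide-bonded residue (free amino acid minus one water)
RESIDUE_ELECTRONS = {
    "ALA": 38, "ARG": 84, "ASN": 60, "ASP": 60, "CYS": 54, "GLN": 68,
    "GLU": 68, "GLY": 30, "HIS": 72, "ILE": 62, "LEU": 62, "LYS": 70,
    "MET": 70, "PHE": 78, "PRO": 52, "SER": 46, "THR": 54, "TRP": 98,
    "TYR": 86, "VAL": 54,
}

_ATOMIC_NUMBERS = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "CL": 17, "K": 19, "CA": 20, "FE": 26, "ZN": 30, "SE": 34,
    "NA": 11, "MG": 12,
}


@dataclass
class GuinierResult:
    """Radius of gyration from the Guinier approximation."""

    rg: float              # nm
    i0: float              # intensity units
    q_range: tuple[float, float]   # A^-1
    n_points: int
    r_squared: float
    qmax_rg: float         # dimensionless q_max * R_g of the final fit
    rg_stderr: float = float("nan")  # nm, from the fit covariance


@dataclass
class SAXSFitResult:
    """Scale/background fit of a calculated against an experimental curve."""

    scale: float
    background: float
    chi2: float            # reduced chi-square
    residuals: np.ndarray  # (I_exp - (c * I_calc + b)) / sigma
    q: np.ndarray          # grid the residuals live on (A^-1)

    def __post_init__(self):
        if self.chi2 < 0:
            raise ValueError("negative chi-square")
        if not np.all(np.isfinite(self.residuals)):
            raise ValueError("non-finite residuals")


def _scattering_centers(frame: ConformerFrame,
                        representation: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions (Angstrom) and effective scattering weights f."""
    coords_A = frame.coords * 10.0
    if representation == "atomic":
        f = np.array([
            _ATOMIC_NUMBERS.get(e.strip().upper(), 6)
            for e in frame.atoms["element"]
        ], dtype=float)
        return coords_A, f
    if representation != "residue_cg":
        raise ValueError(f"unknown representation {representation!r}")
    atoms = frame.atoms
    key = list(zip(atoms["chain_id"], atoms["res_id"]))
    centers, weights = [], []
    seen: dict[tuple, int] = {}
    masses = atoms["mass"].to_numpy()
    for i, k in enumerate(key):
        seen.setdefault(k, len(seen))
    groups: list[list[int]] = [[] for _ in range(len(seen))]
    for i, k in enumerate(key):
        groups[seen[k]].append(i)
    for idx in groups:
        idx = np.asarray(idx)
        m = masses[idx]
        centers.append((m[:, None] * coords_A[idx]).sum(axis=0) / m.sum())
        res_name = atoms["res_name"].iloc[idx[0]]
        f_res = RESIDUE_ELECTRONS.get(res_name)
        if f_res is None:
            f_res = sum(_ATOMIC_NUMBERS.get(e.strip().upper(), 6)
                        for e in atoms["element"].iloc[idx])
        weights.append(float(f_res))
    return np.asarray(centers), np.asarray(weights)


def debye_intensity(frame: ConformerFrame, q_grid,
                    representation: str = "residue_cg") -> SAXSCurve:
    """Orientationally averaged scattering of one rigid conformer (Debye sum).

    I(q) = sum_jk f_j f_k sin(q d_jk)/(q d_jk) over scattering centers;
    I(0) = (sum f)^2 exactly.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative q")
    if frame.n_atoms == 0:
        raise ValueError("empty frame")
    pos, f = _scattering_centers(frame, representation)
    n = len(pos)
    I_self = float(np.sum(f ** 2))
    if n == 1:
        return SAXSCurve(q, np.full_like(q, I_self))
    d = pdist(pos)                       # Angstrom, unique pairs
    iu = np.triu_indices(n, k=1)
    ff = f[iu[0]] * f[iu[1]]
    # sinc(q*d) in the mathematical sense sin(x)/x
    x = np.outer(q, d)
    cross = 2.0 * (np.sinc(x / np.pi) @ ff)
    return SAXSCurve(q, I_self + cross)


def ensemble_intensity(ensemble: WeightedEnsemble, q_grid,
                       representation: str = "residue_cg") -> SAXSCurve:
    """Weight-averaged Debye intensity over all frames of an ensemble."""
    q = np.asarray(q_grid, dtype=float)
    I = np.zeros_like(q)
    for i in range(ensemble.n_frames):
        w = ensemble.weights[i]
        if w == 0.0:
            continue
        I += w * debye_intensity(ensemble.frame(i), q, representation).I
    return SAXSCurve(q, I)


def fit_scale_and_chi2(calc: SAXSCurve, exp: SAXSCurve,
                       q_max: float | None = None,
                       fit_background: bool = False) -> SAXSFitResult:
    """Fit scale (and optional flat background) and compute reduced chi-square.

    The calculated curve is linearly interpolated onto the experimental q
    grid (never extrapolated); points beyond ``q_max`` or outside the
    calculated range are dropped.  chi2 is the weighted sum of squared
    residuals divided by (N - n_params).
    """
    if not exp.has_sigma:
        raise ValueError("experimental curve lacks uncertainties")
    keep = (exp.q >= calc.q[0]) & (exp.q <= calc.q[-1])
    if q_max is not None:
        keep &= exp.q <= q_max
    q = exp.q[keep]
    I_exp = exp.I[keep]
    sigma = exp.sigma[keep]
    if np.all(sigma == 0):
        raise ValueError("all-zero sigma")
    I_calc = np.interp(q, calc.q, calc.I)
    n_params = 2 if fit_background else 1
    if len(q) - n_params <= 0:
        raise ValueError(
            f"{len(q)} points cannot constrain {n_params} fit parameters"
        )
    if fit_background:
        A = np.column_stack([I_calc, np.ones_like(I_calc)]) / sigma[:, None]
    else:
        A = (I_calc / sigma)[:, None]
    b_vec = I_exp / sigma
    theta, *_ = np.linalg.lstsq(A, b_vec, rcond=None)
    c = float(theta[0])
    b = float(theta[1]) if fit_background else 0.0
    residuals = (I_exp - (c * I_calc + b)) / sigma
    chi2 = float(np.sum(residuals ** 2) / (len(q) - n_params))
    return SAXSFitResult(c, b, chi2, residuals, q)


def guinier_rg(curve: SAXSCurve, qrg_limit: float = 1.3,
               max_iter: int = 20) -> GuinierResult:
    """Radius of gyration (nm) from an iterative low-q Guinier fit.

    A weighted linear fit of ln I against q^2 starts from the lowest
    ceil(n/10)+5 points; the window is then shrunk until
    q_max * R_g <= qrg_limit at the fitted R_g (fixed point, at most
    ``max_iter`` rounds, never fewer than 5 points).  The limit is a
    validity ceiling, not a target: the window is deliberately not extended
    up to it, because filling the window to the ceiling biases R_g upward
    on globular shapes (the Guinier law is an expansion around q = 0).
    """
    usable = curve.I > 0
    q = curve.q[usable]
    I = curve.I[usable]
    sigma = curve.sigma[usable] if curve.has_sigma else None
    if len(q) < 5:
        raise ValueError("fewer than 5 usable points for a Guinier fit")

    x = q ** 2
    y = np.log(I)
    if sigma is not None:
        w = (I / sigma) ** 2     # var(ln I) = (sigma/I)^2
    else:
        w = np.ones_like(x)

    def _fit(n_pts: int):
        xw, yw, ww = x[:n_pts], y[:n_pts], w[:n_pts]
        (slope, intercept), cov = np.polyfit(xw, yw, 1, w=np.sqrt(ww),
                                             cov="unscaled")
        yhat = slope * xw + intercept
        ss_res = float(np.sum(ww * (yw - yhat) ** 2))
        ybar = float(np.average(yw, weights=ww))
        ss_tot = float(np.sum(ww * (yw - ybar) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, intercept, cov, r2

    n_pts = min(len(q), int(np.ceil(len(q) / 10)) + 5)
    for _ in range(max_iter):
        slope, intercept, cov, r2 = _fit(n_pts)
        if slope >= 0:
            raise ValueError("no Guinier regime: non-negative low-q slope")
        rg_A = np.sqrt(-3.0 * slope)
        n_new = int(np.searchsorted(q, qrg_limit / rg_A, side="right"))
        n_new = max(5, min(n_new, n_pts))  # shrink-only: never chase the ceiling
        if n_new == n_pts:
            break
        n_pts = n_new
    slope, intercept, cov, r2 = _fit(n_pts)
    if slope >= 0:
        raise ValueError("no Guinier regime: non-negative low-q slope")
    rg_A = float(np.sqrt(-3.0 * slope))
    # d(Rg)/d(slope) = -3 / (2 Rg)
    rg_se_A = float(np.sqrt(cov[0, 0]) * 3.0 / (2.0 * rg_A))
    return GuinierResult(
        rg=rg_A / 10.0,
        i0=float(np.exp(intercept)),
        q_range=(float(q[0]), float(q[n_pts - 1])),
        n_points=n_pts,
        r_squared=r2,
        qmax_rg=float(q[n_pts - 1] * rg_A),
        rg_stderr=rg_se_A / 10.0,
    )


def kratky(curve: SAXSCurve) -> SAXSCurve:
    """Kratky transform (q, q^2 I(q)); uncertainties propagate as q^2 sigma."""
    sigma = curve.q ** 2 * curve.sigma if curve.has_sigma else None
    return SAXSCurve(curve.q, curve.q ** 2 * curve.I, sigma)
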