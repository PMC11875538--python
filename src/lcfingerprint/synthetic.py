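"""Synthetic weighted dimer ensembles with known state populations.

The generator emulates the statistical structure of a reweighted
metainference ensemble of a light-chain homodimer: four rigid bead clouds
(VL and CL of chains A and B) plus two linker clouds are placed so that the
elbow angle, the VL/CL dimer distance and the CL-CL / VL-VL interface
distances take prescribed values, state by state.  States are sampled
i.i.d. with prescribed populations; per-state collective variables follow
truncated Gaussians that honor the classification bounds, so the ground
truth labels are exact by construction.

Geometric construction (exact before bead jitter): the hinge (combined
linker center of mass) sits at the origin; the VL-dimer and CL-dimer
centers of mass lie in the xy-plane at equal arm length
r = d_vc / (2 sin(theta/2)) along directions separated by the elbow angle
theta; the two domains of each dimer are split along z by d_vv or d_cc,
which leaves the dimer centers of mass and hence (theta, d_vc) unchanged.

Analytic SAXS fixtures (homogeneous-sphere form factor, noisy curves) are
provided as oracles for the Guinier and chi-square machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ensemble_io import DomainArchitecture, SAXSCurve, WeightedEnsemble
from .geometry import CVRecord
from .reweighting import bias_to_weights
from .states import STATES, StatePartition

__all__ = ["StateGeometry", "SyntheticSpec", "generate_dimer_ensemble",
           "sphere_intensity", "make_noisy_curve", "uniform_ball"]


@dataclass(frozen=True)
class StateGeometry:
    """Mean and spread of the collective variables within one state."""

    theta_mean: float      # rad
    theta_sigma: float
    d_vc_mean: float       # nm
    d_vc_sigma: float
    d_cc_mean: float       # nm
    d_cc_sigma: float
    d_vv_mean: float       # nm
    d_vv_sigma: float


# Defaults sit inside each state's region of the default partition; the
# H state's CL-CL distance is shifted +0.4 nm outward, reflecting the looser
# constant-domain interface of the extended conformation.
_DEFAULT_GEOMETRY = {
    "L_B": StateGeometry(2.1, 0.15, 3.1, 0.12, 2.1, 0.10, 1.8, 0.10),
    "L_S": StateGeometry(2.8, 0.12, 3.7, 0.12, 2.1, 0.10, 1.8, 0.10),
    "G":   StateGeometry(2.8, 0.12, 3.1, 0.10, 2.1, 0.10, 1.8, 0.10),
    "H":   StateGeometry(2.8, 0.12, 4.4, 0.12, 2.5, 0.10, 1.8, 0.10),
}


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic weighted dimer ensemble.

    ``target_populations`` are percents per state (L_B, L_S, G, H) summing
    to 100.  ``jitter_sigma`` is the per-bead Gaussian displacement in nm
    applied after the exact geometric construction.  The weight model is
    either ``uniform`` or ``bias_gaussian`` (per-frame bias drawn from
    N(0, bias_sigma_kJmol), converted to Boltzmann weights).
    """

    n_frames: int
    seed: int
    target_populations: dict[str, float] = field(
        default_factory=lambda: {"L_B": 62.0, "L_S": 33.0, "G": 0.2, "H": 4.8})
    geometry: dict[str, StateGeometry] = field(
        default_factory=lambda: dict(_DEFAULT_GEOMETRY))
    partition: StatePartition = field(default_factory=StatePartition)
    beads_per_domain: int = 50
    beads_per_linker: int = 11
    domain_radius: float = 1.0      # nm
    linker_radius: float = 0.3      # nm
    jitter_sigma: float = 0.05      # nm
    weight_model: str = "uniform"   # uniform | bias_gaussian
    bias_sigma_kJmol: float = 2.0
    temperature_K: float = 310.0
    architecture: DomainArchitecture = field(
        default_factory=DomainArchitecture.default)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        pops = self.target_populations
        if set(pops) != set(STATES) or any(p < 0 for p in pops.values()):
            raise ValueError("populations must cover L_B, L_S, G, H and be >= 0")
        if abs(sum(pops.values()) - 100.0) > 1e-6:
            raise ValueError("populations must sum to 100")
        if self.weight_model not in ("uniform", "bias_gaussian"):
            raise ValueError(f"unknown weight model {self.weight_model!r}")
        p = self.partition
        bounds = self._state_bounds()
        for s, g in self.geometry.items():
            (tlo, thi), (dlo, dhi) = bounds[s]
            if not (tlo < g.theta_mean < thi) or not (dlo < g.d_vc_mean < dhi):
                raise ValueError(
                    f"geometry mean of state {s} lies outside its region"
                )
            if min(g.d_cc_mean, g.d_vv_mean) <= 0:
                raise ValueError("interface distances must be positive")

    def _state_bounds(self):
        """(theta, d_vc) truncation bounds per state under the partition."""
        p = self.partition
        eps = 1e-9
        return {
            "L_B": ((0.2, p.theta_straight), (0.5, 8.0)),
            "G":   ((p.theta_straight + eps, np.pi), (0.5, p.d_low - eps)),
            "L_S": ((p.theta_straight + eps, np.pi), (p.d_low, p.d_high)),
            "H":   ((p.theta_straight + eps, np.pi), (p.d_high + eps, 8.0)),
        }


def uniform_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points uniformly distributed in a ball, recentered to exact zero mean."""
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return pts - pts.mean(axis=0)


def _truncated_normal(mean, sigma, lo, hi, size, rng) -> np.ndarray:
    a, b = (lo - mean) / sigma, (hi - mean) / sigma
    return truncnorm.rvs(a, b, loc=mean, scale=sigma, size=size,
                         random_state=rng)


def _atom_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Bead atom table plus index masks per group (VL_A, CL_A, LK_A, ...)."""
    arch = spec.architecture
    rows = []
    groups: dict[str, list[int]] = {}
    for chain in arch.chain_ids:
        for dom, nb in (("VL", spec.beads_per_domain),
                        ("LINKER", spec.beads_per_linker),
                        ("CL", spec.beads_per_domain)):
            lo, hi = arch.domain_range(dom, chain)
            if nb > hi - lo + 1:
                raise ValueError(
                    f"{nb} beads do not fit in the {dom} range {lo}-{hi}"
                )
            tag = {"VL": "VL", "CL": "CL", "LINKER": "LK"}[dom] + f"_{chain}"
            groups[tag] = []
            for i in range(nb):
                groups[tag].append(len(rows))
                rows.append({"chain_id": chain, "res_id": lo + i,
                             "res_name": "GLY", "atom_name": "CA",
                             "element": "C", "mass": 12.011})
    atoms = pd.DataFrame(rows)
    return atoms, {k: np.asarray(v) for k, v in groups.items()}


def generate_dimer_ensemble(spec: SyntheticSpec) -> tuple[
        WeightedEnsemble, list[str], list[CVRecord]]:
    """Generate a weighted ensemble plus ground-truth labels and CV records.

    Returns ``(ensemble, truth_labels, truth_cvs)``.  Truth CV records hold
    the target values used in the exact construction (before bead jitter).
    Deterministic for a fixed spec (single RNG stream seeded by ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    arch = spec.architecture
    a_id, b_id = arch.chain_ids
    atoms, groups = _atom_table(spec)
    n = spec.n_frames

    # one rigid template cloud per group, shared by all frames
    templates = {
        tag: uniform_ball(len(idx),
                          spec.linker_radius if tag.startswith("LK")
                          else spec.domain_radius, rng)
        for tag, idx in groups.items()
    }

    probs = np.array([spec.target_populations[s] for s in STATES]) / 100.0
    state_idx = rng.choice(len(STATES), size=n, p=probs)
    labels = [STATES[i] for i in state_idx]

    theta = np.empty(n)
    d_vc = np.empty(n)
    d_cc = np.empty(n)
    d_vv = np.empty(n)
    bounds = spec._state_bounds()
    for k, s in enumerate(STATES):
        sel = state_idx == k
        m = int(sel.sum())
        if m == 0:
            continue
        g = spec.geometry[s]
        (tlo, thi), (dlo, dhi) = bounds[s]
        theta[sel] = _truncated_normal(g.theta_mean, g.theta_sigma,
                                       tlo, thi, m, rng)
        d_vc[sel] = _truncated_normal(g.d_vc_mean, g.d_vc_sigma,
                                      dlo, dhi, m, rng)
        d_cc[sel] = _truncated_normal(g.d_cc_mean, g.d_cc_sigma,
                                      1e-3, np.inf, m, rng)
        d_vv[sel] = _truncated_normal(g.d_vv_mean, g.d_vv_sigma,
                                      1e-3, np.inf, m, rng)

    # exact placement: hinge at origin, dimer arms in the xy-plane
    half = theta / 2.0
    if np.any(np.sin(half) < 1e-6):
        raise ValueError("degenerate elbow angle requested")
    r_arm = d_vc / (2.0 * np.sin(half))
    u = np.stack([np.cos(half), np.sin(half), np.zeros(n)], axis=1)
    v = np.stack([np.cos(half), -np.sin(half), np.zeros(n)], axis=1)
    com_v = r_arm[:, None] * u
    com_c = r_arm[:, None] * v
    z = np.array([0.0, 0.0, 1.0])
    centers = {
        f"VL_{a_id}": com_v + 0.5 * d_vv[:, None] * z,
        f"VL_{b_id}": com_v - 0.5 * d_vv[:, None] * z,
        f"CL_{a_id}": com_c + 0.5 * d_cc[:, None] * z,
        f"CL_{b_id}": com_c - 0.5 * d_cc[:, None] * z,
        f"LK_{a_id}": np.tile(0.25 * z, (n, 1)),
        f"LK_{b_id}": np.tile(-0.25 * z, (n, 1)),
    }

    coords = np.empty((n, len(atoms), 3))
    for tag, idx in groups.items():
        coords[:, idx, :] = templates[tag][None, :, :] + centers[tag][:, None, :]
    if spec.jitter_sigma > 0:
        coords += rng.normal(scale=spec.jitter_sigma, size=coords.shape)

    if spec.weight_model == "uniform":
        weights = np.full(n, 1.0 / n)
    else:
        bias = rng.normal(scale=spec.bias_sigma_kJmol, size=n)
        weights = bias_to_weights(bias, spec.temperature_K).values

    ensemble = WeightedEnsemble(atoms, coords, weights,
                                replicate_id=f"synthetic-seed{spec.seed}",
                                temperature_K=spec.temperature_K)
    truth_cvs = [CVRecord(i, float(theta[i]), float(d_vc[i]),
                          float(d_cc[i]), float(d_vv[i]), float(weights[i]))
                 for i in range(n)]
    return ensemble, labels, truth_cvs


# ---------------------------------------------------------------------------
# analytic SAXS fixtures


def sphere_intensity(radius_nm: float, q_grid, i0: float = 1.0) -> SAXSCurve:
    """Form factor of a homogeneous sphere: I = I0 [3 (sin x - x cos x)/x^3]^2.

    ``x = q R`` with q in inverse Angstrom; the q -> 0 limit is I0 exactly.
    The Guinier radius of this curve is sqrt(3/5) * R.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = q * radius_nm * 10.0
    amp = np.empty_like(x)
    small = np.abs(x) < 1e-4
    amp[small] = 1.0 - x[small] ** 2 / 10.0
    xs = x[~small]
    amp[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return SAXSCurve(q, i0 * amp ** 2)


def make_noisy_curve(curve: SAXSCurve, rel_sigma: float,
                     seed: int) -> SAXSCurve:
    """Add Gaussian noise with sigma(q) = rel_sigma * |I(q)|; records sigma."""
    if rel_sigma <= 0:
        raise ValueError("rel_sigma must be positive")
    rng = np.random.default_rng(seed)
    sigma = rel_sigma * np.abs(curve.I)
    noisy = curve.I + rng.normal(scale=sigma)
    return SAXSCurve(curve.q, noisy, sigma)
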