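"""Collective variables of the light-chain dimer: elbow angle and COM distances.

The global conformation of a VL/CL homodimer is summarised by four
collective variables per frame:

* theta — the elbow angle: the angle at the hinge (center of mass of the
  linker residues of both chains) between the vectors pointing to the
  VL-dimer and CL-dimer centers of mass.  A "straight" molecule has theta
  close to pi.
* d_vc — distance between the VL-dimer and CL-dimer centers of mass (nm).
* d_cc — distance between the two CL-domain centers of mass (nm).
* d_vv — distance between the two VL-domain centers of mass (nm).

Centers of mass are mass-weighted over all atoms of a selection by default;
a ``ca_only`` switch restricts them to C-alpha atoms for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_io import (ConformerFrame, DomainArchitecture, WeightedEnsemble)

__all__ = ["CVRecord", "center_of_mass", "elbow_angle",
           "interdomain_distances", "compute_cv_table"]

_DEGENERATE_ARM = 1e-6  # nm


@dataclass(frozen=True)
class CVRecord:
    """Per-frame collective variables with the frame's statistical weight."""

    frame_index: int
    theta: float   # rad
    d_vc: float    # nm
    d_cc: float    # nm
    d_vv: float    # nm
    weight: float

    def __post_init__(self):
        if not (0.0 <= self.theta <= np.pi + 1e-12):
            raise ValueError(f"elbow angle {self.theta} outside [0, pi]")
        for name in ("d_vc", "d_cc", "d_vv"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and non-negative")


def center_of_mass(frame: ConformerFrame, selection: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position (nm) of the selected atoms."""
    sel = np.asarray(selection)
    if sel.dtype == bool:
        idx = np.flatnonzero(sel)
    else:
        idx = sel
    if len(idx) == 0:
        raise ValueError("empty selection for center of mass")
    m = frame.atoms["mass"].to_numpy()[idx]
    x = frame.coords[idx]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def _domain_masks(atoms: pd.DataFrame, architecture: DomainArchitecture,
                  ca_only: bool = False) -> dict[str, np.ndarray]:
    """Atom masks for VL/CL per chain and for both linkers combined."""
    chain = atoms["chain_id"].to_numpy()
    rid = atoms["res_id"].to_numpy()
    base = np.ones(len(atoms), dtype=bool)
    if ca_only:
        base = atoms["atom_name"].to_numpy() == "CA"
    masks: dict[str, np.ndarray] = {}
    for dom in ("VL", "CL"):
        for c in architecture.chain_ids:
            lo, hi = architecture.domain_range(dom, c)
            m = base & (chain == c) & (rid >= lo) & (rid <= hi)
            if not m.any():
                raise ValueError(f"no atoms for {dom} of chain {c}")
            masks[f"{dom}_{c}"] = m
    link = np.zeros(len(atoms), dtype=bool)
    for c in architecture.chain_ids:
        lo, hi = architecture.domain_range("LINKER", c)
        link |= base & (chain == c) & (rid >= lo) & (rid <= hi)
    if not link.any():
        raise ValueError("no atoms in the linker ranges")
    masks["LINKER"] = link
    a, b = architecture.chain_ids
    masks["VL"] = masks[f"VL_{a}"] | masks[f"VL_{b}"]
    masks["CL"] = masks[f"CL_{a}"] | masks[f"CL_{b}"]
    return masks


def _coms(coords: np.ndarray, masses: np.ndarray,
          mask: np.ndarray) -> np.ndarray:
    """Vectorized COM over frames: coords (F, N, 3) -> (F, 3)."""
    m = masses[mask]
    return np.einsum("fij,i->fj", coords[:, mask, :], m) / m.sum()


def elbow_angle(frame: ConformerFrame,
                architecture: DomainArchitecture,
                ca_only: bool = False) -> float:
    """Elbow angle (rad) at the linker hinge between the VL and CL dimer arms.

    Vertex H is the center of mass of the linker residues of both chains;
    the angle is between H->COM(VL dimer) and H->COM(CL dimer).  Invariant
    under rigid-body transforms.
    """
    masks = _domain_masks(frame.atoms, architecture, ca_only)
    h = center_of_mass(frame, masks["LINKER"])
    v = center_of_mass(frame, masks["VL"]) - h
    c = center_of_mass(frame, masks["CL"]) - h
    nv, nc = np.linalg.norm(v), np.linalg.norm(c)
    if nv < _DEGENERATE_ARM or nc < _DEGENERATE_ARM:
        raise ValueError(
            f"degenerate elbow geometry: arm norms {nv:.2e}, {nc:.2e} nm"
        )
    cosang = np.clip(np.dot(v, c) / (nv * nc), -1.0, 1.0)
    return float(np.arccos(cosang))


def interdomain_distances(frame: ConformerFrame,
                          architecture: DomainArchitecture,
                          ca_only: bool = False) -> tuple[float, float, float]:
    """(d_vc, d_cc, d_vv) in nm for one frame."""
    masks = _domain_masks(frame.atoms, architecture, ca_only)
    a, b = architecture.chain_ids
    com = {k: center_of_mass(frame, masks[k]) for k in
           ("VL", "CL", f"CL_{a}", f"CL_{b}", f"VL_{a}", f"VL_{b}")}
    d_vc = float(np.linalg.norm(com["VL"] - com["CL"]))
    d_cc = float(np.linalg.norm(com[f"CL_{a}"] - com[f"CL_{b}"]))
    d_vv = float(np.linalg.norm(com[f"VL_{a}"] - com[f"VL_{b}"]))
    return d_vc, d_cc, d_vv


def compute_cv_table(ensemble: WeightedEnsemble,
                     architecture: DomainArchitecture,
                     ca_only: bool = False) -> list[CVRecord]:
    """Collective variables for every frame, in frame order.

    Vectorized over frames; each record carries the frame's weight.
    """
    masks = _domain_masks(ensemble.atoms, architecture, ca_only)
    masses = ensemble.masses
    a, b = architecture.chain_ids
    com_v = _coms(ensemble.coords, masses, masks["VL"])
    com_c = _coms(ensemble.coords, masses, masks["CL"])
    com_h = _coms(ensemble.coords, masses, masks["LINKER"])
    com_ca_ = _coms(ensemble.coords, masses, masks[f"CL_{a}"])
    com_cb_ = _coms(ensemble.coords, masses, masks[f"CL_{b}"])
    com_va_ = _coms(ensemble.coords, masses, masks[f"VL_{a}"])
    com_vb_ = _coms(ensemble.coords, masses, masks[f"VL_{b}"])

    v = com_v - com_h
    c = com_c - com_h
    nv = np.linalg.norm(v, axis=1)
    nc = np.linalg.norm(c, axis=1)
    bad = (nv < _DEGENERATE_ARM) | (nc < _DEGENERATE_ARM)
    if bad.any():
        raise ValueError(
            f"degenerate elbow geometry in frame {int(np.flatnonzero(bad)[0])}"
        )
    cosang = np.clip(np.einsum("ij,ij->i", v, c) / (nv * nc), -1.0, 1.0)
    theta = np.arccos(cosang)
    d_vc = np.linalg.norm(com_v - com_c, axis=1)
    d_cc = np.linalg.norm(com_ca_ - com_cb_, axis=1)
    d_vv = np.linalg.norm(com_va_ - com_vb_, axis=1)

    return [CVRecord(i, float(theta[i]), float(d_vc[i]), float(d_cc[i]),
                     float(d_vv[i]), float(ensemble.weights[i]))
            for i in range(ensemble.n_frames)]


def cv_table_to_frame(records: list[CVRecord]) -> pd.DataFrame:
    """CV records as a DataFrame (frame, theta_rad, d_vc_nm, d_cc_nm, d_vv_nm, weight)."""
    return pd.DataFrame({
        "frame": [r.frame_index for r in records],
        "theta_rad": [r.theta for r in records],
        "d_vc_nm": [r.d_vc for r in records],
        "d_cc_nm": [r.d_cc for r in records],
        "d_vv_nm": [r.d_vv for r in records],
        "weight": [r.weight for r in records],
    })


def cv_table_from_frame(df: pd.DataFrame) -> list[CVRecord]:
    """Inverse of :func:`cv_table_to_frame`."""
    return [CVRecord(int(r.frame), float(r.theta_rad), float(r.d_vc_nm),
                     float(r.d_cc_nm), float(r.d_vv_nm), float(r.weight))
            for r in df.itertuples(index=False)]
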