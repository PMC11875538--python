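"""Shared fixtures: tiny hand-built frames, synthetic ensembles, backbones."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lcfingerprint import (ConformerFrame, DomainArchitecture, SyntheticSpec,
                           WeightedEnsemble, generate_dimer_ensemble)


def make_frame(chains, res_ids, positions, masses=None, atom_names=None,
               res_names=None, elements=None) -> ConformerFrame:
    """Build a ConformerFrame from parallel lists (positions in nm)."""
    n = len(res_ids)
    atoms = pd.DataFrame({
        "chain_id": chains,
        "res_id": res_ids,
        "res_name": res_names if res_names is not None else ["GLY"] * n,
        "atom_name": atom_names if atom_names is not None else ["CA"] * n,
        "element": elements if elements is not None else ["C"] * n,
        "mass": masses if masses is not None else [12.011] * n,
    })
    return ConformerFrame(atoms, np.asarray(positions, dtype=float))


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector (nm)."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-5, 5, size=3)
    return R, t


def place_next_atom(a, b, c, bond, angle, dihedral):
    """NeRF placement: position d with given bond |cd|, angle bcd, dihedral abcd."""
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_coords(phi_deg: float, psi_deg: float) -> np.ndarray:
    """Coordinates (nm) of C(0), N(1), CA(1), C(1), N(2) realizing (phi, psi).

    Idealized geometry: 0.147 nm bonds, 120 deg bond angles.
    """
    ang = np.radians(120.0)
    r = 0.147
    c_prev = np.array([0.0, 0.0, 0.0])
    n = np.array([r, 0.0, 0.0])
    ca = n + r * np.array([np.cos(np.radians(60.0)), np.sin(np.radians(60.0)), 0.0])
    c = place_next_atom(c_prev, n, ca, r, ang, np.radians(phi_deg))
    n_next = place_next_atom(n, ca, c, r, ang, np.radians(psi_deg))
    return np.stack([c_prev, n, ca, c, n_next])


def backbone_ensemble(phi_psi_list, weights=None) -> WeightedEnsemble:
    """Ensemble of 5-atom backbones, one frame per (phi, psi) pair (degrees).

    Residue 1 of chain A carries the (phi, psi) of interest.
    """
    atoms = pd.DataFrame({
        "chain_id": ["A"] * 5,
        "res_id": [0, 1, 1, 1, 2],
        "res_name": ["GLY"] * 5,
        "atom_name": ["C", "N", "CA", "C", "N"],
        "element": ["C", "N", "C", "C", "N"],
        "mass": [12.011, 14.007, 12.011, 12.011, 14.007],
    })
    coords = np.stack([backbone_coords(phi, psi) for phi, psi in phi_psi_list])
    n = len(phi_psi_list)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    return WeightedEnsemble(atoms, coords, w)


@pytest.fixture(scope="session")
def default_arch() -> DomainArchitecture:
    return DomainArchitecture.default()


@pytest.fixture(scope="session")
def small_ensemble():
    """200-frame default-population synthetic ensemble with ground truth."""
    spec = SyntheticSpec(n_frames=200, seed=11)
    ens, labels, truth = generate_dimer_ensemble(spec)
    return spec, ens, labels, truth


@pytest.fixture(scope="session")
def exact_ensemble():
    """Zero-jitter ensemble: measured CVs equal the construction targets."""
    spec = SyntheticSpec(n_frames=60, seed=7, jitter_sigma=0.0)
    ens, labels, truth = generate_dimer_ensemble(spec)
    return spec, ens, labels, truth
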