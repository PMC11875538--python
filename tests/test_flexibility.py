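"""RMSF with weighted superposition and Ramachandran occupancies."""

import numpy as np
import pandas as pd
import pytest

from lcfingerprint import (DomainArchitecture, WeightedEnsemble, average_rmsf,
                           left_handed_alpha_occupancy, rmsf)
from lcfingerprint.flexibility import (ALPHA_L_REGION, RMSFProfile, _dihedral,
                                       ramachandran_angles, region_occupancy)

from conftest import backbone_ensemble, random_rigid_transform


ARCH = DomainArchitecture(("A", "B"), (1, 10), (11, 12), (13, 20))


def ca_chain_ensemble(frame_coords, weights=None):
    """Ensemble of C-alpha-only chains covering residues 1-20 on chains A, B."""
    n_res = 20
    rows = []
    for chain in ("A", "B"):
        for r in range(1, n_res + 1):
            rows.append({"chain_id": chain, "res_id": r, "res_name": "GLY",
                         "atom_name": "CA", "element": "C", "mass": 12.011})
    atoms = pd.DataFrame(rows)
    coords = np.asarray(frame_coords, float)
    n = coords.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    return WeightedEnsemble(atoms, coords, w)


def helix_chain_coords():
    """One frame: both chains on a helix (superposition is well-conditioned)."""
    xyz = np.zeros((40, 3))
    for i in range(20):
        xyz[i] = [0.15 * i, np.cos(0.7 * i), np.sin(0.7 * i)]
        xyz[20 + i] = [0.15 * i, 3.0 + np.cos(0.7 * i), np.sin(0.7 * i)]
    return xyz


class TestRmsf:
    def test_identical_frames_have_zero_rmsf(self):
        base = helix_chain_coords()
        ens = ca_chain_ensemble([base, base, base])
        prof = rmsf(ens, ARCH, "A", "VL")
        assert np.allclose(prof.values, 0.0, atol=1e-12)
        assert len(prof.values) == 10

    def test_single_displaced_atom_equal_weights(self):
        # one atom moved 0.2 nm in one of two frames; deviations are +-0.1
        base = helix_chain_coords()
        moved = base.copy()
        moved[4, 2] += 0.2  # residue 5 of chain A
        ens = ca_chain_ensemble([base, moved])
        prof = rmsf(ens, ARCH, "A", "VL",
                    fit_core={1, 2, 3, 7, 8, 9, 10})
        i = list(prof.res_ids).index(5)
        assert prof.values[i] == pytest.approx(0.1, abs=1e-6)
        others = np.delete(prof.values, i)
        assert np.all(others < 1e-6)

    def test_single_displaced_atom_skewed_weights(self):
        # weighted-variance oracle: sqrt(0.9*0.02^2 + 0.1*0.18^2) = 0.06
        base = helix_chain_coords()
        moved = base.copy()
        moved[4, 2] += 0.2
        ens = ca_chain_ensemble([base, moved], weights=[0.9, 0.1])
        prof = rmsf(ens, ARCH, "A", "VL",
                    fit_core={1, 2, 3, 7, 8, 9, 10})
        i = list(prof.res_ids).index(5)
        assert prof.values[i] == pytest.approx(0.06, abs=1e-6)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        base = helix_chain_coords()
        frames = [base + rng.normal(0, 0.05, base.shape) for _ in range(5)]
        ens = ca_chain_ensemble(frames)
        prof0 = rmsf(ens, ARCH, "A", "VL")
        R, t = random_rigid_transform(rng)
        moved = ca_chain_ensemble([f @ R.T + t for f in frames])
        prof1 = rmsf(moved, ARCH, "A", "VL")
        assert np.allclose(prof0.values, prof1.values, atol=1e-9)

    def test_extra_iterations_change_little(self):
        rng = np.random.default_rng(9)
        base = helix_chain_coords()
        frames = [base + rng.normal(0, 0.05, base.shape) for _ in range(8)]
        ens = ca_chain_ensemble(frames)
        p2 = rmsf(ens, ARCH, "A", "VL", n_iter=2)
        p4 = rmsf(ens, ARCH, "A", "VL", n_iter=4)
        assert np.abs(p2.values - p4.values).max() < 1e-4

    def test_too_small_fit_core_rejected(self):
        ens = ca_chain_ensemble([helix_chain_coords()])
        with pytest.raises(ValueError, match="at least 3"):
            rmsf(ens, ARCH, "A", "VL", fit_core={1, 2})


class TestAverageRmsf:
    def _profile(self, values, tag):
        return RMSFProfile(np.arange(1, len(values) + 1), values,
                           domain="VL", provenance=[tag])

    def test_identical_profiles_unchanged(self):
        p = self._profile([0.1, 0.2, 0.3], "r1:A")
        avg = average_rmsf([p, p])
        assert np.allclose(avg.values, p.values)

    def test_chain_mean(self):
        a = self._profile([0.1, 0.1], "r1:A")
        b = self._profile([0.3, 0.3], "r1:B")
        assert np.allclose(average_rmsf([a, b]).values, 0.2)

    def test_provenance_lists_all_inputs(self):
        profs = [self._profile([0.1], f"r{i}:{c}")
                 for i in (1, 2) for c in ("A", "B")]
        avg = average_rmsf(profs)
        assert sorted(avg.provenance) == ["r1:A", "r1:B", "r2:A", "r2:B"]

    def test_label_mismatch_rejected(self):
        a = self._profile([0.1, 0.2], "x")
        b = RMSFProfile(np.array([5, 6]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="different residue"):
            average_rmsf([a, b])


class TestRamachandran:
    def test_dihedral_matches_biotite(self):
        import biotite.structure as struc
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.normal(size=(4, 3))
            ours = _dihedral(p[0], p[1], p[2], p[3])
            theirs = struc.dihedral(p[0], p[1], p[2], p[3])
            assert float(ours) == pytest.approx(float(theirs), abs=1e-6)

    def test_constructed_backbone_recovers_phi_psi(self):
        ens = backbone_ensemble([(60.0, 45.0), (-60.0, -45.0)])
        phi, psi = ramachandran_angles(ens, "A", 1)
        assert phi == pytest.approx([60.0, -60.0], abs=1e-6)
        assert psi == pytest.approx([45.0, -45.0], abs=1e-6)

    def test_all_frames_inside_alpha_l(self):
        ens = backbone_ensemble([(60.0, 45.0)] * 3)
        assert left_handed_alpha_occupancy(ens, "A", 1) == pytest.approx(1.0)

    def test_all_frames_outside_alpha_l(self):
        ens = backbone_ensemble([(-60.0, -45.0)] * 3)
        assert left_handed_alpha_occupancy(ens, "A", 1) == pytest.approx(0.0)

    def test_weighted_half_occupancy(self):
        ens = backbone_ensemble([(60.0, 45.0), (-60.0, -45.0)],
                                weights=[0.5, 0.5])
        assert left_handed_alpha_occupancy(ens, "A", 1) == pytest.approx(0.5)

    def test_exhaustive_partition_sums_to_one(self):
        ens = backbone_ensemble([(60.0, 45.0), (-60.0, -45.0), (170.0, 170.0),
                                 (-170.0, 10.0)])
        # four rectangles tiling the torus (phi half-open, psi closed-open
        # via complementary rectangles)
        total = 0.0
        for phi_lo, phi_hi in ((-180.0, 0.0), (0.0, 180.0)):
            phi_part = (region_occupancy(ens, "A", 1,
                                         (phi_lo, phi_hi, -60.0, 90.0))
                        + region_occupancy(ens, "A", 1,
                                           (phi_lo, phi_hi, 90.0 + 1e-12, 180.0))
                        + region_occupancy(ens, "A", 1,
                                           (phi_lo, phi_hi, -180.0, -60.0 - 1e-12)))
            total += phi_part
        assert total == pytest.approx(1.0)

    def test_terminal_residue_rejected(self):
        ens = backbone_ensemble([(60.0, 45.0)])
        with pytest.raises(ValueError, match="terminal"):
            ramachandran_angles(ens, "A", 0)
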