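"""Debye back-calculation, ensemble averaging, chi-square and Guinier fits."""

import numpy as np
import pytest

from lcfingerprint import (SAXSCurve, SyntheticSpec, WeightedEnsemble,
                           debye_intensity, ensemble_average_rg,
                           ensemble_intensity, fit_scale_and_chi2,
                           generate_dimer_ensemble, guinier_rg, kratky,
                           make_noisy_curve, sphere_intensity)

from conftest import make_frame


Q = np.linspace(0.005, 0.3, 80)


def two_point_frame(d_nm):
    return make_frame(["A", "A"], [1, 2], [[0, 0, 0], [d_nm, 0, 0]],
                      elements=["C", "C"])


class TestDebyeIntensity:
    def test_single_scatterer_is_flat(self):
        f = make_frame(["A"], [1], [[0.3, 0.1, 0.2]])
        curve = debye_intensity(f, Q, representation="atomic")
        assert np.allclose(curve.I, 36.0)  # f = Z_C = 6, I = f^2

    def test_two_point_closed_form(self):
        # I(q) = 2 f^2 (1 + sin(qd)/(qd)) for two equal scatterers
        f = two_point_frame(0.5)
        curve = debye_intensity(f, Q, representation="atomic")
        qd = Q * 5.0  # d in Angstrom
        expected = 2 * 36.0 * (1 + np.sin(qd) / qd)
        assert np.abs(curve.I - expected).max() < 1e-10

    def test_i0_is_total_scattering_squared(self, exact_ensemble):
        spec, ens, _, _ = exact_ensemble
        frame = ens.frame(0)
        curve = debye_intensity(frame, np.array([0.0, 0.01]))
        n_res = len(frame.atoms)  # one bead per residue
        assert curve.I[0] == pytest.approx((30.0 * n_res) ** 2)

    def test_low_q_slope_matches_coordinate_rg(self, exact_ensemble):
        """Guinier-limit oracle: slope of ln I vs q^2 equals -Rg^2/3."""
        spec, ens, _, _ = exact_ensemble
        single = WeightedEnsemble(ens.atoms, ens.coords[:1], np.array([1.0]))
        rg_coord_nm, _ = ensemble_average_rg(single)
        rg_A = rg_coord_nm * 10
        q = np.linspace(0.001, 0.5 / rg_A, 30)
        curve = debye_intensity(single.frame(0), q)
        slope = np.polyfit(q ** 2, np.log(curve.I), 1)[0]
        assert np.sqrt(-3 * slope) == pytest.approx(rg_A, rel=0.01)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            debye_intensity(two_point_frame(0.5), np.array([-0.1, 0.1]))


class TestEnsembleIntensity:
    def _tiny(self, weights):
        spec = SyntheticSpec(n_frames=2, seed=5, beads_per_domain=6,
                             beads_per_linker=3)
        ens, _, _ = generate_dimer_ensemble(spec)
        return WeightedEnsemble(ens.atoms, ens.coords, weights)

    def test_single_frame_identity(self):
        ens = self._tiny(np.array([1.0, 0.0]))
        curve = ensemble_intensity(ens, Q)
        ref = debye_intensity(ens.frame(0), Q)
        assert np.allclose(curve.I, ref.I)

    def test_equal_weights_give_arithmetic_mean(self):
        ens = self._tiny(np.array([0.5, 0.5]))
        curve = ensemble_intensity(ens, Q)
        mean = 0.5 * (debye_intensity(ens.frame(0), Q).I
                      + debye_intensity(ens.frame(1), Q).I)
        assert np.allclose(curve.I, mean)


class TestFitScaleAndChi2:
    def test_identical_curves_fit_exactly(self):
        calc = sphere_intensity(2.5, Q, i0=100.0)
        exp = SAXSCurve(Q, calc.I, np.ones_like(Q))
        fit = fit_scale_and_chi2(calc, exp)
        assert fit.scale == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(fit.residuals, 0.0)

    def test_doubled_curve_recovers_scale_two(self):
        calc = sphere_intensity(2.5, Q, i0=100.0)
        exp = SAXSCurve(Q, 2 * calc.I, np.ones_like(Q))
        fit = fit_scale_and_chi2(calc, exp)
        assert fit.scale == pytest.approx(2.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)

    def test_three_point_hand_normal_equations(self):
        q = np.array([0.01, 0.02, 0.03])
        calc = SAXSCurve(q, np.array([5.0, 2.5, 1.0]))
        exp = SAXSCurve(q, np.array([10.0, 5.0, 2.0]), np.ones(3))
        fit = fit_scale_and_chi2(calc, exp, fit_background=False)
        assert fit.scale == pytest.approx(2.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-24)

    def test_background_fit(self):
        q = np.linspace(0.01, 0.2, 50)
        calc = sphere_intensity(2.0, q, i0=50.0)
        exp = SAXSCurve(q, 3.0 * calc.I + 7.0, np.ones_like(q))
        fit = fit_scale_and_chi2(calc, exp, fit_background=True)
        assert fit.scale == pytest.approx(3.0)
        assert fit.background == pytest.approx(7.0)

    def test_missing_sigma_rejected(self):
        calc = sphere_intensity(2.0, Q)
        with pytest.raises(ValueError, match="uncertainties"):
            fit_scale_and_chi2(calc, calc)

    def test_noisy_reduced_chi2_near_one(self):
        base = sphere_intensity(2.5, np.linspace(0.005, 0.2, 200), i0=1000.0)
        noisy = make_noisy_curve(base, rel_sigma=0.02, seed=3)
        fit = fit_scale_and_chi2(base, noisy)
        assert 0.5 <= fit.chi2 <= 1.5


class TestGuinier:
    def test_exact_guinier_law_recovered(self):
        # I = 100 exp(-q^2 Rg^2 / 3) with Rg = 2.5 nm = 25 A
        q = np.linspace(0.001, 0.05, 100)
        curve = SAXSCurve(q, 100.0 * np.exp(-q ** 2 * 25.0 ** 2 / 3.0))
        res = guinier_rg(curve)
        assert res.rg == pytest.approx(2.5, abs=1e-6)
        assert res.i0 == pytest.approx(100.0, abs=1e-6)

    def test_sphere_form_factor(self):
        # Guinier radius of a homogeneous sphere: sqrt(3/5) R
        R = 3.227
        curve = sphere_intensity(R, np.linspace(0.002, 0.2, 400), i0=100.0)
        res = guinier_rg(curve)
        assert res.rg == pytest.approx(np.sqrt(3 / 5) * R, rel=0.01)
        assert res.qmax_rg <= 1.3

    def test_noisy_curve_within_three_stderr(self):
        q = np.linspace(0.002, 0.1, 150)
        clean = SAXSCurve(q, 500.0 * np.exp(-q ** 2 * 25.0 ** 2 / 3.0))
        noisy = make_noisy_curve(clean, rel_sigma=0.02, seed=7)
        res = guinier_rg(noisy)
        assert res.rg_stderr > 0
        assert abs(res.rg - 2.5) < 3 * res.rg_stderr

    def test_rising_curve_has_no_guinier_regime(self):
        q = np.linspace(0.01, 0.1, 30)
        curve = SAXSCurve(q, 1.0 + q ** 2)
        with pytest.raises(ValueError, match="no Guinier regime"):
            guinier_rg(curve)

    def test_too_few_points_rejected(self):
        q = np.array([0.01, 0.02, 0.03, 0.04])
        with pytest.raises(ValueError, match="fewer than 5"):
            guinier_rg(SAXSCurve(q, np.exp(-q ** 2)))

    def test_dumbbell_ensemble_guinier_matches_coordinate_rg(self, exact_ensemble):
        spec, ens, _, _ = exact_ensemble
        rg_coord, _ = ensemble_average_rg(ens)
        qmax = 1.3 / (rg_coord * 10)
        sub = WeightedEnsemble(ens.atoms, ens.coords[:10],
                               np.full(10, 0.1))
        curve = ensemble_intensity(sub, np.linspace(qmax / 60, qmax, 60))
        rg_sub, _ = ensemble_average_rg(sub)
        res = guinier_rg(curve)
        assert res.rg == pytest.approx(rg_sub, rel=0.02)


class TestKratky:
    def test_constant_intensity_gives_parabola(self):
        curve = SAXSCurve(Q, np.full_like(Q, 3.0))
        k = kratky(curve)
        assert np.allclose(k.I, 3.0 * Q ** 2)

    def test_peak_of_gaussian_curve_at_sqrt3_over_rg(self):
        # d/dq [q^2 exp(-q^2 Rg^2/3)] = 0 at q = sqrt(3)/Rg
        rg_A = 25.0
        q = np.linspace(0.005, 0.2, 4000)
        curve = SAXSCurve(q, np.exp(-q ** 2 * rg_A ** 2 / 3.0))
        k = kratky(curve)
        q_peak = k.q[np.argmax(k.I)]
        assert q_peak == pytest.approx(np.sqrt(3.0) / rg_A, rel=1e-3)

    def test_transform_preserves_sigma_scaling(self):
        curve = SAXSCurve(Q, np.full_like(Q, 2.0), np.full_like(Q, 0.1))
        k = kratky(curve)
        assert np.allclose(k.sigma, 0.1 * Q ** 2)
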