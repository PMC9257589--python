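"""Forward model: constitutive law, equilibrium solver, strain profiles."""

import numpy as np
import pytest
from dataclasses import replace

from irismech.fem import (
    FESolution,
    IrisModelConfig,
    SolverError,
    cauchy_stress,
    plane_stress_lambda_z,
    pupil_strain_for_ratio,
    solve_iris,
    strain_profiles,
)


class TestCauchyStress:
    def test_reference_state_is_stress_free(self):
        s = cauchy_stress(1.0, 1.0, 1.0, E=10.0, nu=0.3)
        assert np.allclose(s, 0.0, atol=1e-14)

    def test_active_traction_at_identity_is_pure_hoop(self):
        srr, stt, szz = cauchy_stress(1.0, 1.0, 1.0, E=10.0, nu=0.3,
                                      active=10.0)
        assert stt == pytest.approx(10.0)
        assert srr == pytest.approx(0.0, abs=1e-14)
        assert szz == pytest.approx(0.0, abs=1e-14)

    def test_small_strain_uniaxial_matches_linear_elasticity(self):
        # plane-strain uniaxial stretch: sigma_rr -> (lambda_L + 2 mu) e
        E, nu, e = 10.0, 0.3, 1e-6
        mu = E / (2 * (1 + nu))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        srr, _, _ = cauchy_stress(1.0 + e, 1.0, 1.0, E=E, nu=nu)
        assert srr == pytest.approx((lam + 2 * mu) * e, rel=1e-5)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            cauchy_stress(-0.5, 1.0, 1.0, E=1.0, nu=0.3)

    @pytest.mark.parametrize("lam_r,lam_t", [(1.3, 0.6), (0.8, 1.1),
                                             (2.0, 0.5)])
    def test_plane_stress_condition_is_enforced(self, lam_r, lam_t):
        E, nu = 5.0, 0.4
        mu = E / (2 * (1 + nu))
        lamL = E * nu / ((1 + nu) * (1 - 2 * nu))
        lz = plane_stress_lambda_z(lam_r, lam_t, mu, lamL)
        _, _, szz = cauchy_stress(lam_r, lam_t, lz, E=E, nu=nu)
        assert abs(szz) < 1e-10


class TestSolveIris:
    def test_zero_traction_is_identity(self):
        sol = solve_iris(IrisModelConfig(traction=0.0))
        assert np.allclose(sol.r, sol.R, atol=1e-12)
        assert sol.pupil_strain == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_pupil_strain(self):
        e1 = solve_iris(IrisModelConfig(youngs_modulus=10, traction=50)).pupil_strain
        e2 = solve_iris(IrisModelConfig(youngs_modulus=20, traction=100)).pupil_strain
        assert abs(e1 - e2) < 1e-8

    def test_mesh_convergence(self):
        e100 = solve_iris(IrisModelConfig(traction=5, n_elements=100)).pupil_strain
        e400 = solve_iris(IrisModelConfig(traction=5, n_elements=400)).pupil_strain
        assert abs(e100 - e400) < 1e-3

    def test_reference_geometry_gives_published_strain_scale(self):
        # a 1 mm sphincter at T_s:E = 5 constricts the pupil to roughly
        # the cohort maximum strain
        eps = pupil_strain_for_ratio(5.0, sphincter_width=1.0,
                                     poisson_ratio=0.49)
        assert eps == pytest.approx(-0.386, rel=0.15)

    def test_strain_magnitude_increases_with_traction(self):
        eps = [pupil_strain_for_ratio(r) for r in (0.5, 1.0, 2.0, 4.0)]
        assert all(e2 < e1 for e1, e2 in zip(eps, eps[1:]))

    def test_deformed_radius_monotone_and_J_positive(self):
        sol = solve_iris(IrisModelConfig(traction=5.0))
        assert np.all(np.diff(sol.r) > 0)
        assert np.all(sol.J > 0)

    def test_warm_start_agrees_with_cold_start(self):
        cfg = IrisModelConfig(traction=4.0)
        cold = solve_iris(cfg)
        near = solve_iris(IrisModelConfig(traction=3.5))
        warm = solve_iris(cfg, warm_start=near)
        assert warm.pupil_strain == pytest.approx(cold.pupil_strain,
                                                  abs=1e-10)

    def test_small_strain_matches_linear_ode_oracle(self):
        """Independent finite-difference solve of the linearised
        plane-stress equations with an active hoop stress in the ring."""

        def linear_pupil_strain(rho, a_s=1.0, nu=0.3, n=4000):
            Rin, Rout = 3.4, 6.0
            C = 1.0 / (1 - nu ** 2)
            R = np.linspace(Rin, Rout, n)
            h = R[1] - R[0]
            T = np.where(R <= Rin + a_s, rho, 0.0)
            A = np.zeros((n, n))
            b = np.zeros(n)
            for i in range(1, n - 1):
                A[i, i - 1] = C * (1 / h ** 2 - 1 / (2 * h * R[i]))
                A[i, i] = C * (-2 / h ** 2 - 1 / R[i] ** 2)
                A[i, i + 1] = C * (1 / h ** 2 + 1 / (2 * h * R[i]))
                b[i] = T[i] / R[i]
            A[0, 0] = -3 / (2 * h) + nu / Rin
            A[0, 1] = 4 / (2 * h)
            A[0, 2] = -1 / (2 * h)
            A[-1, -1] = 1.0
            u = np.linalg.solve(A, b)
            return u[0] / Rin

        for rho in (0.01, 0.05, 0.1):
            fe = pupil_strain_for_ratio(rho, poisson_ratio=0.3)
            lin = linear_pupil_strain(rho)
            assert fe == pytest.approx(lin, rel=0.01)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            IrisModelConfig(poisson_ratio=0.6)
        with pytest.raises(ValueError):
            IrisModelConfig(sphincter_width=5.0)
        with pytest.raises(ValueError):
            IrisModelConfig(traction=-1.0)

    def test_extreme_traction_approaches_closed_pupil(self):
        # the fiber push-forward makes the active hoop stress scale with
        # lambda_theta^2, so constriction is self-limiting: the pupil
        # approaches but never reaches full closure
        sol = solve_iris(IrisModelConfig(traction=500.0))
        assert -0.5 < sol.pupil_strain < -0.45
        assert sol.r[0] > 0.0


class TestStrainProfiles:
    def test_zero_load_profiles_vanish(self):
        prof = strain_profiles(solve_iris(IrisModelConfig(traction=0.0)))
        assert np.allclose(prof[["E_rr", "E_tt", "E_rt"]], 0.0, atol=1e-12)

    def test_limbus_hoop_strain_is_zero(self):
        sol = solve_iris(IrisModelConfig(traction=5.0))
        assert sol.E_tt[-1] == 0.0

    def test_peak_radial_strain_at_sphincter_edge(self):
        cfg = IrisModelConfig(traction=5.0, sphincter_width=1.0)
        prof = strain_profiles(solve_iris(cfg))
        edge = cfg.sphincter_width / (cfg.R_out - cfg.R_in)
        elem = 1.0 / cfg.n_elements
        assert abs(prof.attrs["peak_E_rr_x_bar"] - edge) < 3 * elem

    def test_shear_identically_zero(self):
        prof = strain_profiles(solve_iris(IrisModelConfig(traction=3.0)))
        assert np.all(prof["E_rt"] == 0.0)
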