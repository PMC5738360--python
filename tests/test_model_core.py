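"""Closed-form steady-state algebra and the coupled fixed-point solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chachakit as ck
from chachakit.model_core import SteadyStateConvergenceError, chacha_rhs

from conftest import random_rate_params


class TestDoxSteadyState:
    def setup_method(self):
        self.p = ck.DoxInductionParams(kappa1=100.0, kappa2=10.0, K_D=50.0, n_hill=1.0)

    def test_zero_dox_gives_zero_reporter(self):
        assert ck.dox_steady_state_gfp(0.0, self.p) == 0.0

    def test_saturation_approaches_kappa1_kappa2(self):
        g = ck.dox_steady_state_gfp(1e9, self.p)
        assert g == pytest.approx(self.p.kappa1 * self.p.kappa2, rel=1e-6)

    def test_half_saturation_at_kd(self):
        # D^n == K_D -> half of the plateau (m = 1)
        d = self.p.K_D ** (1.0 / self.p.n_hill)
        assert ck.dox_steady_state_gfp(d, self.p) == pytest.approx(
            self.p.kappa1 * self.p.kappa2 / 2
        )

    def test_general_m_exponent(self):
        pm = ck.DoxInductionParams(kappa1=4.0, kappa2=3.0, K_D=1.0, n_hill=1.0, m=2.0)
        # C_ss at D=1 is kappa1/2 = 2; G = kappa2 * C^2 = 12
        assert ck.dox_steady_state_gfp(1.0, pm) == pytest.approx(12.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            ck.dox_steady_state_gfp(-1.0, self.p)


class TestChaChaSurface:
    def setup_method(self):
        self.p = ck.SteadyStateParams(G_max=100.0, K_L=10.0, K_A=5.0, n_stoich=2.0)

    @pytest.mark.parametrize("L,A", [(0.0, 7.0), (3.0, 0.0), (0.0, 0.0)])
    def test_zero_input_gives_zero(self, L, A):
        assert ck.chacha_steady_state_gfp(L, A, self.p) == 0.0

    def test_product_of_half_maxima_is_quarter_plateau(self):
        A_half = self.p.K_A ** (1.0 / self.p.n_stoich)
        g = ck.chacha_steady_state_gfp(self.p.K_L, A_half, self.p)
        assert g == pytest.approx(self.p.G_max / 4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ck.chacha_steady_state_gfp(-1.0, 1.0, self.p)
        with pytest.raises(ValueError):
            ck.chacha_steady_state_gfp(1.0, -1.0, self.p)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_monotone_nondecreasing_in_both_arguments(self, L, A):
        grid_L = np.linspace(L, L * 10, 101)
        grid_A = np.linspace(A, A * 10, 101)
        along_L = ck.chacha_steady_state_gfp(grid_L, A, self.p)
        along_A = ck.chacha_steady_state_gfp(L, grid_A, self.p)
        assert np.all(np.diff(along_L) >= 0)
        assert np.all(np.diff(along_A) >= 0)

    @given(st.floats(1e-3, 1e3), st.floats(0.1, 100), st.floats(0.1, 100))
    def test_plateau_scale_consistency(self, c, L, A):
        scaled = ck.SteadyStateParams(
            G_max=self.p.G_max * c, K_L=self.p.K_L, K_A=self.p.K_A,
            n_stoich=self.p.n_stoich,
        )
        assert ck.chacha_steady_state_gfp(L, A, scaled) == pytest.approx(
            c * ck.chacha_steady_state_gfp(L, A, self.p), rel=1e-12
        )


class TestLumping:
    def test_unit_rates(self, unit_rates):
        lp = ck.derive_steady_state_params(unit_rates)
        assert lp.G_max == pytest.approx(0.5)
        assert lp.K_L == pytest.approx(1.0)
        assert lp.K_A == pytest.approx(1.0)
        assert lp.n_stoich == 1.0

    def test_k_l_proportional_to_receptor_degradation(self, unit_rates):
        doubled = unit_rates.model_copy(update={"beta_R": 2.0})
        assert ck.derive_steady_state_params(doubled).K_L == pytest.approx(
            2 * ck.derive_steady_state_params(unit_rates).K_L
        )


class TestCoupledSteadyState:
    def test_no_ligand_limits(self, unit_rates):
        sol = ck.solve_coupled_steady_state(unit_rates, 0.0)
        assert sol["Rstar_ss"] == 0.0
        assert sol["C_ss"] == 0.0
        assert sol["G_ss"] == 0.0
        assert sol["A_ss"] == pytest.approx(unit_rates.alpha_A / unit_rates.beta_A)
        assert sol["R_ss"] == pytest.approx(unit_rates.alpha_R / unit_rates.beta_R)

    def test_unit_rates_agree_with_long_integration(self, unit_rates):
        sol = ck.solve_coupled_steady_state(unit_rates, 1.0)
        traj = ck.simulate_chacha(
            unit_rates, ck.Schedule.constant(1.0), (0.0, 200.0), rtol=1e-9, atol=1e-12
        )
        for i, sym in enumerate(("R", "Rstar", "A", "C", "G")):
            key = {"R": "R_ss", "Rstar": "Rstar_ss", "A": "A_ss",
                   "C": "C_ss", "G": "G_ss"}[sym]
            assert traj.terminal(sym) == pytest.approx(sol[key], rel=1e-6)

    @pytest.mark.parametrize("n_stoich", [0.5, 1.0, 2.0, 2.33, 3.0])
    def test_residuals_vanish_for_random_draws(self, n_stoich):
        rng = np.random.default_rng(int(n_stoich * 100))
        for _ in range(10):
            p = random_rate_params(rng, n_stoich)
            L = float(np.exp(rng.uniform(np.log(0.1), np.log(10))))
            sol = ck.solve_coupled_steady_state(p, L)
            state = np.array([sol["R_ss"], sol["Rstar_ss"], sol["A_ss"],
                              sol["C_ss"], sol["G_ss"]])
            rhs = chacha_rhs(state, L, p)
            # balances are relative to the dominant flux in each equation
            assert np.all(np.abs(rhs) <= 1e-8 * max(p.alpha_R, p.alpha_A, 1.0))

    def test_surface_identity_reproduces_g_ss(self, unit_rates):
        """Plugging (L, A_ss) into the lumped surface returns the solved G_ss."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_rate_params(rng, 2.33)
            L = float(rng.uniform(0.1, 10.0))
            sol = ck.solve_coupled_steady_state(p, L)
            lp = ck.derive_steady_state_params(p)
            g = ck.chacha_steady_state_gfp(L, sol["A_ss"], lp)
            assert g == pytest.approx(sol["G_ss"], rel=1e-8)

    def test_closed_form_matches_ode_with_solved_adaptor(self):
        """Long-time integration agrees with the closed form at the solved A_ss."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_rate_params(rng, 2.0)
            L = 1.0
            sol = ck.solve_coupled_steady_state(p, L)
            t_end = 60.0 / min(p.beta_R, p.beta_Rstar, p.beta_A, p.beta_C, p.beta_G)
            traj = ck.simulate_chacha(
                p, ck.Schedule.constant(L), (0.0, t_end), rtol=1e-9, atol=1e-12
            )
            lp = ck.derive_steady_state_params(p)
            g_closed = ck.chacha_steady_state_gfp(L, sol["A_ss"], lp)
            assert traj.terminal("G") == pytest.approx(g_closed, rel=1e-4)

    def test_negative_ligand_rejected(self, unit_rates):
        with pytest.raises(ValueError):
            ck.solve_coupled_steady_state(unit_rates, -1.0)

    def test_convergence_error_carries_residual_report(self, unit_rates):
        with pytest.raises(SteadyStateConvergenceError) as err:
            ck.solve_coupled_steady_state(unit_rates, 1.0, rtol=1e-30)
        assert err.value.residuals  # named, per-equation report
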