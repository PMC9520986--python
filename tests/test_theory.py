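"""Analytical apparatus: chi, Flory gamma, f1/f2, the mu ODE and its closed form."""

import math

import numpy as np
import pytest
import sympy

from fractalknots import theory


class TestChi:
    def test_values(self):
        assert theory.chi_of(2.0) == 2.0
        assert theory.chi_of(3.0) == pytest.approx(5.0 / 3.0, rel=1e-15)

    def test_large_df_limit(self):
        assert theory.chi_of(1e9) == pytest.approx(1.0, abs=1e-8)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            theory.chi_of(0.0)


class TestGammaFlory:
    def test_ideal_chain_swelling(self):
        # independent symbolic oracle: minimize F = v N^2/R^d + R^2/N^(2/d_f)
        R, N, v, d_f = sympy.symbols("R N v d_f", positive=True)
        d = 3
        F = v * N**2 / R**d + R**2 / N ** (sympy.Integer(2) / d_f)
        Rstar = sympy.solve(sympy.diff(F, R), R)[0]
        # swelling exponent nu = d log R* / d log N
        nu = sympy.simplify(N * sympy.diff(sympy.log(Rstar), N))
        # nu = 3/5 for the ordinary chain; gamma = 1 + 2 nu = 11/5
        assert sympy.simplify(nu.subs(d_f, 2) - sympy.Rational(3, 5)) == 0
        assert sympy.simplify(nu - (2 + 2 / d_f) / 5) == 0
        assert theory.gamma_flory(2.0, 3) == pytest.approx(11.0 / 5.0, rel=1e-14)

    def test_crossing_at_three_halves_is_exact(self):
        # symbolically: gamma(d_f) - chi(d_f) = 0 at d_f = 3/2 in 3D
        x = sympy.Symbol("x", positive=True)
        gamma = 1 + 2 * (2 * (1 + 1 / x) / 5)
        chi = 1 + 2 / x
        roots = sympy.solve(sympy.Eq(gamma, chi), x)
        assert sympy.Rational(3, 2) in roots
        assert abs(theory.delta_exponent(1.5, 3)) < 1e-14

    def test_gamma_dominates_chi_above_crossing(self):
        grid = np.linspace(1.5, 12.0, 400)
        assert np.all(theory.gamma_flory(grid, 3) >= theory.chi_of(grid) - 1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            theory.gamma_flory(0.9, 3)
        with pytest.raises(ValueError):
            theory.gamma_flory(2.0, 4)


class TestFFunctions:
    def test_sign_structure(self):
        # f1 vanishes at the crossing, is negative above it
        f1_lo, _ = theory.f_functions(1.5)
        assert abs(f1_lo) < 1e-14
        f1, f2 = theory.f_functions(np.array([2.0, 3.0, 5.0]))
        assert np.all(f1 < 0)

    def test_roughly_constant_on_trusted_range(self):
        pts = np.array([x for x in theory.FIG_GRID if x > theory.TRUST_DF_MIN])
        f1, f2 = theory.f_functions(pts)
        assert np.std(f1) / abs(np.mean(f1)) < 0.35
        ratio = -f2 / f1
        assert np.std(ratio) / abs(np.mean(ratio)) < 0.25

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            theory.f_functions(8.0)

    def test_extrapolated_flag(self):
        assert theory.theory_params(1.2).extrapolated
        assert not theory.theory_params(3.0).extrapolated


class TestModeAmplitudeModel:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_continuity_at_crossover(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(34):  # ~100 random triples across the three seeds
            N = int(rng.integers(100, 2000))
            N0 = float(rng.uniform(5.0, N / 4.0))
            d_f = float(rng.uniform(1.8, 5.0))
            q_star = N / (2.0 * N0)
            if q_star < 1.0 or q_star > N / 2:
                continue
            below = theory.mode_amplitude_model(q_star * (1 - 1e-12), N, N0, d_f)
            above = theory.mode_amplitude_model(q_star * (1 + 1e-12), N, N0, d_f)
            assert below == pytest.approx(above, rel=1e-9)

    def test_unconstrained_branch_is_bare_spectrum(self):
        N, N0, d_f, d = 400, 50.0, 3.0, 3
        from fractalknots.beta_model import build_spectrum

        sp = build_spectrum(N, d_f, d)
        q = np.arange(int(N / (2 * N0)) + 2, N // 2)
        model = theory.mode_amplitude_model(q, N, N0, d_f, d)
        assert model == pytest.approx(d / sp.eigenvalues[q - 1], rel=1e-12)

    def test_collapses_when_gamma_equals_chi(self):
        N, N0 = 300, 20.0
        q = np.arange(1, N // 2 + 1)
        model = theory.mode_amplitude_model(q, N, N0, 1.5, 3)
        from fractalknots.beta_model import build_spectrum

        sp = build_spectrum(N, 1.5, 3)
        assert model == pytest.approx(3 / sp.eigenvalues[q - 1], rel=1e-12)


class TestMuOde:
    def test_frozen_coefficients_match_closed_form(self):
        c2, c3 = theory.representative_constants()
        f1 = c2
        f2 = -c2 * c3
        grid = np.linspace(1.8, 5.0, 40)
        mu0 = 5.0
        c1 = (mu0 - c3) / math.exp(c2 * grid[0])
        numeric = theory.solve_mu_ode(grid, (grid[0], mu0), frozen=(f1, f2))
        closed = theory.mu_closed_form(grid, c1, c2, c3)
        assert np.max(np.abs(numeric - closed) / np.abs(closed)) < 1e-6

    @pytest.mark.parametrize("mu0", [3.0, 5.0, 8.0])
    def test_solution_decreases(self, mu0):
        grid = np.linspace(1.8, 5.0, 30)
        mu = theory.solve_mu_ode(grid, (grid[0], mu0))
        assert np.all(np.diff(mu) < 0)

    def test_closed_form_properties(self):
        # strictly decreasing for c2 < 0, c1 > 0; limit is c3
        x = np.linspace(1.2, 10, 200)
        mu = theory.mu_closed_form(x, 16.9, -1.138, 3.703)
        assert np.all(np.diff(mu) < 0)
        assert theory.mu_closed_form(1e6, 16.9, -1.138, 3.703) == pytest.approx(3.703)

    def test_closed_form_solves_frozen_ode(self):
        # d mu / d d_f == c2 (mu - c3) for the double-exponential form
        c1, c2, c3 = 12.0, -0.9, 3.5
        x = 2.7
        h = 1e-6
        dmu = (
            theory.mu_closed_form(x + h, c1, c2, c3)
            - theory.mu_closed_form(x - h, c1, c2, c3)
        ) / (2 * h)
        mu = theory.mu_closed_form(x, c1, c2, c3)
        assert dmu == pytest.approx(c2 * (mu - c3), rel=1e-6)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            theory.solve_mu_ode([3.0, 2.0], (2.0, 5.0))
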