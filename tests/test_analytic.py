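"""Recursion engine: selection operator, moment closure, breeder's equation."""

import math

import numpy as np
import pytest
from scipy import integrate

from matevolve import (EnvParams, EnvironmentProcess, ModelParams, TraitState,
                       delta_m_initial, equilibrium_variance, iterate,
                       iterate_ensemble, mean_fitness, mean_phenotype,
                       phenotypic_variance_step, select, trait_update,
                       variance_fixed_point)
from matevolve.analytic import _develop_moments, _mean_fitness_values
from matevolve.errors import DivergenceError, ParameterError


def _state(**kw):
    defaults = dict(a_bar=0.0, b_bar=0.0, m_bar=0.0, z_bar_star=0.0,
                    sigma_z2_star=1.0, cov_a_zstar=0.0, cov_b_zstar=0.0,
                    cov_m_zstar=0.0)
    defaults.update(kw)
    return TraitState(**defaults)


class TestMeanPhenotype:
    @pytest.mark.parametrize("a,b,m,cue,zstar,expected", [
        (1.5, 0.0, 0.0, 3.7, 0.0, 1.5),
        (0.0, 2.0, 0.0, 3.0, 5.0, 6.0),
        (0.1, 0.5, -0.2, 1.0, 2.0, 0.2),
    ])
    def test_linear_reaction_norm_with_maternal_input(self, a, b, m, cue,
                                                      zstar, expected):
        st = _state(a_bar=a, b_bar=b, m_bar=m, z_bar_star=zstar)
        assert mean_phenotype(st, cue) == pytest.approx(expected)


class TestSelect:
    def test_no_shift_at_optimum(self):
        z_star, _ = select(3.0, 2.0, 3.0, 40.0)
        assert z_star == pytest.approx(3.0)

    def test_vanishing_selection_limit(self):
        z_star, v_star = select(1.0, 2.0, 10.0, 1e12)
        assert z_star == pytest.approx(1.0, abs=1e-9)
        assert v_star == pytest.approx(2.0, rel=1e-9)

    def test_printed_example(self):
        z_star, v_star = select(0.0, 2.0, 10.0, 40.0)
        assert z_star == pytest.approx(10.0 * 2.0 / 42.0)
        assert v_star == pytest.approx(80.0 / 42.0)

    def test_matches_gaussian_product_quadrature(self):
        """select() must equal the exact moments of N(z,s2) * Gaussian weight."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            zb = rng.uniform(-5, 5)
            s2 = rng.uniform(0.2, 5.0)
            th = rng.uniform(-5, 5)
            w2 = rng.uniform(0.5, 50.0)
            f = lambda z: (np.exp(-(z - zb) ** 2 / (2 * s2))
                           * np.exp(-(z - th) ** 2 / (2 * w2)))
            lo, hi = zb - 30, zb + 30
            norm = integrate.quad(f, lo, hi)[0]
            m1 = integrate.quad(lambda z: z * f(z), lo, hi)[0] / norm
            m2 = integrate.quad(lambda z: z * z * f(z), lo, hi)[0] / norm
            z_star, v_star = select(zb, s2, th, w2)
            assert abs(z_star - m1) < 1e-10
            assert abs(v_star - (m2 - m1 ** 2)) < 1e-10

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ParameterError):
            select(0.0, 0.0, 1.0, 40.0)


class TestMeanFitness:
    def test_no_selection_no_cost_limit(self):
        p = ModelParams(omega_z2=1e14, omega_b2=1e14, omega_m2=1e14)
        st = _state(m_bar=0.0)
        st.z_bar, st.sigma_z2 = 5.0, 2.0
        assert mean_fitness(st, p, 5.0) == pytest.approx(1.0, abs=1e-9)

    def test_variance_load_only(self):
        p = ModelParams(G_bb=0.0, G_mm=0.0)
        st = _state()
        st.z_bar, st.sigma_z2 = 10.0, 2.5
        expected = math.sqrt(p.omega_z2 / (p.omega_z2 + 2.5))
        assert mean_fitness(st, p, 10.0) == pytest.approx(expected)

    def test_profile_peaks_at_negative_m(self, base_model):
        """At matched equilibrium (z at the optimum, no costs), mean fitness
        is maximized at a negative maternal-effect coefficient."""
        p = base_model.replace(omega_b2=1e12, omega_m2=1e12)
        ms = np.linspace(-0.9, 0.9, 181)
        z, eps = 10.0, 5.0
        w = [_mean_fitness_values(z, equilibrium_variance(m, z, eps, p),
                                  0.0, 0.0, p, z) for m in ms]
        assert ms[int(np.argmax(w))] < 0


class TestVarianceRecursion:
    def test_no_maternal_terms_fixed_point(self, base_model):
        p = base_model.replace(G_mm=0.0)
        eps = 3.0
        st = _state(sigma_z2_star=1.0)
        s2 = phenotypic_variance_step(st, p, eps)
        assert s2 == pytest.approx(p.G_aa + p.G_bb * eps ** 2 + p.sigma_e2)

    def test_no_genetics_gives_residual_variance(self):
        p = ModelParams(G_aa=0.0, G_bb=0.0, G_mm=0.0, sigma_e2=1.0)
        assert phenotypic_variance_step(_state(), p, 2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("m,rtol", [(0.0, 1e-2), (-0.2, 1e-2),
                                        (-0.5, 1e-2), (0.3, 3e-2)])
    def test_fixed_point_matches_closed_form(self, base_model, m, rtol):
        """Iterated moment recursion vs the weak-selection equilibrium
        formula: agreement to the approximation order (1% for the negative
        coefficients the model evolves toward; the formula neglects the
        within-generation selection of transmitted variance, which grows
        with positive m, hence the looser band there)."""
        fp = variance_fixed_point(m, 10.0, 5.0, base_model)
        eq = equilibrium_variance(m, 10.0, 5.0, base_model)
        assert fp == pytest.approx(eq, rel=rtol)

    def test_equilibrium_variance_trivial_cases(self):
        p = ModelParams(G_aa=0.0, G_bb=0.0, G_mm=0.0, sigma_e2=1.0)
        assert equilibrium_variance(0.0, 0.0, 0.0, p) == pytest.approx(1.0)
        p2 = ModelParams(G_mm=0.0)
        assert equilibrium_variance(0.0, 7.0, 2.0, p2) == pytest.approx(
            p2.G_aa + p2.G_bb * 4.0 + p2.sigma_e2)

    def test_stability_guard(self, base_model):
        with pytest.raises(DivergenceError):
            phenotypic_variance_step(_state(m_bar=0.96), base_model, 0.0)


class TestTraitUpdate:
    def test_no_genetic_variance_no_response(self):
        p = ModelParams(G_aa=0.0, G_bb=0.0, G_mm=0.0)
        st = _state(a_bar=1.0, b_bar=0.5, m_bar=-0.3, z_bar_star=2.0)
        assert trait_update(st, p, theta=5.0, cue=1.0) == (0.0, 0.0, 0.0)

    def test_cost_driven_decay_of_plasticity(self, base_model):
        # at the optimum with no variance gradient in b, only the cost acts
        st = _state(a_bar=1.0, b_bar=0.5)
        st_z = mean_phenotype(st, 0.0)
        da, db, dm = trait_update(st, base_model, theta=st_z, cue=0.0)
        assert da == pytest.approx(0.0, abs=1e-15)
        expected = -base_model.G_bb * 0.5 / (base_model.omega_b2
                                             + base_model.G_bb)
        assert db == pytest.approx(expected)
        assert db < 0

    def test_matches_finite_difference_gradient(self, base_model):
        """Each response must equal G times the central-difference gradient
        of log mean fitness on the one-generation maps (rel err < 1e-4)."""
        rng = np.random.default_rng(42)
        p = base_model
        for _ in range(25):
            st = _state(a_bar=rng.uniform(-2, 2), b_bar=rng.uniform(-1, 1),
                        m_bar=rng.uniform(-0.7, 0.7),
                        z_bar_star=rng.uniform(-5, 10),
                        sigma_z2_star=rng.uniform(0.5, 4.0),
                        cov_a_zstar=rng.uniform(-0.1, 0.1),
                        cov_b_zstar=rng.uniform(-0.1, 0.1),
                        cov_m_zstar=rng.uniform(-0.05, 0.05))
            cue = rng.uniform(-3, 6)
            theta = rng.uniform(-5, 12)
            deltas = trait_update(st, p, theta, cue)

            def lnW(a, b, m):
                z, s2, *_ = _develop_moments(
                    p, a, b, m, st.z_bar_star, st.sigma_z2_star,
                    st.cov_a_zstar, st.cov_b_zstar, st.cov_m_zstar, cue)
                return np.log(_mean_fitness_values(z, s2, b, m, p, theta))

            h = 1e-6
            x0 = (st.a_bar, st.b_bar, st.m_bar)
            G = (p.G_aa, p.G_bb, p.G_mm)
            for i in range(3):
                hi = [x0[0], x0[1], x0[2]]
                lo = [x0[0], x0[1], x0[2]]
                hi[i] += h
                lo[i] -= h
                fd = G[i] * (lnW(*hi) - lnW(*lo)) / (2 * h)
                assert deltas[i] == pytest.approx(
                    fd, rel=1e-4, abs=1e-12), f"component {i}"

    def test_novel_maternal_effect_selected_negative(self, base_model):
        """At a stationary optimum with plasticity absent, a rare maternal
        effect experiences negative selection."""
        p = base_model.replace(G_bb=0.0)
        z = 10.0
        # quasi-equilibrium parent-offspring covariances at m = 0
        st = _state(a_bar=z, m_bar=0.0, z_bar_star=z,
                    sigma_z2_star=equilibrium_variance(0.0, z, 0.0, p),
                    cov_a_zstar=p.G_aa / 2.0, cov_m_zstar=p.G_mm * z / 2.0)
        _, _, dm = trait_update(st, p, theta=z, cue=0.0)
        assert dm < 0


class TestDeltaMInitial:
    def test_always_negative_over_valid_parameters(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            val = delta_m_initial(z_bar=rng.uniform(-20, 20),
                                  G_aa=rng.uniform(0, 1),
                                  G_mm=rng.uniform(1e-4, 0.99),
                                  omega_z2=rng.uniform(0.5, 100),
                                  sigma_e2=rng.uniform(0.1, 2))
            assert val < 0

    def test_vanishing_variance_limit(self):
        assert delta_m_initial(10.0, 0.1, 1e-12, 40.0) == pytest.approx(
            0.0, abs=1e-10)

    @pytest.mark.parametrize("G_mm", [0.0, 1.0, 1.2])
    def test_invalid_G_mm_rejected(self, G_mm):
        with pytest.raises(ParameterError):
            delta_m_initial(10.0, 0.1, G_mm, 40.0)

    def test_matches_equilibrium_manifold_gradient(self):
        """Closed form vs central differences of log mean fitness along the
        constant-environment equilibrium manifold (rel err < 1e-3)."""
        G_aa, G_mm, w2, zbar, se2 = 0.1, 0.005, 40.0, 10.0, 1.0
        p = ModelParams(G_aa=G_aa, G_bb=0.0, G_mm=G_mm, omega_z2=w2,
                        sigma_e2=se2, omega_m2=1e12)

        def lnW(m):
            z = zbar / (1.0 - m)  # mean responds as a/(1-m), a fixed
            s2 = equilibrium_variance(m, z, 0.0, p)
            return np.log(_mean_fitness_values(z, s2, 0.0, 0.0, p, zbar))

        h = 1e-6
        fd = G_mm * (lnW(h) - lnW(-h)) / (2 * h)
        assert delta_m_initial(zbar, G_aa, G_mm, w2, se2) == pytest.approx(
            fd, rel=1e-3)


class TestIterate:
    def test_constant_environment_evolves_negative_m(self, base_model):
        env = EnvironmentProcess(
            EnvParams(scenario="constant", epsilon_const=5.0, sigma_xi2=0.0,
                      tau=0.25), 30_000, seed=1)
        traj = iterate(base_model, env, n_generations=30_000)
        assert traj["m_bar"].iloc[-1] < 0
        # the mean phenotype tracks the optimum theta = 10
        assert traj["z_bar"].iloc[-1] == pytest.approx(10.0, abs=0.1)

    def test_deterministic_given_seed(self, base_model, step_env):
        runs = [iterate(base_model,
                        EnvironmentProcess(step_env, 500, seed=11),
                        n_generations=500) for _ in range(2)]
        assert runs[0].frame.equals(runs[1].frame)

    def test_lande_limit_geometric_convergence(self):
        """With plasticity and maternal effects off and constant variance,
        the elevation approaches the shifted optimum geometrically at rate
        1 - G_aa/(omega_z^2 + sigma_z^2)."""
        p = ModelParams(G_bb=0.0, G_mm=0.0)
        env_p = EnvParams(scenario="step", delta=10.0, t_switch=0,
                          sigma_xi2=0.0, tau=0.0)
        env = EnvironmentProcess(env_p, 300, seed=0)
        a0 = 0.0
        traj = iterate(p, env, TraitState.founder(p, a_bar=a0, b_bar=0.0,
                                                  m_bar=0.0),
                       n_generations=300)
        theta = 20.0
        s2 = p.G_aa + p.sigma_e2
        ratio = 1.0 - p.G_aa / (p.omega_z2 + s2)
        a = traj["a_bar"].to_numpy()
        expected = theta + (a0 - theta) * ratio ** np.arange(300)
        np.testing.assert_allclose(a, expected, atol=1e-10)

    def test_divergence_guard_reports_generation(self, base_model, step_env):
        env = EnvironmentProcess(step_env, 100, seed=0)
        bad = TraitState.founder(base_model, m_bar=0.96)
        with pytest.raises(DivergenceError) as err:
            iterate(base_model, env, bad, n_generations=100)
        assert err.value.generation == 0

    @pytest.mark.parametrize("f,sign", [(0.5, 1), (3.0, -1)])
    def test_sign_law_under_strong_selection(self, f, sign):
        """Without plasticity, strong selection drives the steady-cycle
        maternal effect positive under slow forcing and negative under fast
        forcing, following the between-generation autocorrelation."""
        p = ModelParams(omega_z2=0.7, G_bb=0.0, G_mm=0.045)
        env = EnvironmentProcess(
            EnvParams(scenario="sinusoid", f=f, sigma_xi2=0.01, rho=0.5,
                      tau=0.25), 20_000, seed=2)
        traj = iterate(p, env, TraitState.founder(p, b_bar=0.0),
                       n_generations=20_000)
        m = traj["m_bar"].to_numpy()
        window = int(10 * 2 * np.pi / f)
        steady = m[-window:].mean()
        assert sign * steady > 0.3

    def test_initial_conditions_converge(self, base_model):
        """Different starting trait means reach the same constant-environment
        attractor (vectorized ensemble run)."""
        env = EnvironmentProcess(
            EnvParams(scenario="constant", epsilon_const=0.0, sigma_xi2=0.0,
                      tau=0.25), 60_000, seed=1)
        inits = [TraitState.founder(base_model, a_bar=a, b_bar=b, m_bar=m)
                 for a in (-1, 1e-4, 1) for b in (-1, 1e-4, 1)
                 for m in (-0.5, 1e-4, 0.5)]
        fin = iterate_ensemble(base_model, env, inits, 60_000)
        for key in ("a", "b", "m"):
            assert np.ptp(fin[key]) < 1e-4
        assert fin["m"].mean() < 0
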