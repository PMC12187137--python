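"""Integrator properties: conservation, symmetry, energy decay, division."""

from dataclasses import replace

import numpy as np
import pytest

from polyseg import (FieldState, GridSpec, GrowthSpec, KineticParams,
                     ModelConfig, Stepper, divide, reaction_terms,
                     relax_to_steady_state, simulate_generation,
                     simulate_multispecies, spread_nucleoid_state,
                     compact_nucleoid_state)
from polyseg.energy import chemical_potentials, mobilities, total_free_energy
from polyseg.fields import div_flux, grid_centers, integrate


def explicit_reference_step(state, config, dt):
    """Fully explicit Euler step — the independent one-step oracle."""
    mu_p, mu_n = chemical_potentials(state, config.fh)
    m_p, m_n = mobilities(state, config.kinetics, config.fh)
    h = 1.0 / state.N
    dp_rx, dn_rx = reaction_terms(state, config)
    p_new = state.p + dt * (div_flux(m_p, mu_p, h) + dp_rx)
    n_new = state.n + dt * (div_flux(m_n, mu_n, h) + dn_rx)
    gamma = config.growth.gamma_per_s
    return FieldState(p=p_new, n=n_new, L=state.L * np.exp(gamma * dt),
                      t=state.t + dt)


def smooth_state(N, L=2.2):
    x = grid_centers(N)
    p = 0.2 + 0.03 * np.cos(2 * np.pi * x)
    n = 0.3 + 0.05 * np.cos(np.pi * x) ** 2
    return FieldState(p=p, n=n, L=L)


class TestStep:
    def test_conserves_mass_without_reactions(self, small_config):
        cfg = replace(small_config,
                      kinetics=KineticParams(k1_0=0.0, k_deg=1e-12))
        state = smooth_state(32)
        st = Stepper(cfg)
        m_n0, m_p0 = integrate(state.n), integrate(state.p)
        for _ in range(20):
            state = st.advance(state)
        assert integrate(state.n) == pytest.approx(m_n0, rel=1e-10)
        assert integrate(state.p) == pytest.approx(m_p0, rel=1e-10)

    def test_mirror_symmetric_state_stays_symmetric(self, small_config):
        state = spread_nucleoid_state(small_config)
        st = Stepper(small_config)
        for _ in range(200):
            state = st.advance(state)
        assert np.max(np.abs(state.n - state.n[::-1])) <= 1e-10
        assert np.max(np.abs(state.p - state.p[::-1])) <= 1e-10

    def test_one_step_matches_tiny_dt_explicit_oracle(self, small_config):
        """The IMEX step converges to a dt/100 explicit reference at O(dt)."""
        state = smooth_state(32)
        dt = 0.02
        got = Stepper(small_config, dt=dt).advance(state)
        ref = state.copy()
        for _ in range(100):
            ref = explicit_reference_step(ref, small_config, dt / 100)
        scale = dt * np.max(np.abs(got.p - state.p)) / dt  # one-step change
        err = max(np.max(np.abs(got.p - ref.p)), np.max(np.abs(got.n - ref.n)))
        change = max(np.max(np.abs(ref.p - state.p)),
                     np.max(np.abs(ref.n - state.n)))
        assert err < 0.2 * change  # first-order agreement on one step

    def test_free_energy_nonincreasing_without_reactions(self, small_config):
        cfg = replace(small_config,
                      kinetics=KineticParams(k1_0=0.0, k_deg=1e-12))
        state = smooth_state(32)
        st = Stepper(cfg)
        F = total_free_energy(state, cfg.fh)
        for _ in range(400):
            state = st.advance(state)
            F_new = total_free_energy(state, cfg.fh)
            assert F_new <= F + 1e-8
            F = F_new

    def test_growth_updates_length_exponentially(self):
        cfg = ModelConfig(grid=GridSpec(N=32, dt=0.05),
                          growth=GrowthSpec(gamma=0.57, L0=2.2))
        state = smooth_state(32)
        st = Stepper(cfg)
        for _ in range(10):
            state = st.advance(state)
        assert state.L == pytest.approx(
            2.2 * np.exp(cfg.growth.gamma_per_s * 0.5), rel=1e-12)


class TestReactionTerms:
    def test_production_degradation_balance(self, small_config):
        n0 = 0.3
        k1 = small_config.k1
        p_bal = k1 / small_config.kinetics.k_deg * n0
        state = FieldState(p=np.full(32, p_bal), n=np.full(32, n0), L=2.2)
        dp, dn = reaction_terms(state, small_config)
        assert dp == pytest.approx(np.zeros(32), abs=1e-15)
        assert np.all(dn == 0)

    def test_growth_compensated_production_rate(self):
        """k1 = k1_0 (1 + γ/k_-1) with γ converted from h⁻¹ to s⁻¹."""
        cfg = ModelConfig(growth=GrowthSpec(gamma=0.57))
        expected = 0.002 * (1.0 + 0.57 / (0.003 * 3600.0))
        assert cfg.k1 == pytest.approx(expected, rel=1e-12)

    def test_polar_source_confined_to_window(self):
        from polyseg.params import EctopicSource
        cfg = ModelConfig(grid=GridSpec(N=64),
                          growth=GrowthSpec(gamma=0.57, L0=2.4),
                          source=EctopicSource(kind="polar", amplitude=0.8,
                                               extent=0.8, k1_reduction=0.5))
        state = FieldState(p=np.full(64, 0.2), n=np.full(64, 0.3), L=2.4)
        dp, _ = reaction_terms(state, cfg)
        x_um = grid_centers(64) * 2.4
        inside = x_um < 0.8
        base = 0.5 * cfg.k1 * 0.3 - (0.003 + cfg.growth.gamma_per_s) * 0.2
        assert dp[~inside] == pytest.approx(np.full((~inside).sum(), base))
        assert dp[inside] == pytest.approx(
            np.full(inside.sum(), base + 0.8 * cfg.k1))


class TestRelaxation:
    def test_steady_state_balance_and_fixed_point(self, small_config):
        state, t = relax_to_steady_state(
            small_config, compact_nucleoid_state(small_config), tol=1e-9)
        k1 = small_config.k1
        k_deg = small_config.kinetics.k_deg
        assert k1 * integrate(state.n) == pytest.approx(
            k_deg * integrate(state.p), rel=1e-3)
        # restarting at the steady state returns almost immediately
        _, t2 = relax_to_steady_state(small_config, state, tol=1e-8)
        assert t2 <= 1.0

    def test_nonconvergence_raises(self, small_config):
        from polyseg import ConvergenceError
        with pytest.raises(ConvergenceError):
            relax_to_steady_state(small_config,
                                  compact_nucleoid_state(small_config),
                                  tol=1e-16, max_time=5.0)


class TestGeneration:
    @pytest.fixture(scope="class")
    def slow_generation(self):
        cfg = ModelConfig(grid=GridSpec(N=64, dt=0.05, sample_stride=400),
                          growth=GrowthSpec(gamma=1.2))
        init, _ = relax_to_steady_state(
            cfg, compact_nucleoid_state(cfg), tol=1e-7)
        init.t = 0.0
        return cfg, simulate_generation(cfg, init)

    def test_runs_to_doubled_length(self, slow_generation):
        cfg, traj = slow_generation
        assert traj.final_state.L == pytest.approx(2 * cfg.growth.L0, rel=1e-4)

    def test_nucleoid_amount_conserved_along_trajectory(self, slow_generation):
        _, traj = slow_generation
        masses = traj.n.mean(axis=1)
        assert np.max(np.abs(masses - masses[0]) / masses[0]) < 1e-6

    def test_divide_halves_integrals_and_length(self, slow_generation):
        cfg, traj = slow_generation
        mother = traj.final_state
        daughter, new_pole = divide(mother, cfg)
        assert new_pole == "right"
        assert daughter.L == pytest.approx(mother.L / 2)
        assert integrate(daughter.n) == pytest.approx(
            2 * integrate(mother.n[:32]) / 2, rel=1e-6)

    def test_divide_mirror_symmetric_mother_gives_identical_daughters(
            self, small_config):
        state = spread_nucleoid_state(small_config)
        d1, _ = divide(state, small_config, daughter="old_pole")
        d2, _ = divide(state, small_config, daughter="new_pole")
        assert d1.p == pytest.approx(d2.p, rel=1e-9)
        assert d1.n == pytest.approx(d2.n, rel=1e-9)


class TestMultiSpecies:
    def _config(self, Ds):
        return ModelConfig(grid=GridSpec(N=32, dt=0.05, sample_stride=100),
                           growth=GrowthSpec(gamma=1.2),
                           D_p_species=Ds)

    def test_identical_species_remain_proportional(self):
        cfg = self._config([0.023, 0.023, 0.023])
        init = spread_nucleoid_state(cfg)
        traj = simulate_multispecies(cfg, init, L_stop_factor=1.2)
        sp = traj.species[-1]
        for k in range(3):
            assert sp[k] == pytest.approx(traj.p[-1] / 3, rel=1e-8)

    def test_distinct_diffusivities_share_concentration_profile(self):
        """Species with different D have essentially the same normalized
        distribution (the physical picture is insensitive to polydispersity)."""
        cfg = self._config([0.018, 0.023, 0.028])
        init = spread_nucleoid_state(cfg)
        traj = simulate_multispecies(cfg, init)
        sp = traj.species[-1]
        norm = [s / s.mean() for s in sp]
        peak = np.max(norm[0])
        for k in range(1, 3):
            assert np.max(np.abs(norm[k] - norm[0])) / peak < 0.1

    def test_species_sum_matches_mean_diffusivity_run(self):
        cfg = self._config([0.018, 0.028])
        init = spread_nucleoid_state(cfg)
        traj = simulate_multispecies(cfg, init, L_stop_factor=1.1)
        cfg1 = replace(self._config(None),
                       kinetics=replace(cfg.kinetics, D_p=0.023))
        traj1 = simulate_generation(cfg1, init)
        # compare at the multispecies run's final length
        i1 = int(np.argmin(np.abs(traj1.lengths - traj.lengths[-1])))
        assert traj.p[-1] == pytest.approx(traj1.p[i1], abs=0.02)
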