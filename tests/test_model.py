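"""Three-pool model: process rates, stepping, integration and sampling."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from dielflux import ExperimentDesign, IrradianceProfile, ModelParameters, irradiance
from dielflux.model import (SimConfig, canonical_variant,
                            comparison_sample_times, production, release,
                            sample_trajectory, simulate, simulate_batch, step,
                            uptake)


class TestIrradiance:
    def test_peak_at_noon_and_dark_at_midnight(self):
        assert irradiance(12.0) == pytest.approx(150.0)
        assert irradiance(0.0) == 0.0
        assert irradiance(20.5) == 0.0  # after dusk (16-h photoperiod)

    def test_half_cosine_value_mid_morning(self):
        # 150 cos(pi * 6 / 16) at 06:00
        assert irradiance(6.0) == pytest.approx(150 * math.cos(6 * math.pi / 16))
        assert irradiance(6.0) == pytest.approx(57.402, abs=1e-3)

    def test_periodic_and_continuous_at_dawn(self):
        t = np.linspace(0, 48, 481)
        vals = irradiance(t)
        assert np.allclose(vals[:241], vals[240:], atol=1e-9)
        assert irradiance(4.0) == pytest.approx(0.0, abs=1e-9)  # dawn edge

    def test_constant_shape(self):
        prof = IrradianceProfile(shape="constant", peak_intensity=42.0)
        assert irradiance(3.0, prof) == 42.0

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            IrradianceProfile(photoperiod=25.0)
        with pytest.raises(ValueError):
            IrradianceProfile(peak_intensity=-1.0)


class TestProcessRates:
    def test_production_reduces_to_base_when_neutral(self):
        p = ModelParameters(o_decay=0.0, b_factor=1.0)
        for t in (3.0, 9.0, 15.0, 21.0):
            assert production(t, p, "ohb", post_inoculation=True) == \
                production(t, p, "base")

    def test_production_o_attenuates_after_peak(self):
        p = ModelParameters(o_decay=0.1)
        base = production(18.0, p, "base")
        assert production(18.0, p, "o") == pytest.approx(base * math.exp(-0.6))
        # pre-noon untouched
        assert production(9.0, p, "o") == production(9.0, p, "base")

    def test_production_b_multiplies_only_post_inoculation(self):
        p = ModelParameters(b_factor=2.0)
        assert production(12.0, p, "b", post_inoculation=True) == \
            pytest.approx(2 * production(12.0, p, "base"))
        assert production(12.0, p, "b", post_inoculation=False) == \
            production(12.0, p, "base")

    def test_release_gradient_and_homeostatic_term(self):
        p = ModelParameters(r_diff=0.3, h_coef=0.5)
        assert release(2.0, 2.0, 4.0, p, "base") == 0.0
        assert release(2.0, 1.0, 4.0, p, "h") == pytest.approx(0.3 + 2.0)
        assert release(2.0, 1.0, 4.0, ModelParameters(r_diff=0.3, h_coef=0.0), "h") == \
            pytest.approx(0.3)
        # back-diffusion allowed
        assert release(1.0, 2.0, 0.0, p, "base") < 0

    def test_uptake_michaelis_menten(self):
        p = ModelParameters(u_vmax=2.0, u_km=1.5)
        assert uptake(0.0, p) == 0.0
        assert uptake(1.5, p) == pytest.approx(1.0)  # half saturation
        assert uptake(1.5e6 * 1.0, p) == pytest.approx(2.0, rel=1e-5)  # asymptote
        assert uptake(10.0, p, post_inoculation=False) == 0.0
        E = np.linspace(0, 10, 50)
        assert np.all(np.diff(uptake(E, p)) >= 0)
        assert np.all(uptake(E, p) < p.u_vmax)


class TestStep:
    def test_all_rates_zero_leaves_state_unchanged(self):
        p = ModelParameters(n_scale=0.0, t_frac=0.0, r_diff=0.0, u_vmax=0.0,
                            c_frac=0.0)
        state, fluxes, clamped = step((1.0, 2.0, 3.0), 12.0, p)
        assert state == (1.0, 2.0, 3.0)
        assert not clamped

    def test_euler_accumulation_of_constant_production(self):
        # N = 1 via constant irradiance; all sinks off
        prof = IrradianceProfile(shape="constant", peak_intensity=50.0)
        p = ModelParameters(n_scale=0.02, t_frac=0.0, r_diff=0.0, u_vmax=0.0,
                            c_frac=0.0)
        state = (0.0, 0.0, 0.0)
        for i in range(10):
            state, _, _ = step(state, i * 0.1, p, dt=0.1, profile=prof)
        assert state[0] == pytest.approx(1.0, rel=1e-12)

    def test_single_step_mass_balance_identity(self, rng):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=1.0, c_frac=0.3)
        state = tuple(rng.uniform(0.5, 5.0, 3))
        new, fl, clamped = step(state, 10.0, p, dt=0.1)
        assert not clamped
        expected = sum(state) + (fl["N"] - fl["T"] - fl["C"]) * 0.1
        assert sum(new) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_state_aborts(self):
        with pytest.raises(FloatingPointError):
            step((math.nan, 0.0, 0.0), 0.0, ModelParameters())

    def test_negative_pool_clamped_and_reported(self):
        p = ModelParameters(u_vmax=100.0, u_km=0.01, r_diff=0.0)
        (_, E2, _), _, clamped = step((0.0, 0.1, 0.0), 12.0, p, dt=0.1)
        assert E2 == 0.0
        assert "E" in clamped


class TestSimulate:
    def test_default_grid_has_2400_intervals(self):
        traj = simulate(ModelParameters())
        assert traj.n_intervals == 2400
        assert traj.time[-1] == pytest.approx(240.0)

    def test_uptake_zero_through_axenic_phase(self):
        traj = simulate(ModelParameters(u_vmax=5.0))
        axenic = traj.time < 144.0
        assert np.all(traj.U[axenic] == 0.0)
        assert np.any(traj.U[~axenic] > 0.0)

    def test_no_uptake_keeps_bacterial_pool_empty(self):
        traj = simulate(ModelParameters(u_vmax=0.0))
        assert np.all(traj.B == 0.0)

    def test_conservation_without_allocation_or_catabolism(self):
        p = ModelParameters(t_frac=0.0, c_frac=0.0)
        traj = simulate(p)
        assert not traj.clamp_events
        injected = np.sum(traj.N[:-1]) * 0.1
        total = traj.P[-1] + traj.E[-1] + traj.B[-1]
        assert total == pytest.approx(injected, rel=1e-9)

    def test_neutral_active_terms_reduce_to_base_bitwise(self):
        base = simulate(ModelParameters())
        p = ModelParameters(o_decay=0.0, h_coef=0.0, b_factor=1.0)
        for variant in ("o", "h", "b", "oh", "ob", "hb", "ohb"):
            traj = simulate(p, variant)
            for field in "PEBNTRUC":
                assert np.array_equal(getattr(traj, field), getattr(base, field))

    def test_constant_light_reaches_algebraic_fixed_point(self):
        # axenic steady state: E* = P*, N = t_frac P* (+ r_diff (P*-E*) = 0)
        prof = IrradianceProfile(shape="constant", peak_intensity=150.0)
        p = ModelParameters(n_scale=0.02, t_frac=0.2, r_diff=0.3, u_vmax=0.0)
        cfg = SimConfig(duration_days=60.0, axenic_days=59.0)
        traj = simulate(p, "base", cfg, prof)
        N = p.n_scale * 150.0

        def rhs(x):
            P, E = x
            R = p.r_diff * (P - E)
            return [N - p.t_frac * P - R, R]

        P_star, E_star = fsolve(rhs, [1.0, 1.0])
        assert N == pytest.approx(p.t_frac * P_star + p.r_diff * (P_star - E_star))
        assert traj.P[-1] == pytest.approx(P_star, rel=1e-3)
        assert traj.E[-1] == pytest.approx(E_star, rel=1e-3)

    def test_halving_dt_changes_samples_under_one_percent(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.1, u_vmax=1.0, u_km=1.0)
        coarse = simulate(p, "base", SimConfig(dt=0.1))
        fine = simulate(p, "base", SimConfig(dt=0.05))
        Pc, Uc = sample_trajectory(coarse, design, SimConfig(dt=0.1))
        Pf, Uf = sample_trajectory(fine, design, SimConfig(dt=0.05))
        assert np.allclose(Pc, Pf, rtol=0.01)
        assert np.allclose(Uc, Uf, rtol=0.01)


class TestSampling:
    def test_nine_samples_on_final_two_days(self, design, sim_config):
        traj = simulate(ModelParameters())
        P, U = sample_trajectory(traj, design, sim_config)
        assert len(P) == len(U) == 9
        idx = np.round(comparison_sample_times(design, sim_config) / 0.1).astype(int)
        assert np.array_equal(P, traj.P[idx])

    def test_window_must_fit_comparison_period(self, sim_config):
        wide = ExperimentDesign(n_timepoints=11, sampling_interval=6.0, window=60.0)
        traj = simulate(ModelParameters())
        with pytest.raises(ValueError):
            sample_trajectory(traj, wide, sim_config)

    def test_batch_integrator_matches_scalar_runs(self, design, sim_config):
        params = [ModelParameters(t_frac=0.05, r_diff=0.2, u_vmax=1.0),
                  ModelParameters(t_frac=0.3, r_diff=0.05, u_vmax=3.0, u_km=0.2),
                  ModelParameters(o_decay=0.2, h_coef=0.7, b_factor=2.0)]
        fields = (*ModelParameters.BASE_FIELDS, "o_decay", "h_coef", "b_factor")
        arrays = {f: np.array([getattr(p, f) for p in params]) for f in fields}
        times = comparison_sample_times(design, sim_config)
        P_s, U_s, _ = simulate_batch(arrays, "ohb", times, sim_config)
        for i, p in enumerate(params):
            traj = simulate(p, "ohb", sim_config)
            P, U = sample_trajectory(traj, design, sim_config)
            assert np.array_equal(P_s[i], P)
            assert np.array_equal(U_s[i], U)


class TestConfigValidation:
    def test_variant_canonicalisation(self):
        assert canonical_variant("") == "base"
        assert canonical_variant({"b", "o"}) == "ob"
        assert canonical_variant("ho") == "oh"
        with pytest.raises(ValueError):
            canonical_variant("x")

    def test_simconfig_invariants(self):
        with pytest.raises(ValueError):
            SimConfig(dt=-0.1)
        with pytest.raises(ValueError):
            SimConfig(axenic_days=10.0, duration_days=10.0)
        with pytest.raises(ValueError):
            SimConfig(dt=0.7)  # not an integer number of steps

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            ModelParameters(u_km=0.0)
        with pytest.raises(ValueError):
            ModelParameters(b_factor=0.0)
        with pytest.raises(ValueError):
            ModelParameters(t_frac=-0.1)
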