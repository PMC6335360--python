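"""Mossy-fiber encodings, reservoir dynamics, PC/cFN readouts."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from omvsim.cerebellum import (cfn_activity, granule_drive_function,
                               mf_burst_rate, mf_target_rate,
                               net_cerebellar_output, normalize_mf,
                               pc_population_activity, reservoir_baseline,
                               reservoir_step)
from omvsim.weights import init_weights


class TestMossyFibers:
    def test_target_rate_reaches_sustained_value_at_onset(self):
        assert mf_target_rate(0.05, t_on=0.05, y_d=10.0, lam=2.0,
                              alpha=0.015) == pytest.approx(20.0)

    def test_gaussian_buildup_one_spread_before_onset(self):
        rate = mf_target_rate(0.05 - 0.015, t_on=0.05, y_d=10.0, lam=2.0,
                              alpha=0.015)
        assert rate == pytest.approx(20.0 * math.exp(-1.0), rel=1e-12)

    def test_sustained_after_onset(self):
        assert mf_target_rate(0.2, 0.05, 10.0, 2.0, 0.015) == 20.0

    def test_hold_silences_both_channels(self):
        assert mf_target_rate(0.2, 0.05, 10.0, 2.0, 0.015,
                              hold_active=True) == 0.0
        assert mf_burst_rate(784.9, hold_active=True) == 0.0

    def test_burst_channel_is_identity(self):
        assert mf_burst_rate(784.9) == 784.9
        assert mf_burst_rate(0.0) == 0.0

    def test_normalization_brings_channels_to_unit_scale(self):
        mf = normalize_mf(40.0, 1100.0, A=1100.0, mf_target_norm=40.0)
        assert mf == pytest.approx([1.0, 1.0])


class TestReservoir:
    def test_drive_function_midpoint_and_bounds(self):
        assert granule_drive_function(0.0, f_max=1.0) == 0.5
        x = np.linspace(-20, 20, 101)
        y = granule_drive_function(x, f_max=2.0)
        assert y.min() > 0 and y.max() < 2.0
        assert granule_drive_function(0.0, f_max=2.0) == 1.0

    def test_frozen_drive_follows_leaky_integrator_closed_form(self):
        # with S held fixed, z(t) = S (1 - e^{-t/tau}) per unit
        tau, dt, steps = 0.02, 0.0001, 2000
        S = 0.7
        z = np.zeros(1)
        for _ in range(steps):
            z = z + (dt / tau) * (-z + S)  # same update, frozen S
        t = steps * dt
        assert z[0] == pytest.approx(S * (1 - math.exp(-t / tau)), rel=1e-2)

    def test_baseline_fixed_point_matches_numeric_solution(self, tiny_config,
                                                           tiny_weights):
        # oracle: solve z* = f(-rho w z*) with a generic root finder
        cfg = tiny_config
        w = tiny_weights.w_rec_contra
        z_sim = reservoir_baseline(w, cfg.tau, cfg.rho, cfg.dt, cfg.f_max)
        z_solved = fsolve(
            lambda z: granule_drive_function(-cfg.rho * (w @ z),
                                             cfg.f_max) - z,
            np.full(cfg.N, 0.5), xtol=1e-12)
        assert np.allclose(z_sim, z_solved, atol=1e-6)

    def test_zero_rho_decouples_units(self, tiny_config, tiny_weights):
        cfg = tiny_config
        mf = np.array([0.3, 0.1])
        z = np.full(cfg.N, 0.2)
        stepped = reservoir_step(z, mf, tiny_weights.w_mf_grc_contra,
                                 tiny_weights.w_rec_contra, cfg.tau,
                                 rho=0.0, dt=cfg.dt, f_max=cfg.f_max)
        # with rho = 0 the update depends on MF input only, not on w_rec
        expected = z + (cfg.dt / cfg.tau) * (
            -z + granule_drive_function(
                tiny_weights.w_mf_grc_contra @ mf, cfg.f_max))
        assert np.allclose(stepped, np.maximum(expected, 0.0))

    def test_activity_nonnegative_and_bounded(self, tiny_config,
                                              tiny_weights):
        cfg = tiny_config
        z = reservoir_baseline(tiny_weights.w_rec_contra, cfg.tau, cfg.rho,
                               cfg.dt, cfg.f_max)
        rng = np.random.default_rng(0)
        for _ in range(500):
            mf = rng.uniform(0, 1, 2)
            z = reservoir_step(z, mf, tiny_weights.w_mf_grc_contra,
                               tiny_weights.w_rec_contra, cfg.tau, cfg.rho,
                               cfg.dt, cfg.f_max)
            assert z.min() >= 0.0
            assert z.max() <= cfg.f_max + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_stability_long_run_many_structures(self, tiny_config, seed):
        # bounded activity over 10x the trial duration per random structure
        cfg = tiny_config
        w = init_weights(cfg, seed)
        z = np.zeros(cfg.N)
        steps = int(10 * cfg.trial_duration / cfg.dt)
        rng = np.random.default_rng(seed)
        for _ in range(steps):
            mf = rng.uniform(0, 1, 2)
            z = reservoir_step(z, mf, w.w_mf_grc_contra, w.w_rec_contra,
                               cfg.tau, cfg.rho, cfg.dt, cfg.f_max)
        assert np.all(np.isfinite(z))
        assert z.max() <= cfg.f_max + 1e-12

    def test_echo_property_initial_conditions_forgotten(self, tiny_config,
                                                        tiny_weights):
        # two trajectories under the same input converge after a transient
        cfg = tiny_config
        rng = np.random.default_rng(3)
        z_a = np.zeros(cfg.N)
        z_b = rng.uniform(0, 1, cfg.N)
        gap = [np.linalg.norm(z_a - z_b)]
        for _ in range(int(0.5 / cfg.dt)):
            mf = rng.uniform(0, 1, 2)
            args = (mf, tiny_weights.w_mf_grc_contra,
                    tiny_weights.w_rec_contra, cfg.tau, cfg.rho, cfg.dt,
                    cfg.f_max)
            z_a = reservoir_step(z_a, *args)
            z_b = reservoir_step(z_b, *args)
            gap.append(np.linalg.norm(z_a - z_b))
        assert gap[-1] < 1e-6 * gap[0]
        # distance shrinks monotonically after a short transient
        tail = np.asarray(gap[int(0.05 / cfg.dt):])
        assert np.all(np.diff(tail) <= 1e-12)


class TestReadouts:
    def test_pc_zero_weights(self):
        assert pc_population_activity(np.ones(5), np.zeros(5)) == 0.0

    def test_pc_unit_vector_selects_one_granule(self):
        z = np.array([0.1, 0.7, 0.3])
        e1 = np.array([0.0, 1.0, 0.0])
        assert pc_population_activity(z, e1) == pytest.approx(0.7)

    def test_pc_all_ones_sums_baseline(self):
        z = np.full(20, 0.45)
        assert pc_population_activity(z, np.ones(20)) == pytest.approx(9.0)

    def test_pc_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            pc_population_activity(np.ones(5), np.ones(4))

    def test_cfn_arithmetic(self):
        assert cfn_activity(0.0, 40.0, 20.0, 0.5) == pytest.approx(20.0)
        assert cfn_activity(1.0, 40.0, 20.0, 0.5) == pytest.approx(0.0)
        assert cfn_activity(0.5, 0.0, 20.0, 0.5) < 0  # inhibition only

    def test_net_output_symmetry_and_signs(self):
        assert net_cerebellar_output(37.0, 37.0, 0.02, -0.02) == 0.0
        assert net_cerebellar_output(100.0, 0.0, 0.02, -0.02) == \
            pytest.approx(2.0)
        assert net_cerebellar_output(0.0, 100.0, 0.02, -0.02) == \
            pytest.approx(-2.0)


class TestBilateralOrganization:
    def test_bilateral_granule_populations_track_each_other(self, tiny):
        # both sides receive the same MF channels; their population-rate
        # time courses should be strongly correlated despite independent
        # random structure
        from omvsim.simulation import simulate_trial
        cfg, w = tiny
        rec = simulate_trial(cfg, w, 15.0)
        pop_c = rec.z_contra.mean(axis=1)
        pop_i = rec.z_ipsi.mean(axis=1)
        r = np.corrcoef(pop_c, pop_i)[0, 1]
        assert r > 0.8

    def test_shared_reservoir_trains_comparably(self, tiny):
        # one shared granule layer with independent readouts reaches an
        # endpoint accuracy comparable to the bilateral configuration
        import dataclasses
        from omvsim.adaptation import train
        cfg, w = tiny
        kwargs = dict(seed=5, explore_epochs=2, inner_iters=5,
                      polish_targets=6, polish_blocks=3,
                      polish_block_iters=4)
        bilateral = train(cfg, w, **kwargs)
        shared = dataclasses.replace(
            w, w_rec_ipsi=w.w_rec_contra.copy(),
            w_mf_grc_ipsi=w.w_mf_grc_contra.copy())
        shared_res = train(cfg, shared, **kwargs)
        err = lambda r: np.mean(np.abs(list(r.per_target_error.values())))
        assert err(shared_res) < max(3.0 * err(bilateral), 1.0)
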