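"""Closed-loop trial simulation: determinism, hold behavior, overshoot."""

import numpy as np
import pytest

from omvsim.simulation import SimulationEngine, simulate_trial


@pytest.fixture(scope="module")
def engine(tiny):
    return SimulationEngine(*tiny)


class TestTrialStructure:
    def test_all_series_share_grid_length(self, tiny, engine):
        cfg, w = tiny
        rec = simulate_trial(cfg, w, 12.0, engine=engine)
        n = cfg.n_steps + 1
        assert rec.n_samples == n
        for name in ("u", "theta", "theta_dot", "mf_target", "mf_burst",
                     "y_pc_contra", "ycfn_ipsi", "y_c", "D"):
            assert getattr(rec, name).shape == (n,)
        assert rec.z_contra.shape == (n, cfg.N)

    def test_burst_bounded_and_nonnegative(self, tiny, engine):
        cfg, w = tiny
        rec = simulate_trial(cfg, w, 18.0, engine=engine)
        assert rec.u.min() >= 0.0
        assert rec.u.max() < cfg.A

    def test_post_hold_silence_and_constant_position(self, tiny, engine):
        cfg, w = tiny
        rec = simulate_trial(cfg, w, 15.0, engine=engine)
        held = rec.time >= rec.hold_time + cfg.dt / 2
        assert held.any()
        assert not rec.u[held].any()
        assert not rec.mf_target[held].any()
        assert not rec.mf_burst[held].any()
        assert np.ptp(rec.theta[held]) == 0.0
        assert not rec.theta_dot[held].any()

    def test_no_burst_before_command(self, tiny, engine):
        cfg, w = tiny
        rec = simulate_trial(cfg, w, 15.0, engine=engine)
        pre = rec.time < cfg.t_on
        assert not rec.u[pre].any()
        assert np.allclose(rec.theta[pre], 0.0)

    def test_nonpositive_target_rejected(self, tiny, engine):
        cfg, w = tiny
        with pytest.raises(ValueError):
            simulate_trial(cfg, w, -3.0, engine=engine)

    def test_invalid_motivation_rejected(self, tiny, engine):
        cfg, w = tiny
        with pytest.raises(ValueError):
            simulate_trial(cfg, w, 10.0, motivation_scale=1.5, engine=engine)


class TestDeterminismAndBatching:
    def test_identical_runs_bit_identical(self, tiny, engine):
        cfg, w = tiny
        a = simulate_trial(cfg, w, 10.0, engine=engine)
        b = simulate_trial(cfg, w, 10.0, engine=engine)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.z_contra, b.z_contra)

    def test_batch_columns_match_single_trials(self, tiny, engine):
        cfg, w = tiny
        targets = np.array([6.0, 12.0, 18.0])
        batch = engine.run_batch(targets)
        for i, target in enumerate(targets):
            rec = simulate_trial(cfg, w, target, engine=engine)
            assert batch.endpoint[i] == pytest.approx(rec.endpoint,
                                                      abs=1e-12)

    def test_early_stop_equals_full_run(self, tiny, engine):
        targets = np.array([8.0, 16.0])
        a = engine.run_batch(targets, early_stop=True)
        b = engine.run_batch(targets, early_stop=False)
        assert np.allclose(a.endpoint, b.endpoint, atol=1e-12)
        assert np.allclose(a.tracking_cost, b.tracking_cost, rtol=1e-9)


class TestClampReplay:
    def test_self_replay_reproduces_trial(self, tiny, engine):
        cfg, w = tiny
        base = simulate_trial(cfg, w, 14.0, engine=engine)
        replay = simulate_trial(cfg, w, 14.0, clamp_yc=base.y_c,
                                engine=engine)
        assert np.max(np.abs(replay.theta - base.theta)) < 1e-9
        assert np.max(np.abs(replay.u - base.u)) < 1e-9
        assert replay.clamped and not base.clamped

    def test_wrong_grid_length_rejected(self, tiny, engine):
        cfg, w = tiny
        with pytest.raises(ValueError, match="grid"):
            simulate_trial(cfg, w, 14.0, clamp_yc=np.zeros(10),
                           engine=engine)


class TestUntrainedBehaviour:
    def test_untrained_overshoots_every_target(self, tiny, engine):
        # zero readouts leave y_c = 0: the imperfect displacement estimate
        # (gain k < 1) makes every saccade hypermetric
        cfg, w = tiny
        for target in (10.0, 12.0, 15.0, 20.0):
            rec = simulate_trial(cfg, w, target, engine=engine)
            assert rec.endpoint > target

    def test_perfect_integrator_slower_peak_speed(self, tiny):
        # k = 1: accurate displacement estimate, strictly lower peak speed
        cfg, w = tiny
        rec_imperfect = simulate_trial(cfg, w, 15.0)
        cfg_perfect = cfg.replace(k=1.0)
        rec_perfect = simulate_trial(cfg_perfect, w, 15.0)
        assert rec_perfect.theta_dot.max() < rec_imperfect.theta_dot.max()
        assert abs(rec_perfect.endpoint - 15.0) < abs(
            rec_imperfect.endpoint - 15.0)

    def test_open_loop_settles_where_command_equals_estimate(self, tiny):
        # without cut-off, D -> y_d while the raw integral (and the eye)
        # overshoots by ~1/k
        cfg, w = tiny
        cfg = cfg.replace(trial_duration=1.0, cutoff_after_onset=0.9)
        rec = simulate_trial(cfg, w, 15.0)
        assert rec.D[-1] == pytest.approx(15.0, abs=0.05)
        assert rec.endpoint == pytest.approx(15.0 / cfg.k, rel=0.05)
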