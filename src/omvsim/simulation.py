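"""Closed-loop wiring of brainstem, vermis and plant into saccade trials.

The loop is advanced on a fixed grid with a one-step (dt) feedback delay:
the mossy-fiber efference copy and the fastigial excitation at step t use
the burst of step t-1, so the net cerebellar correction y_c(t) is computed
from reservoir state that has seen u up to t-1, and only then the new
burst u(t) is produced.  This fixed ordering avoids the algebraic loop a
simultaneous coupling would create.  Per step, in order:

1. eye-hold switch state from the detected onset and the clock;
2. mossy-fiber rates from the previous burst and the clock (hold-gated);
3. reservoir Euler step on both sides;
4. Purkinje, fastigial, and net cerebellar output (or the clamped
   replay value);
5. burst output from command + correction - displacement estimate;
6. displacement-integrator step (and the tonic neural-integrator charge);
7. plant step with the matched pulse+step motoneuron drive
   m = k2 * u + k3 * int u dt (the burst is a velocity command passed
   through the viscous coefficient; the neural-integrator charge holds
   position through the stiffness), or position clamp after the hold
   fires.

Movement onset is detected online as the first crossing of the
onset-speed threshold; the hold fires a fixed interval after onset.  If
the speed never crosses the threshold the hold fires at trial end and the
trial is flagged degenerate.

:class:`SimulationEngine` carries the precomputed plant discretization and
reservoir resting states and runs whole *batches* of trials column-wise;
:func:`simulate_trial` is the single-trial interface returning a full
:class:`~omvsim.records.TrialRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import brainstem, cerebellum
from .config import ModelConfig
from .plant import discretize_plant
from .records import TrialRecord
from .weights import NetworkWeights

__all__ = ["SimulationEngine", "BatchResult", "simulate_trial",
           "NumericalDivergenceError"]


class NumericalDivergenceError(RuntimeError):
    """A simulated signal became non-finite; names the step and signal."""


@dataclass
class BatchResult:
    """Per-trial outcomes of a batched run (arrays of length B)."""

    endpoint: np.ndarray        #: final (held) eye position, deg
    peak_speed: np.ndarray      #: max eye speed, deg/s
    tracking_cost: np.ndarray   #: int |desired - theta| dt over the trial
    onset_time: np.ndarray      #: detected onset, NaN if never crossed
    hold_time: np.ndarray       #: time the hold switch fired
    degenerate: np.ndarray      #: True where onset was never detected
    traces: dict[str, np.ndarray] | None = None  #: (T, B) series if recorded


class SimulationEngine:
    """Runs the closed loop for a fixed (config, fixed-weights) pair.

    The plastic readout vectors, the reservoir parameters (tau, rho), the
    targets and the motivation scale can all vary per batch column, which
    is what makes finite-difference training affordable: every perturbed
    parameter vector is just another column.
    """

    def __init__(self, config: ModelConfig, weights: NetworkWeights):
        config.validate()
        weights.validate()
        if weights.n_units != config.N:
            raise ValueError(
                f"weights have N={weights.n_units}, config.N={config.N}")
        self.config = config
        self.weights = weights
        self.disc = discretize_plant(config.k1, config.k2, config.k3,
                                     config.dt)
        self._baseline_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    # -- reservoir resting state ------------------------------------------

    def baseline(self, rho: float) -> tuple[np.ndarray, np.ndarray]:
        """Relaxed granule fixed points (contra, ipsi) for a given rho."""
        key = float(rho)
        if key not in self._baseline_cache:
            cfg = self.config
            zc = cerebellum.reservoir_baseline(
                self.weights.w_rec_contra, cfg.tau, key, cfg.dt, cfg.f_max)
            zi = cerebellum.reservoir_baseline(
                self.weights.w_rec_ipsi, cfg.tau, key, cfg.dt, cfg.f_max)
            self._baseline_cache[key] = (zc, zi)
        return self._baseline_cache[key]

    def _baselines_for(self, rho_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Stack per-column resting states, computing each unique rho once."""
        n = self.config.N
        zb_c = np.empty((n, rho_vec.size))
        zb_i = np.empty((n, rho_vec.size))
        for value in np.unique(rho_vec):
            zc, zi = self.baseline(float(value))
            cols = rho_vec == value
            zb_c[:, cols] = zc[:, None]
            zb_i[:, cols] = zi[:, None]
        return zb_c, zb_i

    # -- batched closed loop ----------------------------------------------

    def run_batch(
        self,
        targets: np.ndarray,
        motivation_scale: np.ndarray | float = 1.0,
        w_pf_pc_contra: np.ndarray | None = None,
        w_pf_pc_ipsi: np.ndarray | None = None,
        tau: np.ndarray | float | None = None,
        rho: np.ndarray | float | None = None,
        clamp_yc: np.ndarray | None = None,
        record: bool = False,
        early_stop: bool = True,
    ) -> BatchResult:
        """Simulate B trials column-wise.

        ``w_pf_pc_*`` may be (N,) shared across columns or (N, B) per
        column; None uses the vectors stored in the weights container.
        ``clamp_yc`` of shape (T,) or (T, B) replays a fixed vermal output
        instead of the computed one (the reservoir still runs, so granule
        traces remain observable).

        With ``early_stop`` (ignored when recording) the loop exits once
        every column's eye-hold switch has fired; the remaining tracking
        cost is added analytically since positions are frozen.
        """
        cfg = self.config
        w = self.weights
        targets = np.atleast_1d(np.asarray(targets, dtype=float))
        if np.any(targets <= 0):
            raise ValueError("targets must be positive (rightward saccades)")
        command = brainstem.sc_command(targets)  # 1 Hz per degree
        B = targets.size
        scale = np.broadcast_to(
            np.asarray(motivation_scale, dtype=float), (B,)).copy()
        if np.any((scale <= 0) | (scale > 1)):
            raise ValueError("motivation_scale must lie in (0, 1]")

        def _readout(vec, fallback):
            if vec is None:
                vec = fallback
            vec = np.asarray(vec, dtype=float)
            return vec[:, None] if vec.ndim == 1 else vec

        wpc_c = _readout(w_pf_pc_contra, w.w_pf_pc_contra)
        wpc_i = _readout(w_pf_pc_ipsi, w.w_pf_pc_ipsi)

        tau_vec = np.broadcast_to(np.asarray(
            cfg.tau if tau is None else tau, dtype=float), (B,))
        rho_vec = np.broadcast_to(np.asarray(
            cfg.rho if rho is None else rho, dtype=float), (B,))

        n_steps = cfg.n_steps
        if clamp_yc is not None:
            clamp_yc = np.asarray(clamp_yc, dtype=float)
            if clamp_yc.shape[0] != n_steps + 1:
                raise ValueError(
                    "clamp_yc must cover the full time grid "
                    f"({n_steps + 1} samples, got {clamp_yc.shape[0]})")
            if clamp_yc.ndim == 1:
                clamp_yc = clamp_yc[:, None]

        z_c, z_i = self._baselines_for(np.asarray(rho_vec))
        z_c, z_i = z_c.copy(), z_i.copy()

        theta = np.zeros(B)
        theta_dot = np.zeros(B)
        D = np.zeros(B)       # k * int u dt (displacement estimate)
        n_int = np.zeros(B)   # int u dt (neural-integrator charge)
        u = np.zeros(B)
        onset = np.full(B, np.inf)
        cost = np.zeros(B)
        peak_speed = np.zeros(B)
        dt = cfg.dt
        euler = cfg.plant_integrator == "euler"

        traces: dict[str, np.ndarray] | None = None
        if record:
            names = ("u", "D", "mf_target", "mf_burst", "y_pc_contra",
                     "y_pc_ipsi", "ycfn_contra", "ycfn_ipsi", "y_c",
                     "theta", "theta_dot")
            traces = {name: np.zeros((n_steps + 1, B)) for name in names}
            traces["z_contra"] = np.zeros((n_steps + 1, cfg.N, B))
            traces["z_ipsi"] = np.zeros((n_steps + 1, cfg.N, B))
            # sample 0: resting values
            ypc_c0 = cerebellum.pc_population_activity(z_c, wpc_c)
            ypc_i0 = cerebellum.pc_population_activity(z_i, wpc_i)
            ycfn_c0 = cerebellum.cfn_activity(ypc_c0, 0.0,
                                              cfg.w_pc_cfn_contra,
                                              cfg.w_mf_cfn_contra)
            ycfn_i0 = cerebellum.cfn_activity(ypc_i0, 0.0,
                                              cfg.w_pc_cfn_ipsi,
                                              cfg.w_mf_cfn_ipsi)
            traces["y_pc_contra"][0] = ypc_c0
            traces["y_pc_ipsi"][0] = ypc_i0
            traces["ycfn_contra"][0] = ycfn_c0
            traces["ycfn_ipsi"][0] = ycfn_i0
            traces["y_c"][0] = cerebellum.net_cerebellar_output(
                ycfn_c0, ycfn_i0, cfg.r1, cfg.r2)
            if clamp_yc is not None:
                traces["y_c"][0] = clamp_yc[0]
            traces["z_contra"][0] = z_c
            traces["z_ipsi"][0] = z_i

        last_step = n_steps
        for i in range(1, n_steps + 1):
            t = i * dt
            hold = brainstem.hold_switch(onset, t, cfg.cutoff_after_onset)
            live = ~hold
            if early_stop and not record and not np.any(live):
                last_step = i - 1
                break

            mft = cerebellum.mf_target_rate(t, cfg.t_on, targets, cfg.lam,
                                            cfg.alpha, hold_active=hold)
            mfb = cerebellum.mf_burst_rate(u, hold_active=hold)
            mf = cerebellum.normalize_mf(mft, mfb, cfg.A,
                                         cfg.mf_target_norm, cfg.mf_gain)

            z_c = cerebellum.reservoir_step(z_c, mf, w.w_mf_grc_contra,
                                            w.w_rec_contra, tau_vec, rho_vec,
                                            dt, cfg.f_max)
            z_i = cerebellum.reservoir_step(z_i, mf, w.w_mf_grc_ipsi,
                                            w.w_rec_ipsi, tau_vec, rho_vec,
                                            dt, cfg.f_max)

            ypc_c = cerebellum.pc_population_activity(z_c, wpc_c)
            ypc_i = cerebellum.pc_population_activity(z_i, wpc_i)
            ycfn_c = cerebellum.cfn_activity(ypc_c, u, cfg.w_pc_cfn_contra,
                                             cfg.w_mf_cfn_contra)
            ycfn_i = cerebellum.cfn_activity(ypc_i, u, cfg.w_pc_cfn_ipsi,
                                             cfg.w_mf_cfn_ipsi)
            if clamp_yc is not None:
                y_c = np.broadcast_to(clamp_yc[i], (B,))
            else:
                y_c = cerebellum.net_cerebellar_output(ycfn_c, ycfn_i,
                                                       cfg.r1, cfg.r2)

            y_d = np.where((t >= cfg.t_on) & live, command, 0.0)
            state = brainstem.BrainstemState(D=D, n_int=n_int, u_prev=u,
                                             hold_active=hold)
            u = brainstem.burst_output(y_d, y_c, state, cfg.A, cfg.sigma,
                                       scale)
            if t < cfg.t_on:
                # omnipause gate: the burst pathway is released only by the
                # collicular trigger, so cerebellar drive alone cannot move
                # the eye before the command
                u = np.zeros_like(u)
            state = brainstem.integrator_step(state, u, cfg.k, dt)
            D, n_int = state.D, state.n_int

            # matched pulse+step motoneuron drive: the velocity pulse u acts
            # through the viscosity, the tonic NI charge through the
            # stiffness, so theta tracks int u dt (1 Hz ~ 1 deg/s)
            m = cfg.k2 * u + cfg.k3 * n_int
            if euler:
                acc = (m - cfg.k2 * theta_dot - cfg.k3 * theta) / cfg.k1
                theta_new = theta + dt * theta_dot
                theta_dot_new = theta_dot + dt * acc
            else:
                theta_new = (self.disc.Ad[0, 0] * theta
                             + self.disc.Ad[0, 1] * theta_dot
                             + self.disc.Bd[0] * m)
                theta_dot_new = (self.disc.Ad[1, 0] * theta
                                 + self.disc.Ad[1, 1] * theta_dot
                                 + self.disc.Bd[1] * m)
            theta = np.where(live, theta_new, theta)
            theta_dot = np.where(live, theta_dot_new, 0.0)

            np.maximum(peak_speed, theta_dot, out=peak_speed)
            onset = np.where(
                np.isinf(onset) & (theta_dot >= cfg.onset_speed_threshold),
                t, onset)

            desired = np.where(t >= cfg.t_on, targets, 0.0)
            cost += np.abs(desired - theta) * dt

            if not (np.all(np.isfinite(u)) and np.all(np.isfinite(theta))):
                signal = "u" if not np.all(np.isfinite(u)) else "theta"
                raise NumericalDivergenceError(
                    f"non-finite signal '{signal}' at step {i} (t={t:.4f}s)")

            if record:
                for name, value in (("u", u), ("D", D), ("mf_target", mft),
                                    ("mf_burst", mfb),
                                    ("y_pc_contra", ypc_c),
                                    ("y_pc_ipsi", ypc_i),
                                    ("ycfn_contra", ycfn_c),
                                    ("ycfn_ipsi", ycfn_i), ("y_c", y_c),
                                    ("theta", theta),
                                    ("theta_dot", theta_dot)):
                    traces[name][i] = value
                traces["z_contra"][i] = z_c
                traces["z_ipsi"][i] = z_i

        if last_step < n_steps:
            # all eyes are held: positions frozen, remaining cost is linear
            cost += np.abs(targets - theta) * dt * (n_steps - last_step)

        degenerate = np.isinf(onset)
        hold_time = np.where(degenerate, cfg.trial_duration,
                             onset + cfg.cutoff_after_onset)
        hold_time = np.minimum(hold_time, cfg.trial_duration)
        return BatchResult(
            endpoint=theta,
            peak_speed=peak_speed,
            tracking_cost=cost,
            onset_time=np.where(degenerate, np.nan, onset),
            hold_time=hold_time,
            degenerate=degenerate,
            traces=traces,
        )


def simulate_trial(
    config: ModelConfig,
    weights: NetworkWeights,
    target: float,
    motivation_scale: float = 1.0,
    clamp_yc: np.ndarray | None = None,
    engine: SimulationEngine | None = None,
) -> TrialRecord:
    """Simulate one saccade trial and record every signal.

    ``clamp_yc``, if given, must cover the full time grid and replaces the
    computed vermal output sample-for-sample (the "clamped OMV" protocol).
    """
    if engine is None:
        engine = SimulationEngine(config, weights)
    result = engine.run_batch(
        np.array([float(target)]),
        motivation_scale=float(motivation_scale),
        clamp_yc=clamp_yc,
        record=True,
    )
    tr = result.traces
    time = np.arange(config.n_steps + 1) * config.dt
    return TrialRecord(
        time=time,
        u=tr["u"][:, 0],
        D=tr["D"][:, 0],
        mf_target=tr["mf_target"][:, 0],
        mf_burst=tr["mf_burst"][:, 0],
        z_contra=tr["z_contra"][:, :, 0],
        z_ipsi=tr["z_ipsi"][:, :, 0],
        y_pc_contra=tr["y_pc_contra"][:, 0],
        y_pc_ipsi=tr["y_pc_ipsi"][:, 0],
        ycfn_contra=tr["ycfn_contra"][:, 0],
        ycfn_ipsi=tr["ycfn_ipsi"][:, 0],
        y_c=tr["y_c"][:, 0],
        theta=tr["theta"][:, 0],
        theta_dot=tr["theta_dot"][:, 0],
        target=float(target),
        motivation_scale=float(motivation_scale),
        t_on=config.t_on,
        onset_time=float(result.onset_time[0]),
        hold_time=float(result.hold_time[0]),
        clamped=clamp_yc is not None,
    )
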