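"""Bilateral oculomotor vermis: mossy fibers, granular reservoir, PC and cFN.

Two mossy-fiber channels drive each side of the vermis:

* ``MF_target`` carries the commanded displacement with a Gaussian
  long-lead build-up before movement initiation, sustaining at
  ``lam * y_d`` from ``t_on`` until the cut-off switch fires;
* ``MF_burst`` is the efference copy of the brainstem burst ``u``.

Before entering the granular layer the two channels are normalized to a
comparable [0, 1] magnitude (by ``lam * 20 deg`` and by the nominal burst
amplitude ``A`` respectively) so the drawn input weights act on inputs of
similar scale.

The granular layer is a leaky rate reservoir of N units per side,

    tau * dz/dt = -z + S,    S = f(w_mf_grc @ m - rho * w_rec @ z),

with f a logistic saturation scaled to [0, f_max], ``w_rec`` nonnegative
(the minus sign makes the recurrence inhibitory) and normalized to unit
spectral radius so ``rho`` sets the effective recurrent gain.  Activities
are rectified at zero.

Each Purkinje layer is the *total population projection* onto one
fastigial nucleus -- a single scalar readout ``y_pc = w_pf_pc . z`` -- not
an individual cell.  The fastigial output combines PC inhibition with
direct mossy-fiber excitation,

    y_cfn = -w_pc_cfn * y_pc + w_mf_cfn * u,

and the net cerebellar correction fed back to the burst generator is the
responsibility-weighted difference of the two sides,

    y_c = r1 * y_cfn_contra + r2 * y_cfn_ipsi.

All operations are vectorized: ``z`` may be (N,) or (N, B) for a batch of
B trials, in which case per-trial parameters broadcast along the batch.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mf_target_rate",
    "mf_burst_rate",
    "normalize_mf",
    "granule_drive_function",
    "reservoir_step",
    "reservoir_baseline",
    "pc_population_activity",
    "cfn_activity",
    "net_cerebellar_output",
]


def mf_target_rate(t: float, t_on: float, y_d, lam: float, alpha: float,
                   hold_active=False):
    """Target-channel mossy-fiber rate (Hz).

    Gaussian build-up ``lam * y_d * exp(-(t - t_on)^2 / alpha^2)`` for
    t <= t_on, sustained at ``lam * y_d`` afterwards, silenced by the
    cut-off switch.
    """
    y_d = np.asarray(y_d, dtype=float)
    sustained = lam * y_d
    if t <= t_on:
        rate = sustained * np.exp(-((t - t_on) ** 2) / alpha**2)
    else:
        rate = sustained
    rate = np.where(hold_active, 0.0, rate)
    return rate[()] if rate.ndim == 0 else rate


def mf_burst_rate(u, hold_active=False):
    """Efference-copy channel: the burst rate itself, gated by the hold."""
    u = np.asarray(u, dtype=float)
    rate = np.where(hold_active, 0.0, u)
    return rate[()] if rate.ndim == 0 else rate


def normalize_mf(mf_target, mf_burst, A: float, mf_target_norm: float,
                 mf_gain: float = 1.0):
    """Stack the two MF channels scaled into comparable units.

    Each channel is first brought to a [0, 1] range (the burst channel by
    the *nominal* burst amplitude, so reductions of the effective
    amplitude remain visible to the vermis), then multiplied by
    ``mf_gain``.  The gain sets where the granule drive lands on the
    saturating transfer function: at 1 the drawn input weights push most
    units into saturation (near-binary responses), while smaller gains
    keep the granule population in its sensitive range so activities
    grade with the burst rate.  Returns shape (2,) or (2, B).
    """
    return np.stack([
        np.asarray(mf_target, dtype=float) * (mf_gain / mf_target_norm),
        np.asarray(mf_burst, dtype=float) * (mf_gain / A),
    ])


def granule_drive_function(x, f_max: float = 1.0):
    """Logistic saturation scaled to (0, f_max); f(0) = f_max / 2."""
    return f_max / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def reservoir_step(z, mf, w_mf_grc, w_rec, tau, rho, dt: float,
                   f_max: float = 1.0):
    """One Euler step of the leaky reservoir; rectifies z at zero.

    Parameters ``tau`` and ``rho`` may be scalars or per-column arrays
    when ``z`` is (N, B).
    """
    rec = w_rec @ z
    S = granule_drive_function(w_mf_grc @ mf - rho * rec, f_max)
    z_new = z + (dt / np.asarray(tau, dtype=float)) * (-z + S)
    return np.maximum(z_new, 0.0)


def reservoir_baseline(w_rec, tau, rho, dt: float, f_max: float = 1.0,
                       horizon: float | None = None):
    """Relaxed fixed point of the reservoir under zero mossy-fiber input.

    Integrates the dynamics from z = 0 for ``horizon`` seconds (default
    40 tau, ample for convergence at rho <= 1).  ``rho`` may be a scalar
    or a vector of M values, in which case the result is (N, M).  The
    fixed point solves z* = f(-rho * w_rec @ z*) per unit and is
    independent of tau.
    """
    n = w_rec.shape[0]
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    z = np.zeros((n, rho_arr.size))
    if horizon is None:
        horizon = 40.0 * float(np.max(tau))
    steps = int(np.ceil(horizon / dt))
    mf0 = np.zeros((2, rho_arr.size))
    w_mf0 = np.zeros((n, 2))
    for _ in range(steps):
        z = reservoir_step(z, mf0, w_mf0, w_rec, tau=float(np.max(tau)),
                           rho=rho_arr, dt=dt, f_max=f_max)
    if np.ndim(rho) == 0:
        return z[:, 0]
    return z


def pc_population_activity(z, w_pf_pc):
    """Total Purkinje population projection onto one cFN: w_pf_pc . z.

    With matching batch shapes (N, B) the dot product is taken per column.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w_pf_pc, dtype=float)
    if z.shape[0] != w.shape[0]:
        raise ValueError(
            f"length mismatch: z has {z.shape[0]} units, "
            f"w_pf_pc has {w.shape[0]}")
    if z.ndim == 1 and w.ndim == 1:
        return float(w @ z)
    if w.ndim == 1:
        return w @ z
    return np.einsum("nb,nb->b", w, z)


def cfn_activity(y_pc, u, w_pc_cfn: float, w_mf_cfn: float):
    """Fastigial rate: PC inhibition plus mossy-fiber excitation."""
    return -w_pc_cfn * np.asarray(y_pc, dtype=float) + w_mf_cfn * np.asarray(
        u, dtype=float)


def net_cerebellar_output(y_cfn_contra, y_cfn_ipsi, r1: float, r2: float):
    """Net correction to the burst generator: r1*contra + r2*ipsi."""
    return r1 * np.asarray(y_cfn_contra, dtype=float) + r2 * np.asarray(
        y_cfn_ipsi, dtype=float)
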