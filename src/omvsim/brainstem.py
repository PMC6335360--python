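"""Grouped brainstem burst generator with internal displacement feedback.

The medium-lead burst neurons are collapsed into a single rate unit whose
output ``u`` (Hz) is a saturating function of the dynamic motor error:
the desired displacement command ``y_d`` plus the cerebellar correction
``y_c`` minus an internal estimate of the displacement already executed.
That estimate is produced by a displacement integrator (DI) that performs
imperfect integration of the burst itself,

    u(t) = A * (1 - exp(-(y_c + y_d - k * int u dt) / sigma)),

with gain ``k < 1`` making the estimate inaccurate: the loop settles where
the scaled integral equals the command, so the raw integral -- and with it
the eye -- overshoots the target by roughly 1/k when the cerebellar
correction is absent.  Burst neurons cannot fire negatively, so ``u`` is
rectified at zero; braking drive is carried by the ipsilateral fastigial
pathway through ``y_c`` instead.

A superior-colliculus "dummy" unit supplies ``y_d`` as a step with firing
rate numerically equal to the target eccentricity (1 Hz per degree), and a
timed switch replaces omnipause-neuron dynamics: a fixed interval after
detected movement onset it silences the burst and the cerebellar inputs
and holds the eye at the reached position.

All functions accept scalars or numpy arrays (vectorized over trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BrainstemState",
    "sc_command",
    "burst_output",
    "integrator_step",
    "hold_switch",
]


@dataclass
class BrainstemState:
    """State of the grouped burst generator for one (or a batch of) trials.

    ``D`` is the displacement-integrator accumulation, i.e. k * int u dt,
    in degree-equivalent drive units.  ``n_int`` is the raw (unscaled)
    integral of the burst, which feeds the tonic (neural-integrator) step
    component of the motor drive.
    """

    D: np.ndarray | float = 0.0
    n_int: np.ndarray | float = 0.0
    u_prev: np.ndarray | float = 0.0
    hold_active: np.ndarray | bool = False


def sc_command(target_amplitude):
    """Step command of the dummy superior-colliculus unit (1 Hz = 1 deg).

    Only rightward (nonnegative) horizontal saccades are modeled.
    """
    target_amplitude = np.asarray(target_amplitude, dtype=float)
    if np.any(target_amplitude < 0):
        raise ValueError("only rightward (nonnegative) targets are modeled")
    return target_amplitude[()] if target_amplitude.ndim == 0 else target_amplitude


def burst_output(y_d, y_c, state: BrainstemState, A: float, sigma: float,
                 motivation_scale=1.0):
    """Rectified burst rate ``u`` given the current drives and DI state.

    ``motivation_scale`` multiplies the burst amplitude ``A``; values below
    one emulate a reduced motivational state.  Output is zero wherever the
    eye-hold switch is active.  Bounded in [0, A * motivation_scale).
    """
    drive = np.asarray(y_c, dtype=float) + np.asarray(y_d, dtype=float) - state.D
    u = A * np.asarray(motivation_scale, dtype=float) * (
        1.0 - np.exp(-drive / sigma))
    u = np.maximum(u, 0.0)
    u = np.where(state.hold_active, 0.0, u)
    return u[()] if np.ndim(u) == 0 else u


def integrator_step(state: BrainstemState, u, k: float, dt: float) -> BrainstemState:
    """Advance the displacement integrator: D <- D + k*u*dt.

    The integration itself is perfect; the imperfection of the internal
    displacement estimate is realized purely through the gain k < 1.  The
    raw integral ``n_int`` (the neural-integrator charge) advances with
    unit gain.
    """
    u = np.asarray(u, dtype=float)
    return BrainstemState(
        D=state.D + k * u * dt,
        n_int=state.n_int + u * dt,
        u_prev=u[()] if u.ndim == 0 else u,
        hold_active=state.hold_active,
    )


def hold_switch(onset_time, t: float, cutoff_after_onset: float):
    """True once ``t`` reaches ``onset_time + cutoff_after_onset``.

    ``onset_time`` may be None / NaN / inf where movement onset has not
    occurred, in which case the switch stays off.  The condition is
    monotone in ``t``, so once fired it remains fired for the trial.
    """
    if onset_time is None:
        return False
    onset = np.asarray(onset_time, dtype=float)
    with np.errstate(invalid="ignore"):
        fired = np.where(np.isfinite(onset), t >= onset + cutoff_after_onset,
                         False)
    return bool(fired) if fired.ndim == 0 else fired
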