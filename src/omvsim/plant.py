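"""Second-order linear oculomotor plant.

The eye and orbital tissue are approximated by the overdamped system

    k1 * theta'' + k2 * theta' + k3 * theta = m(t)

with theta the horizontal eye position in degrees and m(t) the net motor
drive.  With the default constants (k1=0.003 s^2, k2=0.6 s, k3=4) the
characteristic roots are about -6.9/s and -193/s: a fast 5 ms component
riding on a slow 145 ms one, with no ringing.

The default integration scheme is the exact zero-order-hold discretization
of the two-state companion system (matrix exponential, precomputed once
per step size), which is unconditionally stable; a forward-Euler fallback
exists for cross-checking.  After the eye-hold switch fires, the position
is clamped: velocity is zeroed and further steps are bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = ["PlantState", "PlantDiscretization", "discretize_plant",
           "plant_step", "plant_step_euler", "clamp_position"]


@dataclass
class PlantState:
    """Eye position (deg) and velocity (deg/s); scalar or batch arrays."""

    theta: np.ndarray | float = 0.0
    theta_dot: np.ndarray | float = 0.0


@dataclass(frozen=True)
class PlantDiscretization:
    """Precomputed exact one-step propagator for a fixed dt."""

    Ad: np.ndarray  #: (2, 2) state transition over dt
    Bd: np.ndarray  #: (2,) input vector for zero-order-hold drive
    dt: float


def companion_matrices(k1: float, k2: float, k3: float):
    """Continuous-time system x' = F x + G m for x = (theta, theta_dot)."""
    F = np.array([[0.0, 1.0], [-k3 / k1, -k2 / k1]])
    G = np.array([0.0, 1.0 / k1])
    return F, G


def discretize_plant(k1: float, k2: float, k3: float,
                     dt: float) -> PlantDiscretization:
    """Exact ZOH discretization: Ad = expm(F dt), Bd = F^-1 (Ad - I) G."""
    F, G = companion_matrices(k1, k2, k3)
    Ad = expm(F * dt)
    Bd = np.linalg.solve(F, (Ad - np.eye(2)) @ G)
    return PlantDiscretization(Ad=Ad, Bd=Bd, dt=dt)


def plant_step(state: PlantState, m, disc: PlantDiscretization) -> PlantState:
    """Advance one exact step holding the drive m constant over dt."""
    x = np.stack([np.asarray(state.theta, dtype=float),
                  np.asarray(state.theta_dot, dtype=float)])
    m = np.asarray(m, dtype=float)
    xn = disc.Ad @ x + np.multiply.outer(disc.Bd, m)
    return PlantState(theta=xn[0][()] if xn[0].ndim == 0 else xn[0],
                      theta_dot=xn[1][()] if xn[1].ndim == 0 else xn[1])


def plant_step_euler(state: PlantState, m, k1: float, k2: float, k3: float,
                     dt: float) -> PlantState:
    """Forward-Euler step; testing oracle for the exact scheme."""
    theta = np.asarray(state.theta, dtype=float)
    theta_dot = np.asarray(state.theta_dot, dtype=float)
    m = np.asarray(m, dtype=float)
    acc = (m - k2 * theta_dot - k3 * theta) / k1
    return PlantState(theta=theta + dt * theta_dot,
                      theta_dot=theta_dot + dt * acc)


def clamp_position(state: PlantState) -> PlantState:
    """Hold the eye at the reached position: zero the velocity.

    Idempotent; while the hold is active the simulation bypasses
    ``plant_step`` so the position trace stays constant.
    """
    return PlantState(theta=state.theta,
                      theta_dot=np.zeros_like(np.asarray(state.theta, dtype=float))[()]
                      if np.ndim(state.theta) == 0 else np.zeros_like(state.theta))
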