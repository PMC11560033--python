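"""Toy rigid-helix steering simulator.

Reproduces, at desk scale, the logic of an orientation-steered MD protocol:
a harmonic restraint whose target orientation interpolates from the
identity to a target quaternion over a pulling phase (default 20 ns), after
which the restraint is removed and the angle diffuses freely (default
70 ns of relaxation).

The dynamics is overdamped rotational Brownian motion of the single
geodesic angle θ toward the moving target:

    dθ = −(k/γ)·(θ − θ_target(t))·dt + sqrt(2·D·dt)·ξ

with friction γ in kcal·ns/(mol·deg²) and angular diffusivity D in
deg²/ns.  The companion restraint holding the reference helix (TM3) at
(1,0,0,0) is represented by the fixed laboratory frame and is not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpcrmech.heligeom import UnitQuaternion, interpolate_orientation, quaternion_angle

#: Force constant printed for the pulling restraint: 5000 kcal/(mol·rad²).
DEFAULT_K_PER_RAD2 = 5000.0
#: Same constant expressed per squared degree (≈ 1.52 kcal/(mol·deg²)).
DEFAULT_K_PER_DEG2 = DEFAULT_K_PER_RAD2 * (np.pi / 180.0) ** 2


@dataclass(frozen=True)
class SteeringSchedule:
    """Pull-then-relax schedule for the moving orientation target."""

    q_target: UnitQuaternion
    pull_duration: float = 20.0  # ns
    relax_duration: float = 70.0  # ns
    timestep: float = 0.01  # ns

    def __post_init__(self) -> None:
        if self.pull_duration <= 0 or self.relax_duration < 0 or self.timestep <= 0:
            raise ValueError("durations must be positive and timestep > 0")

    @property
    def total_duration(self) -> float:
        return self.pull_duration + self.relax_duration

    def target_at(self, t: float) -> UnitQuaternion:
        """Target orientation at time t: linear-in-angle ramp, then hold."""
        frac = min(max(t / self.pull_duration, 0.0), 1.0)
        return interpolate_orientation(self.q_target, frac)

    def target_angle_at(self, t: float) -> float:
        return quaternion_angle(self.target_at(t))


def restraint_energy(
    q_current: UnitQuaternion, q_moving_target: UnitQuaternion, k: float
) -> float:
    """Harmonic restraint energy ½·k·θ_dev² (kcal/mol, k in kcal/(mol·deg²)).

    θ_dev is the angle of the relative rotation between the current and the
    target orientation.
    """
    if k < 0:
        raise ValueError("force constant must be non-negative")
    theta_dev = quaternion_angle(q_moving_target.compose(q_current.conjugate()))
    return 0.5 * k * theta_dev**2


def simulate_pull(
    schedule: SteeringSchedule,
    k: float = DEFAULT_K_PER_DEG2,
    rotational_friction: float = 2.6,
    temperature_factor: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Overdamped Langevin dynamics of the steering angle.

    Parameters
    ----------
    k : kcal/(mol·deg²), restraint stiffness (0 disables the force).
    rotational_friction : kcal·ns/(mol·deg²), drag γ of the helix angle.
    temperature_factor : deg²/ns, angular diffusivity D (0 → deterministic).
    seed : reproducibility; identical seeds give bitwise-identical series.

    Returns
    -------
    DataFrame with columns ``time`` (ns), ``theta`` (deg, angle from the
    start orientation), ``theta_target`` and ``theta_dev`` (deg, deviation
    from the moving target; 0 once the restraint is released).
    """
    if rotational_friction <= 0:
        raise ValueError("rotational friction must be positive")
    dt = schedule.timestep
    if k * dt / rotational_friction > 0.5:
        raise ValueError(
            "unstable integration: k*dt/friction = "
            f"{k * dt / rotational_friction:.3f} > 0.5; reduce the timestep"
        )
    rng = np.random.default_rng(seed)
    n_steps = int(round(schedule.total_duration / dt))
    times = np.arange(n_steps + 1) * dt
    theta = np.empty(n_steps + 1)
    target = np.array([schedule.target_angle_at(t) for t in times])
    theta[0] = 0.0
    sigma = np.sqrt(2.0 * temperature_factor * dt)
    noise = rng.standard_normal(n_steps) * sigma
    for i in range(n_steps):
        t = times[i]
        if t < schedule.pull_duration and k > 0:
            drift = -(k / rotational_friction) * (theta[i] - target[i]) * dt
        else:
            drift = 0.0
        theta[i + 1] = theta[i] + drift + noise[i]
    dev = np.where(times <= schedule.pull_duration, np.abs(theta - target), 0.0)
    return pd.DataFrame(
        {"time": times, "theta": theta, "theta_target": target, "theta_dev": dev}
    )
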