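"""Deterministic Newtonian mechanics of the puck-sliding task.

A puck of mass ``m`` rests at distance ``Δx`` from a target on a surface with
friction coefficient ``μ``.  A button press of duration ``t`` applies a
constant force ``F``, so the puck is released with velocity ``v0 = F t / m``
(impulse–momentum).  Sliding under kinetic friction decelerates the puck at
``μ g``, so it travels ``v0² / (2 μ g)``.  Inverting this chain gives the
press-time that lands the puck exactly on the target,

    T = (m / F) * sqrt(2 μ g Δx),

linear in mass and square-root in distance.  Collisions between pucks are
one-dimensional and perfectly elastic (momentum and kinetic energy conserved),
and are simulated without friction.

On screen, the scene is drawn from a bird's-eye view; 1080 vertical pixels
correspond to roughly 11.5 m of simulated surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "EnvironmentParams",
    "PuckSpec",
    "ideal_press_time",
    "release_velocity",
    "simulate_slide",
    "SlideResult",
    "elastic_collision",
    "collision_implied_mass",
    "metres_to_pixels",
    "pixels_to_metres",
]


@dataclass(frozen=True)
class EnvironmentParams:
    """Physical constants and display geometry of the simulated environment.

    The behavioural task only identifies relative quantities (mass ratios,
    the square-root scaling of press-time with distance), so the absolute
    values of ``friction_coefficient``, ``interaction_force`` and
    ``frame_interval`` are conventions; they are configurable and default to
    round numbers.
    """

    friction_coefficient: float = 0.2
    gravity: float = 9.81
    interaction_force: float = 10.0
    frame_interval: float = 1.0 / 60.0
    distance_range: tuple[float, float] = (1.0, 5.0)
    pixels_per_metre: float = 1080.0 / 11.5

    def __post_init__(self) -> None:
        for name in (
            "friction_coefficient",
            "gravity",
            "interaction_force",
            "frame_interval",
            "pixels_per_metre",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a finite positive number")
        lo, hi = self.distance_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("distance_range must satisfy min < max")

    # μ g appears everywhere as the sliding deceleration
    @property
    def deceleration(self) -> float:
        return self.friction_coefficient * self.gravity

    def to_dict(self) -> dict:
        return {
            "friction_coefficient": self.friction_coefficient,
            "gravity": self.gravity,
            "interaction_force": self.interaction_force,
            "frame_interval": self.frame_interval,
            "distance_range": list(self.distance_range),
            "pixels_per_metre": self.pixels_per_metre,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentParams":
        d = dict(d)
        if "distance_range" in d:
            d["distance_range"] = tuple(d["distance_range"])
        return cls(**d)

    def with_frame_interval(self, dt: float) -> "EnvironmentParams":
        return replace(self, frame_interval=dt)


@dataclass(frozen=True)
class PuckSpec:
    """A puck as simulated: an id (its surface texture/colour) and a mass."""

    puck_id: str
    mass: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mass) or self.mass <= 0:
            raise ValueError("puck mass must be a finite positive number")


def ideal_press_time(distance: float, mass: float, env: EnvironmentParams) -> float:
    """Press-time that brings the puck exactly to ``distance`` metres.

    ``T = (m / F) * sqrt(2 μ g Δx)``: linear in mass, square-root in distance.

    Raises
    ------
    ValueError
        If ``mass <= 0`` or ``distance < 0``.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if np.any(np.asarray(distance) < 0):
        raise ValueError("distance must be non-negative")
    return (mass / env.interaction_force) * np.sqrt(2.0 * env.deceleration * distance)


def release_velocity(press_time: float, mass: float, env: EnvironmentParams) -> float:
    """Release velocity ``v0 = F t / m`` produced by a press of ``press_time`` s."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if np.any(np.asarray(press_time) < 0):
        raise ValueError("press_time must be non-negative")
    return env.interaction_force * press_time / mass


@dataclass(frozen=True)
class SlideResult:
    displacement: float
    times: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    velocities: np.ndarray = field(repr=False)

    def trajectory_frame(self):
        """Trajectory as a pandas DataFrame (frame, t, x, v)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(len(self.times)),
                "t": self.times,
                "x": self.positions,
                "v": self.velocities,
            }
        )


def simulate_slide(v0: float, env: EnvironmentParams) -> SlideResult:
    """Frame-wise simulation of a puck sliding under friction.

    Difference equations per display frame: ``v ← v − μ g dt`` and the
    displacement advanced by the trapezoid of the frame's start/end
    velocities — exact for the linear velocity decay of constant kinetic
    friction, so the total displacement matches the closed form
    ``v0² / (2 μ g)`` to rounding error at any frame rate.  The final
    partial frame (where ``v`` crosses zero) is truncated analytically so
    the displacement never overshoots.
    """
    if v0 < 0:
        raise ValueError("v0 must be non-negative")
    a = env.deceleration
    dt = env.frame_interval
    times = [0.0]
    xs = [0.0]
    vs = [float(v0)]
    x, v, t = 0.0, float(v0), 0.0
    while v > 0.0:
        v_new = v - a * dt
        if v_new <= 0.0:
            # analytic remainder: decelerate from v to rest in t* = v / a
            t_star = v / a
            x += v * t_star - 0.5 * a * t_star**2
            t += t_star
            v = 0.0
        else:
            x += 0.5 * (v + v_new) * dt
            v = v_new
            t += dt
        times.append(t)
        xs.append(x)
        vs.append(v)
    return SlideResult(
        displacement=x,
        times=np.asarray(times),
        positions=np.asarray(xs),
        velocities=np.asarray(vs),
    )


def elastic_collision(
    vF: float, vNF: float, mF: float, mNF: float
) -> tuple[float, float]:
    """One-dimensional perfectly elastic collision.

    Returns post-collision velocities ``(uF, uNF)`` of the pucks with masses
    ``mF`` and ``mNF`` and pre-collision velocities ``vF`` and ``vNF``.
    Momentum and kinetic energy are conserved exactly.  Works element-wise on
    arrays.
    """
    mF = np.asarray(mF, dtype=float)
    mNF = np.asarray(mNF, dtype=float)
    if np.any(mF <= 0) or np.any(mNF <= 0):
        raise ValueError("masses must be positive")
    total = mF + mNF
    uF = ((mF - mNF) * vF + 2.0 * mNF * vNF) / total
    uNF = ((mNF - mF) * vNF + 2.0 * mF * vF) / total
    if uF.ndim == 0:
        return float(uF), float(uNF)
    return uF, uNF


def collision_implied_mass(vF, vNF, uF, mF):
    """Unknown mass implied by one elastic collision, from the known puck's
    velocity change: ``mNF = mF (vF − uF) / (uF + vF − 2 vNF)``.

    Undefined (division by ~0) when the known puck's velocity is unchanged.
    Works element-wise on arrays.
    """
    denom = np.asarray(uF + vF - 2.0 * vNF, dtype=float)
    return mF * (vF - uF) / denom


def metres_to_pixels(x: float, env: EnvironmentParams) -> float:
    """Convert a simulation-space length in metres to display pixels."""
    return x * env.pixels_per_metre


def pixels_to_metres(px: float, env: EnvironmentParams) -> float:
    return px / env.pixels_per_metre
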