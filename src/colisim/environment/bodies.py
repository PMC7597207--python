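"""Overdamped rigid-body mechanics for capsule-shaped agents in 2D.

Cells at micron scale live at low Reynolds number: viscous drag
overwhelms inertia, so bodies move at the velocity where drag balances
applied force (v = F / gamma) with no ballistic transient. Thermal jitter
is modeled as a force of fixed magnitude applied in a uniform random
direction at a uniform random point along the body axis each step, which
randomizes both position and orientation. Volume exclusion between
capsules is resolved by pushing overlapping bodies apart along the
minimal separation vector between their core segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class AgentBody:
    """A capsule body: core segment of length (length - width), radius width/2."""

    location: np.ndarray  # (x, y) um
    orientation: float  # radians
    length: float = 2.0  # um (total, tip to tip)
    width: float = 1.0  # um
    mass: float = 1000.0  # fg
    thrust: float = 0.0  # pN, applied along the body axis rotated by force_angle
    torque: float = 0.0  # pN um
    force_angle: float = 0.0  # radians, angle of thrust relative to body axis

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        if not (self.length >= self.width > 0):
            raise ValueError("capsule requires length >= width > 0")

    @property
    def volume(self) -> float:
        """Capsule volume in um^3 (cylinder plus hemispherical caps)."""
        r = self.width / 2
        return math.pi * r * r * (self.length - self.width) + 4 / 3 * math.pi * r**3

    @property
    def heading(self) -> np.ndarray:
        return np.array([math.cos(self.orientation), math.sin(self.orientation)])

    def segment(self) -> tuple[np.ndarray, np.ndarray]:
        """End points of the capsule's core segment."""
        half = max(self.length - self.width, 0.0) / 2
        d = self.heading * half
        return self.location - d, self.location + d


@dataclass
class PhysicsConfig:
    translational_damping: float = 0.033707  # pN s / um; run speed = thrust / gamma
    rotational_damping: float = 0.08  # pN um s / rad
    jitter_force: float = 0.002  # pN
    dt: float = 0.01  # s
    bounds: tuple[float, float] = (2500.0, 2500.0)  # um
    exclusion_iterations: int = 3

    def __post_init__(self):
        if self.translational_damping <= 0 or self.rotational_damping <= 0:
            raise ValueError("damping must be > 0 (overdamped regime)")


def segment_segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between two segments, with the closest points."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r)), p1, p2
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= eps:
            s, t = np.clip(-c / a, 0.0, 1.0), 0.0
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    c1 = p1 + d1 * s
    c2 = p2 + d2 * t
    return float(np.linalg.norm(c1 - c2)), c1, c2


def _resolve_overlaps(bodies: list[AgentBody], iterations: int) -> None:
    for _ in range(iterations):
        moved = False
        for i in range(len(bodies)):
            for j in range(i + 1, len(bodies)):
                bi, bj = bodies[i], bodies[j]
                contact = (bi.width + bj.width) / 2
                dist, ci, cj = segment_segment_distance(*bi.segment(), *bj.segment())
                if dist < contact - 1e-9:
                    if dist < 1e-9:
                        # coincident (e.g. just-divided daughters): push
                        # apart along the body axis
                        axis = bi.heading
                    else:
                        axis = (ci - cj) / dist
                    push = (contact - dist) / 2
                    bi.location = bi.location + axis * push
                    bj.location = bj.location - axis * push
                    moved = True
        if not moved:
            break


def _reflect(body: AgentBody, bounds: tuple[float, float]) -> None:
    x, y = body.location
    r = body.width / 2
    if x < r or x > bounds[0] - r:
        body.location[0] = min(max(x, r), bounds[0] - r)
        body.orientation = math.pi - body.orientation
    if y < r or y > bounds[1] - r:
        body.location[1] = min(max(y, r), bounds[1] - r)
        body.orientation = -body.orientation


def step_multibody(
    bodies: list[AgentBody], config: PhysicsConfig, rng: np.random.Generator
) -> list[AgentBody]:
    """Advance all bodies one time-step in place (returns the same list).

    Each body moves at thrust/gamma along its (possibly off-axis) force
    direction, rotates at torque/gamma_r, and receives one jitter kick;
    overlaps are then resolved and out-of-bounds bodies reflected.
    """
    dt = config.dt
    if dt <= 0:
        raise ValueError("dt must be > 0")
    gamma_t = config.translational_damping
    gamma_r = config.rotational_damping
    for body in bodies:
        angle = body.orientation + body.force_angle
        force = body.thrust * np.array([math.cos(angle), math.sin(angle)])
        torque = body.torque
        if config.jitter_force > 0:
            jdir = rng.uniform(0, 2 * math.pi)
            jarm = rng.uniform(-body.length / 2, body.length / 2)
            jangle = rng.uniform(-math.pi, math.pi)
            force = force + config.jitter_force * np.array(
                [math.cos(jdir), math.sin(jdir)]
            )
            torque = torque + config.jitter_force * jarm * math.sin(jangle)
        body.location = body.location + force / gamma_t * dt
        body.orientation = body.orientation + torque / gamma_r * dt
    if len(bodies) > 1:
        _resolve_overlaps(bodies, config.exclusion_iterations)
    for body in bodies:
        _reflect(body, config.bounds)
    return bodies
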