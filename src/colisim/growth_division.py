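"""Minimal agent: exponential mass growth and mass-threshold division.

Cellular mass is lumped into one value growing as m(t) = m0 * 2^(t/tau)
with a doubling time tau of about 40 minutes; cells initialize at
1000 fg and divide when they reach double that mass. Daughters inherit
the mother's phylogeny color with a small random mutation in color
space, so lineages can be traced in colony snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from colisim.engine import Process, VariableSchema


@dataclass
class GrowthState:
    mass: float  # fg
    doubling_time: float = 2400.0  # s (~40 min)
    division_threshold: float = 2000.0  # fg
    phylogeny_color: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.5, 0.5])
    )

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.division_threshold <= 0:
            raise ValueError("division threshold must be > 0")


def grow_mass(mass: float, doubling_time: float, dt: float) -> float:
    """Exponential growth: mass * 2^(dt / doubling_time)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return mass * 2.0 ** (dt / doubling_time)


def mutate_color(color, rng, sigma: float = 0.08) -> np.ndarray:
    """Isotropic Gaussian step in color space, clipped to [0, 1]."""
    return np.clip(np.asarray(color, dtype=float) + rng.normal(0, sigma, 3), 0, 1)


def maybe_divide(state: GrowthState, rng) -> Optional[dict]:
    """Return a divide topology message if mass has reached the threshold."""
    if state.mass >= state.division_threshold:
        return {"type": "divide"}
    return None


class Division(Process):
    """Mass-threshold division check for agents whose growth lives in
    another process (e.g. dFBA metabolism setting boundary mass)."""

    defaults = {
        "time_step": 1.0,
        "threshold_fg": 2000.0,
        "agent_path": ("agents", "cell"),
    }

    def ports_schema(self):
        return {
            "boundary": {
                "mass": VariableSchema(
                    default=1000.0, units="fg", updater="set", divider="halve"
                )
            }
        }

    def next_update(self, states, timestep):
        if states["boundary"]["mass"] >= self.parameters["threshold_fg"]:
            return {
                "_topology": {
                    "type": "divide",
                    "path": tuple(self.parameters["agent_path"]),
                }
            }
        return {}


class GrowDivide(Process):
    """Engine process: grow each step, divide at the threshold.

    The division check runs once per time-step (default 1.0 s), so mass
    may overshoot the threshold by up to one step's growth. Mass uses the
    ``halve`` divider so daughters exactly conserve the mother's mass;
    length halves with it so geometry tracks content.
    """

    defaults = {
        "time_step": 1.0,
        "initial_mass_fg": 1000.0,
        "doubling_time_s": 2400.0,
        "threshold_fg": 2000.0,
        "color_mutation_sigma": 0.08,
        "agent_path": ("agents", "cell"),
        "divide_enabled": True,
        # set by the composer for daughter agents: perturb the inherited
        # lineage color once, on the first step after division
        "mutate_color_on_start": False,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self._color_pending = bool(self.parameters["mutate_color_on_start"])

    def ports_schema(self):
        return {
            "boundary": {
                "mass": VariableSchema(
                    default=self.parameters["initial_mass_fg"],
                    units="fg",
                    updater="set",
                    divider="halve",
                    emit=True,
                ),
                "length": VariableSchema(
                    default=2.0, units="um", updater="set", divider="halve"
                ),
                "color": VariableSchema(
                    default=[0.5, 0.5, 0.5],
                    units="dimensionless",
                    updater="set",
                    divider="copy",
                    emit=True,
                ),
            }
        }

    def next_update(self, states, timestep):
        boundary = states["boundary"]
        mass = boundary["mass"]
        if self.parameters["divide_enabled"] and mass >= self.parameters["threshold_fg"]:
            return {
                "_topology": {
                    "type": "divide",
                    "path": tuple(self.parameters["agent_path"]),
                },
            }
        new_mass = grow_mass(mass, self.parameters["doubling_time_s"], timestep)
        # geometry grows with mass at fixed width: length tracks mass
        length = boundary["length"] * new_mass / mass if mass > 0 else boundary["length"]
        update = {"boundary": {"mass": new_mass, "length": length}}
        if self._color_pending:
            update["boundary"]["color"] = list(
                mutate_color(
                    boundary["color"], self.rng,
                    self.parameters["color_mutation_sigma"],
                )
            )
            self._color_pending = False
        return update
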