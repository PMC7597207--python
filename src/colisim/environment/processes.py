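"""Environment processes wiring the physics and field mechanics to stores.

The environment compartment runs two processes: ``Multibody`` advances
all agent bodies (reading thrust/torque from each agent's boundary store
and writing back location/orientation), and ``Diffusion`` steps the
molecular fields, applies each agent's exchange fluxes to its containing
bin, and refreshes each agent's local external concentrations.
"""

from __future__ import annotations

import numpy as np

from colisim.engine import Process, VariableSchema
from colisim.environment.bodies import AgentBody, PhysicsConfig, step_multibody
from colisim.environment.fields import Field, agent_field_exchange, diffuse_field


def boundary_schema(emit_location: bool = True) -> dict:
    """Schema of an agent's boundary store as seen by the environment."""
    return {
        "location": VariableSchema(
            default=[0.0, 0.0], units="um", updater="set", divider="copy",
            emit=emit_location,
        ),
        "orientation": VariableSchema(
            default=0.0, units="radians", updater="set", divider="copy"
        ),
        "length": VariableSchema(default=2.0, units="um", updater="set", divider="halve"),
        "width": VariableSchema(default=1.0, units="um", updater="set", divider="copy"),
        "mass": VariableSchema(
            default=1000.0, units="fg", updater="set", divider="halve", emit=True
        ),
        "thrust": VariableSchema(default=0.0, units="pN", updater="set", divider="copy"),
        "torque": VariableSchema(
            default=0.0, units="pN um", updater="set", divider="copy"
        ),
        "force_angle": VariableSchema(
            default=0.0, units="radians", updater="set", divider="copy"
        ),
        "exchange": {
            "*": VariableSchema(
                default=0.0, units="mmol", updater="accumulate", divider="halve"
            )
        },
        "external": {
            "*": VariableSchema(
                default=0.0, units="mM", updater="set", divider="copy"
            )
        },
    }


class Multibody(Process):
    """Rigid-body mechanics over every agent in the environment."""

    defaults = {
        "time_step": 0.01,
        "translational_damping": 0.033707,  # pN s/um
        "rotational_damping": 0.08,  # pN um s/rad
        "jitter_force": 0.002,  # pN
        "bounds": (2500.0, 2500.0),  # um
    }

    def ports_schema(self):
        return {"agents": {"*": {"boundary": boundary_schema()}}}

    def next_update(self, states, timestep):
        agents = states["agents"]
        if not agents:
            return {}
        names = sorted(agents)
        bodies = []
        for name in names:
            b = agents[name]["boundary"]
            bodies.append(
                AgentBody(
                    location=np.array(b["location"], dtype=float),
                    orientation=float(b["orientation"]),
                    length=float(b["length"]),
                    width=float(b["width"]),
                    mass=float(b["mass"]),
                    thrust=float(b["thrust"]),
                    torque=float(b["torque"]),
                    force_angle=float(b["force_angle"]),
                )
            )
        config = PhysicsConfig(
            translational_damping=self.parameters["translational_damping"],
            rotational_damping=self.parameters["rotational_damping"],
            jitter_force=self.parameters["jitter_force"],
            dt=timestep,
            bounds=tuple(self.parameters["bounds"]),
        )
        step_multibody(bodies, config, self.rng)
        return {
            "agents": {
                name: {
                    "boundary": {
                        "location": [float(x) for x in body.location],
                        "orientation": float(body.orientation),
                    }
                }
                for name, body in zip(names, bodies)
            }
        }


class Diffusion(Process):
    """Field diffusion plus agent local-environment exchange.

    Parameters carry the field geometry and per-species diffusion
    coefficients; the concentration grids themselves live in the
    ``fields`` store so other processes (and the emitter) can see them.
    """

    defaults = {
        "time_step": 1.0,
        "bounds": (2500.0, 2500.0),
        "n_bins": (1, 1),
        "depth": 1.0,
        "diffusion": {},  # species -> um^2/s
        "substeps": 1,  # explicit substeps per engine step, for stability
        "emit_fields": False,
    }

    def ports_schema(self):
        return {
            "fields": {
                "*": VariableSchema(
                    default=np.zeros(tuple(self.parameters["n_bins"])),
                    units="mM",
                    updater="set",
                    divider="copy",
                    emit=bool(self.parameters["emit_fields"]),
                )
            },
            "agents": {"*": {"boundary": boundary_schema()}},
        }

    def next_update(self, states, timestep):
        grids = {
            name: np.array(grid, dtype=float)
            for name, grid in states["fields"].items()
        }
        fld = Field(
            bounds=tuple(self.parameters["bounds"]),
            n_bins=tuple(self.parameters["n_bins"]),
            concentrations=grids,
            diffusion=dict(self.parameters["diffusion"]),
            depth=self.parameters["depth"],
        )
        substeps = int(self.parameters["substeps"])
        for _ in range(substeps):
            diffuse_field(fld, timestep / substeps)
        agents = states["agents"]
        names = sorted(agents)
        locations = [agents[n]["boundary"]["location"] for n in names]
        exchanges = [dict(agents[n]["boundary"].get("exchange", {})) for n in names]
        fld, locals_out, _short = agent_field_exchange(fld, locations, exchanges)
        update = {
            "fields": {name: grid for name, grid in fld.concentrations.items()},
            "agents": {},
        }
        for name, local, exchange in zip(names, locals_out, exchanges):
            update["agents"][name] = {
                "boundary": {
                    "external": local,
                    # consume the exchange flux we just applied
                    "exchange": {sp: -val for sp, val in exchange.items()},
                }
            }
        return update
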