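"""Composite builders for the package's integrated experiments.

Four registered experiments, each a compartment hierarchy with an
environment (multibody physics + diffusing fields) containing agent
compartments whose internal processes share boundary stores with the
environment:

- ``grow_divide``: minimal exponential-growth agents that divide at
  2000 fg and mutate a lineage color.
- ``diauxie``: transport + dFBA metabolism + minimal LacY expression on
  the packaged glucose/lactose toy network.
- ``flagella_expression``: stochastic transcription / translation /
  complexation / degradation of the seven-operon flagellar network.
- ``chemotaxis``: PMF + chemoreceptor + flagellar activity driving a
  capsule body in a uniform or exponential MeAsp field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from colisim.engine import Experiment
from colisim.environment import Diffusion, Multibody, make_gradient_field
from colisim.chemotaxis import (
    Chemoreceptor,
    FlagellarActivity,
    ProtonMotiveForce,
    ReceptorCluster,
    adapted_methylation,
)
from colisim.gene_expression import (
    Complexation,
    Degradation,
    FLAGELLAR_COMPLEXATION,
    Transcription,
    Translation,
    ample_pools,
    flagellar_chromosome,
)
from colisim.growth_division import Division, GrowDivide
from colisim.metabolism import LacYExpression, Metabolism, Transport

EXPERIMENTS = ("grow_divide", "diauxie", "flagella_expression", "chemotaxis")

FLGM_EXPORT_RULE = {
    "trigger": "basal_body",
    "threshold": 1,
    "export": "FlgM",
    "complex": "FliA_FlgM",
    "release": "FliA",
}


class ExperimentConfigError(Exception):
    pass


@dataclass
class ExperimentConfig:
    name: str
    n_agents: int = 1
    total_time: float = 100.0
    seed: int = 0
    emit_interval: float = 1.0
    bounds: tuple[float, float] = (2500.0, 2500.0)
    # chemotaxis options
    field_shape: str = "uniform"  # or "exponential"
    ligand: str = "MeAsp"
    base_concentration: float = 0.05  # mM
    length_scale: float = 150.0  # um, exponential gradient
    n_flagella: int = 4
    receptorless_fraction: float = 0.0  # fraction of agents with dead receptors
    start_location: Optional[tuple[float, float]] = None
    physics: dict = field(default_factory=dict)
    # diauxie options
    glucose_mM: float = 1.0
    lactose_mM: float = 5.0
    enable_division: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ExperimentConfigError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}"
            )


def _spread_locations(config: ExperimentConfig) -> list[list[float]]:
    cx, cy = (
        config.start_location
        if config.start_location is not None
        else (config.bounds[0] / 2, config.bounds[1] / 2)
    )
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_agents):
        jitter = rng.uniform(-1.0, 1.0, size=2) if config.n_agents > 1 else [0, 0]
        out.append([cx + float(jitter[0]), cy + float(jitter[1])])
    return out


# -- grow/divide -----------------------------------------------------------


def build_grow_divide(config: ExperimentConfig) -> Experiment:
    def composer(agent_id, agent_path, seed):
        name = f"{agent_id}/growth"
        proc = GrowDivide(
            {
                "agent_path": agent_path,
                "mutate_color_on_start": "." in agent_id,
            }
        )
        return {name: proc}, {name: {"boundary": tuple(agent_path) + ("boundary",)}}

    processes = {
        "env/multibody": Multibody(
            {"time_step": 1.0, "bounds": config.bounds, **config.physics}
        )
    }
    topology = {"env/multibody": {"agents": ("agents",)}}
    initial_state: dict = {"agents": {}}
    locations = _spread_locations(config)
    agent_ids = [f"cell{i}" for i in range(config.n_agents)]
    for aid, loc in zip(agent_ids, locations):
        procs, topo = composer(aid, ("agents", aid), config.seed)
        processes.update(procs)
        topology.update(topo)
        initial_state["agents"][aid] = {"boundary": {"location": loc}}
    experiment = Experiment(
        processes,
        topology,
        initial_state,
        emit_interval=config.emit_interval,
        seed=config.seed,
    )
    for aid in agent_ids:
        experiment.register_composer(
            ("agents", aid), composer, [f"{aid}/growth"]
        )
    return experiment


# -- diauxie ---------------------------------------------------------------


def build_diauxie(config: ExperimentConfig) -> Experiment:
    bounds = (50.0, 50.0)
    depth = 0.8  # 50 x 50 x 0.8 um^3 = 2000 um^3 = 2e-12 L single bin
    bin_volume_l = bounds[0] * bounds[1] * depth * 1e-15

    def composer(agent_id, agent_path, seed):
        base = tuple(agent_path)
        procs = {
            f"{agent_id}/transport": Transport({}),
            f"{agent_id}/metabolism": Metabolism(
                {"bin_volume_l": bin_volume_l}
            ),
            f"{agent_id}/lacy": LacYExpression({}),
        }
        topo = {
            f"{agent_id}/transport": {
                "proteins": base + ("proteins",),
                "fluxes": base + ("fluxes",),
                "boundary": base + ("boundary",),
            },
            f"{agent_id}/metabolism": {
                "pools": base + ("pools",),
                "fluxes": base + ("fluxes",),
                "boundary": base + ("boundary",),
            },
            f"{agent_id}/lacy": {
                "rna": base + ("rna",),
                "proteins": base + ("proteins",),
                "boundary": base + ("boundary",),
            },
        }
        if config.enable_division:
            procs[f"{agent_id}/division"] = Division({"agent_path": agent_path})
            topo[f"{agent_id}/division"] = {"boundary": base + ("boundary",)}
        return procs, topo

    processes = {
        "env/multibody": Multibody({"time_step": 1.0, "bounds": bounds}),
        "env/diffusion": Diffusion(
            {
                "time_step": 1.0,
                "bounds": bounds,
                "n_bins": (1, 1),
                "depth": depth,
                "diffusion": {"glc": 0.0, "lac": 0.0},
                "emit_fields": True,
            }
        ),
    }
    topology = {
        "env/multibody": {"agents": ("agents",)},
        "env/diffusion": {"fields": ("fields",), "agents": ("agents",)},
    }
    initial_state: dict = {
        "fields": {
            "glc": np.full((1, 1), config.glucose_mM),
            "lac": np.full((1, 1), config.lactose_mM),
        },
        "agents": {},
    }
    rng = np.random.default_rng(config.seed)
    agent_ids = [f"cell{i}" for i in range(config.n_agents)]
    for i, aid in enumerate(agent_ids):
        procs, topo = composer(aid, ("agents", aid), config.seed)
        processes.update(procs)
        topology.update(topo)
        initial_state["agents"][aid] = {
            "boundary": {
                "location": [
                    float(rng.uniform(10, 40)), float(rng.uniform(10, 40))
                ],
                "external": {"glc": config.glucose_mM, "lac": config.lactose_mM},
            }
        }
    experiment = Experiment(
        processes,
        topology,
        initial_state,
        emit_interval=config.emit_interval,
        seed=config.seed,
    )
    names = ("transport", "metabolism", "lacy") + (
        ("division",) if config.enable_division else ()
    )
    for aid in agent_ids:
        experiment.register_composer(
            ("agents", aid), composer, [f"{aid}/{p}" for p in names]
        )
    return experiment


# -- flagellar expression --------------------------------------------------


def build_flagella_expression(config: ExperimentConfig) -> Experiment:
    chromosome = flagellar_chromosome()

    def composer(agent_id, agent_path, seed):
        base = tuple(agent_path)
        procs = {
            f"{agent_id}/transcription": Transcription({"chromosome": chromosome}),
            f"{agent_id}/translation": Translation({"chromosome": chromosome}),
            f"{agent_id}/complexation": Complexation(
                {
                    "reactions": FLAGELLAR_COMPLEXATION,
                    "export_rule": FLGM_EXPORT_RULE,
                }
            ),
            f"{agent_id}/degradation": Degradation({"chromosome": chromosome}),
        }
        topo = {
            f"{agent_id}/transcription": {
                "pools": base + ("pools",),
                "transcripts": base + ("rna",),
                "tf": base + ("proteins",),
            },
            f"{agent_id}/translation": {
                "pools": base + ("pools",),
                "transcripts": base + ("rna",),
                "proteins": base + ("proteins",),
            },
            f"{agent_id}/complexation": {"molecules": base + ("proteins",)},
            f"{agent_id}/degradation": {
                "pools": base + ("pools",),
                "transcripts": base + ("rna",),
            },
        }
        return procs, topo

    processes: dict = {}
    topology: dict = {}
    initial_state: dict = {"agents": {}}
    agent_ids = [f"cell{i}" for i in range(config.n_agents)]
    for aid in agent_ids:
        procs, topo = composer(aid, ("agents", aid), config.seed)
        processes.update(procs)
        topology.update(topo)
        initial_state["agents"][aid] = {"pools": ample_pools()}
    experiment = Experiment(
        processes,
        topology,
        initial_state,
        emit_interval=config.emit_interval,
        seed=config.seed,
    )
    return experiment


# -- chemotaxis ------------------------------------------------------------


def build_chemotaxis(config: ExperimentConfig) -> Experiment:
    fld = make_gradient_field(
        config.field_shape,
        bounds=config.bounds,
        n_bins=(1, 1) if config.field_shape == "uniform" else (1, 200),
        species=config.ligand,
        base_concentration=config.base_concentration,
        length_scale=config.length_scale,
        origin_y=(
            config.start_location[1]
            if config.start_location is not None
            else config.bounds[1] / 2
        ),
    )
    n_receptorless = int(round(config.n_agents * config.receptorless_fraction))

    def make_composer(receptors_active):
        def composer(agent_id, agent_path, seed):
            base = tuple(agent_path)
            procs = {
                f"{agent_id}/pmf": ProtonMotiveForce({}),
                f"{agent_id}/receptor": Chemoreceptor(
                    {"ligand": config.ligand}
                ),
                f"{agent_id}/flagella": FlagellarActivity(
                    {"receptors_active": receptors_active}
                ),
            }
            topo = {
                f"{agent_id}/pmf": {"membrane": base + ("membrane",)},
                f"{agent_id}/receptor": {
                    "internal": base + ("internal",),
                    "boundary": base + ("boundary",),
                },
                f"{agent_id}/flagella": {
                    "internal": base + ("internal",),
                    "flagella": base + ("flagella",),
                    "membrane": base + ("membrane",),
                    "boundary": base + ("boundary",),
                },
            }
            return procs, topo

        return composer

    processes = {
        "env/multibody": Multibody(
            {"time_step": 0.01, "bounds": config.bounds, **config.physics}
        ),
    }
    topology = {"env/multibody": {"agents": ("agents",)}}
    if config.field_shape != "uniform":
        processes["env/diffusion"] = Diffusion(
            {
                "time_step": 0.01,
                "bounds": config.bounds,
                "n_bins": fld.n_bins,
                "diffusion": {config.ligand: 0.0},  # frozen gradient
            }
        )
        topology["env/diffusion"] = {
            "fields": ("fields",),
            "agents": ("agents",),
        }
    initial_state: dict = {
        "fields": {config.ligand: fld.concentrations[config.ligand]},
        "agents": {},
    }
    locations = _spread_locations(config)
    agent_ids = []
    for i in range(config.n_agents):
        receptors_active = i >= n_receptorless
        aid = ("motor" if not receptors_active else "cell") + str(i)
        agent_ids.append(aid)
        composer = make_composer(receptors_active)
        procs, topo = composer(aid, ("agents", aid), config.seed)
        processes.update(procs)
        topology.update(topo)
        x, y = locations[i]
        local = float(
            fld.concentrations[config.ligand][fld.bin_of((x, y))]
        )
        initial_state["agents"][aid] = {
            "boundary": {
                "location": [x, y],
                "orientation": float(
                    np.random.default_rng(config.seed + i).uniform(
                        -math.pi, math.pi
                    )
                ),
                "external": {config.ligand: local},
            },
            "internal": {
                # start adapted to the ambient concentration so motility
                # reflects baseline behavior from t = 0
                "methylation": adapted_methylation(ReceptorCluster(), local),
            },
            "flagella": {
                f"f{k}": {"rotation": "CCW"}
                for k in range(config.n_flagella)
            },
        }
    return Experiment(
        processes,
        topology,
        initial_state,
        emit_interval=config.emit_interval,
        seed=config.seed,
    )


_BUILDERS = {
    "grow_divide": build_grow_divide,
    "diauxie": build_diauxie,
    "flagella_expression": build_flagella_expression,
    "chemotaxis": build_chemotaxis,
}


def build_experiment(config: ExperimentConfig) -> Experiment:
    """Construct the named composite, ready for ``Experiment.run``."""
    return _BUILDERS[config.name](config)
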