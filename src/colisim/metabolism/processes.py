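"""Engine processes coupling transport, metabolism, and LacY expression.

Transport computes convenience-kinetics fluxes from transporter counts
and the agent's local external concentrations, and pins them into the
flux store. Metabolism re-solves FBA each step under those constraints,
deposits the biomass composition into the internal metabolite pools,
books the exchange against the environment, and sets the agent's mass
to the pooled mass. Both run at a 1.0 s time-step.
"""

from __future__ import annotations

from colisim.engine import Process, VariableSchema
from colisim.metabolism.dfba import COUNT_MMOL, biomass_from_pools, dfba_step
from colisim.metabolism.expression import LacYExpressionState, lacY_expression_step
from colisim.metabolism.kinetics import KineticReaction, transport_step
from colisim.metabolism.network import MetabolicNetwork
from colisim.metabolism.toy import (
    TOY_INITIAL_POOLS,
    TOY_PROTEINS,
    toy_network,
    toy_transport_reactions,
)


def _count_schema(default=0.0, emit=False):
    return VariableSchema(
        default=default, units="counts", updater="accumulate",
        divider="halve", emit=emit,
    )


class Transport(Process):
    """Kinetic transport: writes equality flux constraints for FBA."""

    defaults = {
        "time_step": 1.0,
        "reactions": None,  # list[KineticReaction]; default: toy sugars
        "initial_proteins": None,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self.reactions: list[KineticReaction] = (
            self.parameters["reactions"] or toy_transport_reactions()
        )
        self.initial_proteins = dict(
            self.parameters["initial_proteins"] or TOY_PROTEINS
        )

    def ports_schema(self):
        return {
            "proteins": {
                name: _count_schema(default=count, emit=True)
                for name, count in self.initial_proteins.items()
            },
            "fluxes": {
                rxn.id: VariableSchema(
                    default=0.0, units="counts/s", updater="set", divider="copy"
                )
                for rxn in self.reactions
            },
            "boundary": {
                "external": {
                    "*": VariableSchema(
                        default=0.0, units="mM", updater="set", divider="copy"
                    )
                }
            },
        }

    def next_update(self, states, timestep):
        constraints = transport_step(
            self.reactions,
            states["proteins"],
            states["boundary"]["external"],
        )
        return {"fluxes": {rid: lb for rid, (lb, _ub) in constraints.items()}}


class Metabolism(Process):
    """Dynamic FBA constrained by the flux store."""

    defaults = {
        "time_step": 1.0,
        "network": None,  # MetabolicNetwork; default toy
        "initial_pools": None,
        # local-environment bin volume; at mM concentrations a bin must
        # hold picomole-scale sugar for 1000-fg-scale growth to register
        "bin_volume_l": 2e-12,
        "count_mmol": COUNT_MMOL,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self.network: MetabolicNetwork = self.parameters["network"] or toy_network()
        self.initial_pools = dict(self.parameters["initial_pools"] or TOY_INITIAL_POOLS)

    def ports_schema(self):
        pool_species = set(self.initial_pools) | set(self.network.objective)
        return {
            "pools": {
                species: _count_schema(
                    default=self.initial_pools.get(species, 0.0), emit=True
                )
                for species in sorted(pool_species)
            },
            "fluxes": {
                rid: VariableSchema(
                    default=0.0, units="counts/s", updater="set", divider="copy"
                )
                for rid in self.network.exchange_reactions
            },
            "boundary": {
                "mass": VariableSchema(
                    default=1000.0, units="fg", updater="set", divider="halve",
                    emit=True,
                ),
                "external": {
                    "*": VariableSchema(
                        default=0.0, units="mM", updater="set", divider="copy"
                    )
                },
                "exchange": {
                    "*": VariableSchema(
                        default=0.0, units="mmol", updater="accumulate",
                        divider="halve",
                    )
                },
                "growth_rate": VariableSchema(
                    default=0.0, units="fg/s", updater="set", divider="copy",
                    emit=True,
                ),
            },
        }

    def next_update(self, states, timestep):
        pools = states["pools"]
        constraints = {
            rid: (flux, flux) for rid, flux in states["fluxes"].items()
        }
        pool_deltas, env_deltas, mass_delta, _result = dfba_step(
            self.network,
            pools,
            states["boundary"]["external"],
            constraints,
            timestep,
            bin_volume_l=self.parameters["bin_volume_l"],
            count_mmol=self.parameters["count_mmol"],
        )
        new_pools = dict(pools)
        for species, delta in pool_deltas.items():
            new_pools[species] = new_pools.get(species, 0.0) + delta
        mass = biomass_from_pools(new_pools, self.network.molecular_weights)
        return {
            "pools": pool_deltas,
            "boundary": {
                "mass": mass,
                "exchange": env_deltas,
                "growth_rate": mass_delta / timestep,
            },
        }


class LacYExpression(Process):
    """Minimal stochastic-ODE expression of the lactose transporter."""

    defaults = {
        "time_step": 1.0,
        "glucose_species": "glc",
        "state": None,  # LacYExpressionState overrides
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        overrides = self.parameters["state"] or {}
        self.model = LacYExpressionState(**overrides)

    def ports_schema(self):
        return {
            "rna": {
                "lacY_mRNA": _count_schema(emit=True),
            },
            "proteins": {
                "LacY": _count_schema(emit=True),
            },
            "boundary": {
                "external": {
                    "*": VariableSchema(
                        default=0.0, units="mM", updater="set", divider="copy"
                    )
                }
            },
        }

    def next_update(self, states, timestep):
        self.model.lacY_mRNA = states["rna"]["lacY_mRNA"]
        self.model.LacY_protein = states["proteins"]["LacY"]
        glucose = states["boundary"]["external"].get(
            self.parameters["glucose_species"], 0.0
        )
        dm, dp = lacY_expression_step(self.model, glucose, timestep, self.rng)
        return {
            "rna": {"lacY_mRNA": dm},
            "proteins": {"LacY": dp},
        }
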