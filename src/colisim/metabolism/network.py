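"""Stoichiometric metabolic networks and flux balance analysis.

A :class:`MetabolicNetwork` holds reactions (stoichiometry maps), flux
bounds, an exchange subset crossing the compartment boundary, and a
biomass objective given as a composition map (metabolite -> coefficient).
FBA maximizes the flux of an implicit biomass reaction that drains the
objective metabolites from the steady-state network; that flux times the
composition is what lands in the cell's internal metabolite pools.

Flux sign convention: positive exchange flux imports the metabolite into
the network (uptake); negative exports (secretion).

The LP is solved with the HiGHS solver via scipy.optimize.linprog, which
is deterministic for a fixed problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import linprog

BIOMASS_ID = "BIOMASS"
DEFAULT_BOUND = 1000.0


class NetworkError(Exception):
    pass


@dataclass
class MetabolicNetwork:
    """A stoichiometric LP problem plus mass-accounting metadata."""

    reactions: dict[str, dict[str, float]]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)  # biomass composition
    exchange_reactions: dict[str, str] = field(default_factory=dict)  # rid -> species
    molecular_weights: dict[str, float] = field(default_factory=dict)  # fg per count

    def __post_init__(self):
        if not self.objective:
            raise NetworkError("objective (biomass composition) must be nonempty")
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise NetworkError(f"bounds for {rid!r}: lower > upper")
        for rid in self.exchange_reactions:
            if rid not in self.reactions:
                raise NetworkError(f"exchange reaction {rid!r} not in network")

    @property
    def metabolites(self) -> list[str]:
        mets = set()
        for stoich in self.reactions.values():
            mets.update(stoich)
        mets.update(self.objective)
        return sorted(mets)

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reactions": self.reactions,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "objective": self.objective,
            "exchange_reactions": self.exchange_reactions,
            "molecular_weights": self.molecular_weights,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicNetwork":
        payload = json.loads(Path(path).read_text())
        return cls(
            reactions=payload["reactions"],
            bounds={k: tuple(v) for k, v in payload["bounds"].items()},
            objective=payload["objective"],
            exchange_reactions=payload.get("exchange_reactions", {}),
            molecular_weights=payload.get("molecular_weights", {}),
        )


@dataclass
class FBAResult:
    fluxes: dict[str, float]
    objective_value: float
    feasible: bool


def solve_fba(
    network: MetabolicNetwork,
    constraints: Optional[dict[str, tuple[float, float]]] = None,
) -> FBAResult:
    """Maximize biomass flux subject to S v = 0 and flux bounds.

    ``constraints`` (e.g. transport-imposed exchange bounds) override the
    network's structural bounds for the listed reactions. Infeasibility
    is reported explicitly so callers can shut growth to zero.
    """
    constraints = constraints or {}
    rids = network.reaction_ids()
    mets = network.metabolites
    met_index = {m: i for i, m in enumerate(mets)}
    n_rxn = len(rids) + 1  # + implicit biomass drain
    s_matrix = np.zeros((len(mets), n_rxn))
    for j, rid in enumerate(rids):
        for met, coeff in network.reactions[rid].items():
            s_matrix[met_index[met], j] = coeff
    biomass_col = len(rids)
    for met, coeff in network.objective.items():
        s_matrix[met_index[met], biomass_col] -= coeff

    lp_bounds = []
    for rid in rids:
        lb, ub = network.bounds.get(rid, (-DEFAULT_BOUND, DEFAULT_BOUND))
        if rid in constraints:
            lb, ub = constraints[rid]
        lp_bounds.append((lb, ub))
    lp_bounds.append((0.0, DEFAULT_BOUND))

    cost = np.zeros(n_rxn)
    cost[biomass_col] = -1.0  # maximize biomass flux
    result = linprog(
        cost,
        A_eq=s_matrix,
        b_eq=np.zeros(len(mets)),
        bounds=lp_bounds,
        method="highs",
    )
    if not result.success:
        return FBAResult(fluxes={}, objective_value=0.0, feasible=False)
    fluxes = {rid: float(result.x[j]) for j, rid in enumerate(rids)}
    return FBAResult(
        fluxes=fluxes,
        objective_value=float(result.x[biomass_col]),
        feasible=True,
    )


def load_bigg_json(path: str | Path, objective_composition=None) -> MetabolicNetwork:
    """Optional adapter: load a BiGG-style JSON model through cobra.

    Requires the ``cobra`` package and a downloaded model file; used for
    genome-scale runs, not by the packaged test fixtures. BiGG exchange
    convention (negative flux = uptake) is flipped to this module's
    uptake-positive convention.
    """
    import cobra.io  # deferred: optional dependency

    model = cobra.io.load_json_model(str(path))
    return _from_cobra(model, objective_composition)


def load_sbml(path: str | Path, objective_composition=None) -> MetabolicNetwork:
    """Optional adapter: load an SBML model through cobra."""
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    return _from_cobra(model, objective_composition)


def _from_cobra(model, objective_composition=None) -> MetabolicNetwork:
    reactions = {}
    bounds = {}
    exchange = {}
    weights = {}
    objective = objective_composition or {}
    for rxn in model.reactions:
        if rxn.objective_coefficient and not objective_composition:
            # use the model's biomass composition: reactants with their
            # stoichiometric demand per unit biomass flux
            objective = {
                met.id: -coeff
                for met, coeff in rxn.metabolites.items()
                if coeff < 0
            }
            continue
        stoich = {met.id: coeff for met, coeff in rxn.metabolites.items()}
        if rxn in model.exchanges:
            # flip: BiGG exchanges are written "met <->" (uptake negative)
            stoich = {m: -c for m, c in stoich.items()}
            reactions[rxn.id] = stoich
            bounds[rxn.id] = (-rxn.upper_bound, -rxn.lower_bound)
            exchange[rxn.id] = next(iter(stoich))
        else:
            reactions[rxn.id] = stoich
            bounds[rxn.id] = (rxn.lower_bound, rxn.upper_bound)
    for met in model.metabolites:
        if met.formula_weight:
            # g/mol numerically equals fg/count at the package's
            # 1e-12 mmol-per-count lumping
            weights[met.id] = float(met.formula_weight)
    if not objective:
        raise NetworkError("model has no biomass objective")
    return MetabolicNetwork(
        reactions=reactions,
        bounds=bounds,
        objective=objective,
        exchange_reactions=exchange,
        molecular_weights=weights,
    )
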