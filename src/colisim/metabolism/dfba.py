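"""Dynamic FBA stepping and pool mass accounting.

Counts are lumped units: one count of a species is 1e-12 mmol (~6e8
molecules), chosen so a molecular weight in g/mol numerically equals
fg per count. That keeps environment concentrations (mM in femtoliter-
scale bins) and cell masses (1000-2000 fg) on the same books with exact
mass conservation: environment mass loss equals cell mass gain.
"""

from __future__ import annotations

from typing import Optional

from colisim.metabolism.network import FBAResult, MetabolicNetwork, solve_fba

COUNT_MMOL = 1e-12  # mmol per lumped count


class PoolError(Exception):
    pass


def biomass_from_pools(
    pools: dict[str, float], weights: dict[str, float]
) -> float:
    """Total mass in fg: sum of counts times molecular weight."""
    total = 0.0
    for species, count in pools.items():
        if species not in weights:
            raise PoolError(f"no molecular weight for pooled species {species!r}")
        total += count * weights[species]
    return total


def dfba_step(
    network: MetabolicNetwork,
    pools: dict[str, float],
    local_env: dict[str, float],  # mM per external species
    constraints: dict[str, tuple[float, float]],
    dt: float,
    bin_volume_l: float,
    count_mmol: float = COUNT_MMOL,
) -> tuple[dict[str, float], dict[str, float], float, FBAResult]:
    """One dynamic-FBA step.

    Returns (pool deltas in counts, environment exchange deltas in mmol,
    mass delta in fg, raw FBA result). Uptake is capped by local
    availability before solving, so the optimum never overdraws the bin;
    an infeasible LP yields a zero-growth step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    effective = dict(constraints)
    for rid, species in network.exchange_reactions.items():
        lb, ub = effective.get(
            rid, network.bounds.get(rid, (0.0, 0.0))
        )
        available_mmol = local_env.get(species, 0.0) * bin_volume_l
        cap = available_mmol / count_mmol / dt  # counts/s uptake limit
        ub = min(ub, cap)
        lb = min(lb, ub)
        effective[rid] = (lb, ub)
    result = solve_fba(network, effective)
    if not result.feasible or result.objective_value <= 0:
        return {}, {}, 0.0, result
    growth = result.objective_value
    pool_deltas = {
        met: coeff * growth * dt for met, coeff in network.objective.items()
    }
    env_deltas = {}
    for rid, species in network.exchange_reactions.items():
        flux = result.fluxes.get(rid, 0.0)
        if flux != 0.0:
            # positive flux = uptake = mmol leaving the environment
            env_deltas[species] = env_deltas.get(species, 0.0) - flux * dt * count_mmol
    mass_delta = biomass_from_pools(pool_deltas, network.molecular_weights)
    return pool_deltas, env_deltas, mass_delta, result
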