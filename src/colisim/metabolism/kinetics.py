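"""Convenience kinetics: generalized Michaelis-Menten rate laws.

The convenience-kinetics form handles any number of substrates,
cofactors, and competitive inhibitors with one expression per reaction:

    rate = kcat * E * prod_s [ (s/Km_s) / (1 + s/Km_s + sum_i I_i/Ki_i) ]

For a single substrate with no inhibitors this reduces exactly to
Michaelis-Menten: kcat * E * S / (Km + S).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class KineticReaction:
    """One transport or catalytic reaction with its kinetic parameters."""

    id: str
    substrates: dict[str, float]  # metabolite -> Km (mM)
    enzyme: str  # protein id supplying E (counts)
    kcat: float  # per enzyme per second
    cofactors: dict[str, float] = field(default_factory=dict)  # metabolite -> Km
    competitors: dict[str, float] = field(default_factory=dict)  # metabolite -> Ki

    def __post_init__(self):
        if self.kcat < 0:
            raise ValueError("kcat must be >= 0")
        for km in list(self.substrates.values()) + list(self.cofactors.values()):
            if km <= 0:
                raise ValueError("all Km must be > 0")
        for ki in self.competitors.values():
            if ki <= 0:
                raise ValueError("all Ki must be > 0")


def convenience_rate(
    reaction: KineticReaction,
    concentrations: dict[str, float],
    enzyme_count: float,
) -> float:
    """Evaluate the convenience-kinetics rate (units of kcat * E)."""
    inhibition = sum(
        concentrations.get(met, 0.0) / ki
        for met, ki in reaction.competitors.items()
    )
    rate = reaction.kcat * enzyme_count
    for met, km in {**reaction.substrates, **reaction.cofactors}.items():
        s = concentrations.get(met, 0.0) / km
        rate *= s / (1.0 + s + inhibition)
    return rate


def transport_step(
    reactions: list[KineticReaction],
    protein_counts: dict[str, float],
    local_env: dict[str, float],
    internal: dict[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Compute transport fluxes and pin them as equality flux constraints.

    Each reaction's flux is written as both lower and upper bound for the
    matching exchange reaction, so the downstream FBA problem is limited
    to exactly what transport supplies.
    """
    concentrations = dict(local_env)
    if internal:
        concentrations.update(internal)
    constraints = {}
    for reaction in reactions:
        if reaction.enzyme not in protein_counts:
            raise KeyError(
                f"transporter {reaction.enzyme!r} missing from protein store"
            )
        flux = convenience_rate(
            reaction, concentrations, protein_counts[reaction.enzyme]
        )
        constraints[reaction.id] = (flux, flux)
    return constraints
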