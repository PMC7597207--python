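"""Minimal stochastic-ODE LacY expression (catabolite repression).

This is the coarse gene-expression stand-in used alongside dFBA before
the sequence-based machinery takes over: lacY transcription is
repressed by the glucose signal through a Hill function, mRNA decays
first-order, protein synthesis is proportional to mRNA, protein is
lost only to growth dilution, and both species carry a
chemical-Langevin noise term scaled to sqrt(rate * dt). Counts are
clamped at zero.

Parameter defaults are calibrated (not literature-printed) so that in
the toy diauxie the lag phase lasts a few hundred seconds and the
expressed LacY level then supports lactose growth.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class LacYExpressionState:
    lacY_mRNA: float = 0.0
    LacY_protein: float = 0.0
    # rates, 1/s
    transcription_max: float = 0.1
    transcription_basal: float = 0.001
    mrna_decay: float = 0.02
    translation_per_mrna: float = 0.05
    dilution: float = 2.888e-4  # ln2 / 2400 s
    # repression of transcription by the glucose signal
    repression_k: float = 0.02  # mM
    repression_hill: float = 2.0

    def __post_init__(self):
        if self.lacY_mRNA < 0 or self.LacY_protein < 0:
            raise ValueError("counts must be >= 0")


def lacY_expression_step(
    state: LacYExpressionState,
    glucose_signal: float,
    dt: float,
    rng,
) -> tuple[float, float]:
    """One stochastic step; returns (mRNA delta, protein delta)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    g = max(glucose_signal, 0.0)
    k, h = state.repression_k, state.repression_hill
    repression = k**h / (k**h + g**h) if k > 0 else 1.0
    synth = state.transcription_basal + state.transcription_max * repression
    decay = state.mrna_decay * state.lacY_mRNA
    dm = (synth - decay) * dt
    if rng is not None:
        dm += rng.normal(0.0, ((synth + decay) * dt) ** 0.5)
    dm = max(dm, -state.lacY_mRNA)

    p_synth = state.translation_per_mrna * state.lacY_mRNA
    p_loss = state.dilution * state.LacY_protein
    dp = (p_synth - p_loss) * dt
    if rng is not None:
        dp += rng.normal(0.0, ((p_synth + p_loss) * dt) ** 0.5)
    dp = max(dp, -state.LacY_protein)
    return dm, dp
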