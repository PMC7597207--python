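"""Gillespie stochastic simulation primitives.

The direct method: with propensities a_i, the wait to the next event is
Exponential(sum a_i) and reaction i fires with probability a_i / sum a.
Used for polymerase/ribosome binding and complexation, where reactant
counts are small and discreteness matters.
"""

from __future__ import annotations

import math
from typing import Hashable, Optional


def gillespie_draw(
    propensities: dict[Hashable, float], rng
) -> tuple[float, Optional[Hashable]]:
    """One draw of (wait time, reaction id); (inf, None) if nothing can fire."""
    total = 0.0
    for rid, a in propensities.items():
        if a < 0 or not math.isfinite(a):
            raise ValueError(f"invalid propensity for {rid!r}: {a}")
        total += a
    if total == 0.0:
        return math.inf, None
    wait = rng.exponential(1.0 / total)
    threshold = rng.uniform(0.0, total)
    running = 0.0
    chosen = None
    for rid in sorted(propensities, key=str):
        running += propensities[rid]
        if running >= threshold:
            chosen = rid
            break
    return wait, chosen
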