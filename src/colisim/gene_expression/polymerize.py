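"""Template-directed polymerization with explicit monomer/energy booking."""

from __future__ import annotations

from collections import Counter

RNA_FROM_DNA = str.maketrans("T", "U")


def transcript_sequence(dna: str) -> str:
    """mRNA composition of a sense-strand DNA template (T -> U)."""
    return dna.translate(RNA_FROM_DNA)


def polymerize(
    template: str,
    start: int,
    max_units: int,
    monomers: dict[str, float],
    energy: float,
    energy_per_unit: float,
    pool_prefix: str = "",
) -> tuple[int, Counter, float]:
    """Advance along ``template[start:]`` by up to ``max_units`` residues.

    Consumes one matching monomer and ``energy_per_unit`` ATP per
    residue; stalls (stops early) as soon as a required monomer or the
    energy pool runs out. Monomer pools are looked up under
    ``pool_prefix + residue`` (``nt_`` for nucleotides, ``aa_`` for
    amino acids, so one-letter codes never collide). Returns (units
    advanced, monomers consumed keyed by pool name, energy consumed).
    """
    max_units = min(max_units, len(template) - start)
    if max_units <= 0:
        return 0, Counter(), 0.0
    segment = template[start : start + max_units]
    need = Counter(pool_prefix + residue for residue in segment)
    energy_need = energy_per_unit * max_units
    if energy >= energy_need and all(
        monomers.get(m, 0.0) >= n for m, n in need.items()
    ):
        return max_units, need, energy_need
    # slow path: advance residue by residue until something runs out
    available = dict(monomers)
    consumed: Counter = Counter()
    energy_used = 0.0
    for residue in segment:
        key = pool_prefix + residue
        if available.get(key, 0.0) < 1 or energy - energy_used < energy_per_unit:
            break
        available[key] -= 1
        consumed[key] += 1
        energy_used += energy_per_unit
    return sum(consumed.values()), consumed, energy_used
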