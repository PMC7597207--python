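"""Curated flagellar expression network fixture (synthetic sequences).

Seven flagellar operons wired in the classic three-class cascade: the
master regulator FlhDC is expressed first (class 1); FlhDC-activated
operons encoding the basal body, hook, and the sigma factor FliA follow
(class 2) with increasing FlhDC thresholds, so components appear
"just in time"; FliA-dependent late genes (filament FliC) come last.
FlgM sequesters FliA as a complexation reaction until basal bodies are
built, delaying late transcription.

Operon nucleotide sequences are synthetic placeholders generated
deterministically at realistic-but-scaled lengths (real flagellar
operons run to many kilobases; these are shortened so desk-scale
simulations complete in minutes while keeping per-base accounting
exact). Promoter affinities, gate coefficients and thresholds are
calibrated to give sustained flagellar synthesis with the paper-scale
polymerase budget of 10 RNAPs and 20 ribosomes.
"""

from __future__ import annotations

import numpy as np

from colisim.gene_expression.chromosome import (
    ChromosomeConfig,
    Gene,
    Promoter,
    TFSite,
)

FLAGELLAR_RNAP_COUNT = 10
FLAGELLAR_RIBOSOME_COUNT = 20

# operon -> (length in bp, genes: protein id -> aa length)
_OPERON_PLAN = {
    "flhDC": {"length": 360, "genes": {"FlhDC": 110}},
    "fliLMNOPQR": {"length": 420, "genes": {"FliM": 120}},
    "fliEFGHIJK": {"length": 480, "genes": {"FliF": 90, "FliG": 60}},
    "flgBCDEFGHIJ": {"length": 480, "genes": {"FlgB": 70, "FlgE": 80}},
    "fliAZY": {"length": 330, "genes": {"FliA": 100}},
    "flgMN": {"length": 240, "genes": {"FlgM": 70}},
    "fliC": {"length": 450, "genes": {"FliC": 140}},
}

# promoter regulation: operon -> list of (tf, threshold counts, coefficient)
_REGULATION = {
    "flhDC": [],
    "fliLMNOPQR": [("FlhDC", 4.0, 6.0)],
    "fliEFGHIJK": [("FlhDC", 8.0, 6.0)],
    "flgBCDEFGHIJ": [("FlhDC", 12.0, 6.0)],
    "fliAZY": [("FlhDC", 16.0, 6.0)],
    "flgMN": [("FlhDC", 20.0, 4.0)],
    "fliC": [("FliA", 6.0, 10.0)],
}

_BASAL = {
    "flhDC": 0.02,
    "fliLMNOPQR": 0.002,
    "fliEFGHIJK": 0.002,
    "flgBCDEFGHIJ": 0.002,
    "fliAZY": 0.002,
    "flgMN": 0.002,
    "fliC": 0.0005,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# staged assembly: monomers -> basal body -> hook -> flagellum; FlgM
# sequesters free FliA until enough basal bodies exist
FLAGELLAR_COMPLEXATION = {
    "basal_body_assembly": {
        "FliF": -2, "FliG": -2, "FliM": -1, "FlgB": -1, "basal_body": 1,
    },
    "hook_assembly": {"basal_body": -1, "FlgE": -2, "hook_body": 1},
    "flagellum_assembly": {"hook_body": -1, "FliC": -4, "flagellum": 1},
    "fliA_sequestration": {"FliA": -1, "FlgM": -1, "FliA_FlgM": 1},
}


def flagellar_chromosome(seed: int = 7) -> ChromosomeConfig:
    """Build the seven-operon fixture with deterministic sequences."""
    rng = np.random.default_rng(seed)
    sequences = {}
    promoters = {}
    terminators = {}
    units = {}
    for operon, plan in _OPERON_PLAN.items():
        length = plan["length"]
        sequences[operon] = "".join(
            rng.choice(list(NUCLEOTIDES), size=length)
        )
        terminators[operon] = length
        promoters[operon] = Promoter(
            id=operon,
            operon=operon,
            basal_affinity=_BASAL[operon],
            sites=[
                TFSite(tf=tf, threshold=thr, coefficient=coeff)
                for tf, thr, coeff in _REGULATION[operon]
            ],
        )
        units[operon] = [
            Gene(
                id=protein.lower(),
                protein=protein,
                protein_sequence="".join(
                    rng.choice(list(AMINO_ACIDS), size=aa_len)
                ),
                rbs_affinity=0.03,
            )
            for protein, aa_len in plan["genes"].items()
        ]
    return ChromosomeConfig(
        sequences=sequences,
        promoters=promoters,
        terminators=terminators,
        transcription_units=units,
    )


def ample_pools(scale: float = 1e6) -> dict[str, float]:
    """Nutrient-replete pools: all NTPs, amino acids, and ATP."""
    pools: dict[str, float] = {"ATP": scale, "ADP": 0.0}
    for nt in "ACGU":
        pools["nt_" + nt] = scale
    for aa in AMINO_ACIDS:
        pools["aa_" + aa] = scale
    return pools

OPERON_CLASSES = {
    "flhDC": "master",
    "fliLMNOPQR": "middle",
    "fliEFGHIJK": "middle",
    "flgBCDEFGHIJ": "middle",
    "fliAZY": "middle",
    "flgMN": "middle",
    "fliC": "late",
}
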