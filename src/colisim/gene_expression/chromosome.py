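"""Chromosome configuration: operons, promoters, TF logic, gene products.

Coordinates are 0-based, half-open intervals on the coding strand;
sequences are stored sense-strand (no complement handling). A promoter
carries transcription-factor binding sites with per-TF occupancy
thresholds and binary-sum gate coefficients: a site is occupied when its
TF's concentration exceeds the threshold, and the promoter's RNAP
binding propensity is the basal affinity scaled by the gate output over
occupied sites (activators add positive coefficients, repressors
negative; the gate floors at zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


class ChromosomeError(Exception):
    pass


@dataclass
class TFSite:
    tf: str
    threshold: float  # occupancy threshold on the TF signal (counts)
    coefficient: float  # + activation, - repression (binary-sum gate)


@dataclass
class Gene:
    id: str
    protein: str  # protein (monomer) id produced
    protein_sequence: str  # amino acids, one-letter
    rbs_affinity: float = 0.1  # ribosome binding propensity per mRNA, 1/s


@dataclass
class Promoter:
    id: str
    operon: str
    basal_affinity: float  # RNAP binding propensity with empty gate, 1/s
    sites: list[TFSite] = field(default_factory=list)
    basal_floor: float = 0.0  # fraction of basal kept under full repression


@dataclass
class ChromosomeConfig:
    """Operon sequences plus regulatory structure."""

    sequences: dict[str, str]  # operon id -> nucleotide string (ACGT)
    promoters: dict[str, Promoter]
    terminators: dict[str, int]  # operon id -> terminator position (bp)
    transcription_units: dict[str, list[Gene]]  # promoter id -> genes

    def __post_init__(self):
        for pid, promoter in self.promoters.items():
            if promoter.operon not in self.sequences:
                raise ChromosomeError(
                    f"promoter {pid!r} references unknown operon "
                    f"{promoter.operon!r}"
                )
        for operon, position in self.terminators.items():
            if not 0 < position <= len(self.sequences[operon]):
                raise ChromosomeError(
                    f"terminator for {operon!r} outside sequence"
                )
        for pid, genes in self.transcription_units.items():
            if pid not in self.promoters:
                raise ChromosomeError(f"transcription unit {pid!r} has no promoter")
            for gene in genes:
                if not gene.protein_sequence:
                    raise ChromosomeError(f"gene {gene.id!r} has no protein sequence")

    def transcript_length(self, promoter_id: str) -> int:
        operon = self.promoters[promoter_id].operon
        return self.terminators.get(operon, len(self.sequences[operon]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sequences": self.sequences,
            "terminators": self.terminators,
            "promoters": {
                pid: {
                    "operon": p.operon,
                    "basal_affinity": p.basal_affinity,
                    "basal_floor": p.basal_floor,
                    "sites": [
                        {"tf": s.tf, "threshold": s.threshold,
                         "coefficient": s.coefficient}
                        for s in p.sites
                    ],
                }
                for pid, p in self.promoters.items()
            },
            "transcription_units": {
                pid: [
                    {"id": g.id, "protein": g.protein,
                     "protein_sequence": g.protein_sequence,
                     "rbs_affinity": g.rbs_affinity}
                    for g in genes
                ]
                for pid, genes in self.transcription_units.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromosomeConfig":
        payload = json.loads(Path(path).read_text())
        return cls(
            sequences=payload["sequences"],
            terminators={k: int(v) for k, v in payload["terminators"].items()},
            promoters={
                pid: Promoter(
                    id=pid,
                    operon=p["operon"],
                    basal_affinity=p["basal_affinity"],
                    basal_floor=p.get("basal_floor", 0.0),
                    sites=[TFSite(**s) for s in p["sites"]],
                )
                for pid, p in payload["promoters"].items()
            },
            transcription_units={
                pid: [Gene(**g) for g in genes]
                for pid, genes in payload["transcription_units"].items()
            },
        )


def promoter_binding_propensities(
    promoters: dict[str, Promoter],
    tf_concentrations: dict[str, float],
) -> dict[str, float]:
    """RNAP binding propensity per promoter under the binary-sum gate."""
    propensities = {}
    for pid, promoter in promoters.items():
        gate = 1.0
        repressed = False
        for site in promoter.sites:
            if site.tf not in tf_concentrations:
                raise ChromosomeError(
                    f"promoter {pid!r} references unknown TF {site.tf!r}"
                )
            if tf_concentrations[site.tf] > site.threshold:
                gate += site.coefficient
                if site.coefficient < 0:
                    repressed = True
        value = promoter.basal_affinity * max(gate, 0.0)
        if repressed:
            value = max(value, promoter.basal_affinity * promoter.basal_floor)
        propensities[pid] = value
    return propensities
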