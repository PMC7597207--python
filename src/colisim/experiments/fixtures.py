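"""Deterministic fixture generation: networks, chromosomes, environments."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from colisim.environment import make_gradient_field
from colisim.gene_expression import (
    ChromosomeConfig,
    FLAGELLAR_COMPLEXATION,
    Gene,
    Promoter,
    TFSite,
    flagellar_chromosome,
)
from colisim.metabolism import toy_network

FIXTURE_KINDS = (
    "toy_metabolism",
    "toy_chromosome",
    "flagellar_network",
    "gradient_env",
)


def lac_chromosome(seed: int = 0) -> ChromosomeConfig:
    """A lac-like operon: glucose-repressed transcription unit for LacY."""
    rng = np.random.default_rng(seed)
    length = 240
    sequence = "".join(rng.choice(list("ACGT"), size=length))
    protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=70))
    return ChromosomeConfig(
        sequences={"lacZYA": sequence},
        promoters={
            "lacZYA": Promoter(
                id="lacZYA",
                operon="lacZYA",
                basal_affinity=0.01,
                sites=[TFSite(tf="glucose", threshold=0.05, coefficient=-1.0)],
            )
        },
        terminators={"lacZYA": length},
        transcription_units={
            "lacZYA": [
                Gene(id="lacY", protein="LacY", protein_sequence=protein,
                     rbs_affinity=0.05)
            ]
        },
    )


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write schema-valid fixture files; same seed -> identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "toy_metabolism":
        path = out / "toy_metabolism.json"
        toy_network().to_json(path)
        written.append(path)
    elif kind == "toy_chromosome":
        path = out / "toy_chromosome.json"
        lac_chromosome(seed).to_json(path)
        written.append(path)
    elif kind == "flagellar_network":
        chrom_path = out / "flagellar_chromosome.json"
        flagellar_chromosome(seed or 7).to_json(chrom_path)
        written.append(chrom_path)
        cxn_path = out / "flagellar_complexation.json"
        cxn_path.write_text(
            json.dumps(FLAGELLAR_COMPLEXATION, indent=1, sort_keys=True)
        )
        written.append(cxn_path)
    elif kind == "gradient_env":
        fld = make_gradient_field(
            "exponential",
            bounds=(1000.0, 2000.0),
            n_bins=(1, 200),
            base_concentration=0.05,
            length_scale=150.0,
            origin_y=600.0,
        )
        path = out / "gradient_MeAsp.csv"
        np.savetxt(path, fld.concentrations["MeAsp"], delimiter=",")
        written.append(path)
        meta = out / "gradient_env.json"
        meta.write_text(
            json.dumps(
                {
                    "species": "MeAsp",
                    "shape": "exponential",
                    "bounds_um": [1000.0, 2000.0],
                    "n_bins": [1, 200],
                    "base_concentration_mM": 0.05,
                    "length_scale_um": 150.0,
                    "origin_y_um": 600.0,
                },
                indent=1,
                sort_keys=True,
            )
        )
        written.append(meta)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose {FIXTURE_KINDS}")
    return written
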