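"""Stochastic sequence-based gene expression processes.

Transcription and translation combine Gillespie binding events with
deterministic elongation at fixed rates (50 bp/s for RNAP, 22 aa/s for
ribosomes), consuming matching monomers from the metabolite pools and
hydrolyzing ATP to ADP: one ATP per nucleotide transcribed, two per
amino acid translated, and one per nucleotide reclaimed by degradation.
Polymerase state (bound positions) lives inside each process instance
and is reset on division, matching fixed polymerase counts per cell.
"""

from __future__ import annotations

import math
from collections import Counter

from colisim.engine import Process, VariableSchema
from colisim.gene_expression.chromosome import (
    ChromosomeConfig,
    promoter_binding_propensities,
)
from colisim.gene_expression.gillespie import gillespie_draw
from colisim.gene_expression.polymerize import polymerize, transcript_sequence

RNAP_ELONGATION_BP_S = 50.0
RNAP_OCCLUSION_BP = 30
RIBOSOME_ELONGATION_AA_S = 22.0
RIBOSOME_OCCLUSION_BP = 50
ATP_PER_NT = 1.0
ATP_PER_AA = 2.0
COMPLEXATION_RATE_S = 1000.0


def _count_schema(default=0.0, emit=False, divider="binomial"):
    return VariableSchema(
        default=default, units="counts", updater="accumulate",
        divider=divider, emit=emit,
    )


def _pool_ports():
    return {
        "*": VariableSchema(
            default=0.0, units="counts", updater="accumulate", divider="halve"
        )
    }


class Transcription(Process):
    """RNAP binding (Gillespie, TF-gated) plus deterministic elongation."""

    defaults = {
        "time_step": 1.0,
        "chromosome": None,  # ChromosomeConfig, required
        "n_rnap": 10,
        "elongation_rate": RNAP_ELONGATION_BP_S,
        "occlusion_bp": RNAP_OCCLUSION_BP,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self.chromosome: ChromosomeConfig = self.parameters["chromosome"]
        if self.chromosome is None:
            raise ValueError("Transcription requires a chromosome configuration")
        # bound polymerases: {promoter, position (bp), offset (s into step)}
        self.active: list[dict] = []

    def ports_schema(self):
        return {
            "pools": _pool_ports(),
            "transcripts": {
                pid: _count_schema(emit=True)
                for pid in self.chromosome.promoters
            },
            "tf": {"*": _count_schema()},
        }

    def _free_promoters(self) -> set:
        blocked = {
            pol["promoter"]
            for pol in self.active
            if pol["position"] < self.parameters["occlusion_bp"]
        }
        return set(self.chromosome.promoters) - blocked

    def next_update(self, states, timestep):
        pools = dict(states["pools"])
        tf = states["tf"]
        occupied = self._free_promoters  # recomputed per event
        base = promoter_binding_propensities(self.chromosome.promoters, tf)

        # binding events within the step
        t = 0.0
        while len(self.active) < int(self.parameters["n_rnap"]):
            candidates = {
                pid: base[pid] for pid in occupied() if base[pid] > 0
            }
            wait, chosen = gillespie_draw(candidates, self.rng)
            if chosen is None or t + wait > timestep:
                break
            t += wait
            self.active.append({"promoter": chosen, "position": 0.0, "offset": t})

        # deterministic elongation, consuming nucleotides and ATP
        rate = self.parameters["elongation_rate"]
        deltas: Counter = Counter()
        completed: Counter = Counter()
        still_active = []
        for pol in self.active:
            pid = pol["promoter"]
            operon = self.chromosome.promoters[pid].operon
            template = transcript_sequence(
                self.chromosome.sequences[operon][: self.chromosome.transcript_length(pid)]
            )
            budget = rate * (timestep - pol["offset"])
            pol["offset"] = 0.0
            target = min(
                math.floor(pol["position"] + budget), len(template)
            )
            advance = target - math.floor(pol["position"])
            n, consumed, energy = polymerize(
                template,
                int(math.floor(pol["position"])),
                int(advance),
                pools,
                pools.get("ATP", 0.0) + deltas["ATP"],
                ATP_PER_NT,
                pool_prefix="nt_",
            )
            for monomer, count in consumed.items():
                deltas[monomer] -= count
                pools[monomer] = pools.get(monomer, 0.0) - count
            deltas["ATP"] -= energy
            deltas["ADP"] += energy
            pol["position"] = (
                math.floor(pol["position"]) + n + (budget % 1.0 if n == advance else 0.0)
            )
            if pol["position"] >= len(template):
                completed[pid] += 1
            else:
                still_active.append(pol)
        self.active = still_active
        return {
            "pools": dict(deltas),
            "transcripts": dict(completed),
        }


class Translation(Process):
    """Ribosome initiation per gene, elongation at 22 aa/s, 2 ATP/aa."""

    defaults = {
        "time_step": 1.0,
        "chromosome": None,
        "n_ribosomes": 20,
        "elongation_rate": RIBOSOME_ELONGATION_AA_S,
        "occlusion_bp": RIBOSOME_OCCLUSION_BP,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self.chromosome: ChromosomeConfig = self.parameters["chromosome"]
        if self.chromosome is None:
            raise ValueError("Translation requires a chromosome configuration")
        self.genes = {
            (pid, gene.id): gene
            for pid, genes in self.chromosome.transcription_units.items()
            for gene in genes
        }
        # bound ribosomes: {unit, gene, position (aa), offset (s)}
        self.active: list[dict] = []

    def ports_schema(self):
        return {
            "pools": _pool_ports(),
            "transcripts": {
                pid: _count_schema() for pid in self.chromosome.promoters
            },
            "proteins": {
                gene.protein: _count_schema(emit=True)
                for gene in self.genes.values()
            },
        }

    def _initiation_propensities(self, transcripts) -> dict:
        # a new ribosome may not bind a gene while another sits within
        # the occlusion distance of its start
        blocked = {
            (rib["unit"], rib["gene"])
            for rib in self.active
            if rib["position"] * 3 < self.parameters["occlusion_bp"]
        }
        props = {}
        for (pid, gid), gene in self.genes.items():
            if (pid, gid) in blocked:
                continue
            count = transcripts.get(pid, 0)
            if count > 0:
                props[(pid, gid)] = gene.rbs_affinity * count
        return props

    def next_update(self, states, timestep):
        pools = dict(states["pools"])
        transcripts = states["transcripts"]
        t = 0.0
        while len(self.active) < int(self.parameters["n_ribosomes"]):
            props = self._initiation_propensities(transcripts)
            wait, chosen = gillespie_draw(props, self.rng)
            if chosen is None or t + wait > timestep:
                break
            t += wait
            pid, gid = chosen
            self.active.append(
                {"unit": pid, "gene": gid, "position": 0.0, "offset": t}
            )

        rate = self.parameters["elongation_rate"]
        deltas: Counter = Counter()
        completed: Counter = Counter()
        still_active = []
        for rib in self.active:
            gene = self.genes[(rib["unit"], rib["gene"])]
            template = gene.protein_sequence
            budget = rate * (timestep - rib["offset"])
            rib["offset"] = 0.0
            target = min(math.floor(rib["position"] + budget), len(template))
            advance = target - math.floor(rib["position"])
            n, consumed, energy = polymerize(
                template,
                int(math.floor(rib["position"])),
                int(advance),
                pools,
                pools.get("ATP", 0.0) + deltas["ATP"],
                ATP_PER_AA,
                pool_prefix="aa_",
            )
            for monomer, count in consumed.items():
                deltas[monomer] -= count
                pools[monomer] = pools.get(monomer, 0.0) - count
            deltas["ATP"] -= energy
            deltas["ADP"] += energy
            rib["position"] = (
                math.floor(rib["position"]) + n + (budget % 1.0 if n == advance else 0.0)
            )
            if rib["position"] >= len(template):
                completed[gene.protein] += 1
            else:
                still_active.append(rib)
        self.active = still_active
        return {
            "pools": dict(deltas),
            "proteins": dict(completed),
        }


class Complexation(Process):
    """Gillespie assembly of monomers into (possibly staged) complexes.

    An optional ``export_rule`` models anti-sigma-factor relief: once a
    trigger complex (the basal body) has been assembled, the exported
    species (FlgM) is removed from the cell each step and any
    sequestration complex holding the sigma factor dissociates,
    releasing it to activate late transcription.
    """

    defaults = {
        "time_step": 1.0,
        "reactions": {},  # rid -> {species: stoichiometry, products > 0}
        "rate": COMPLEXATION_RATE_S,  # per reaction, order-of-magnitude
        "max_events": 10000,
        # e.g. {"trigger": "basal_body", "threshold": 1, "export": "FlgM",
        #       "complex": "FliA_FlgM", "release": "FliA"}
        "export_rule": None,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self._produced: Counter = Counter()  # cumulative products assembled

    def ports_schema(self):
        species = {
            s for stoich in self.parameters["reactions"].values() for s in stoich
        }
        rule = self.parameters["export_rule"]
        if rule:
            species.update([rule["export"], rule["complex"], rule["release"]])
        return {
            "molecules": {name: _count_schema(emit=True) for name in sorted(species)}
        }

    def next_update(self, states, timestep):
        counts = dict(states["molecules"])
        reactions = self.parameters["reactions"]
        deltas: Counter = Counter()
        t = 0.0
        for _ in range(int(self.parameters["max_events"])):
            props = {}
            for rid, stoich in reactions.items():
                feasible = all(
                    counts.get(sp, 0) >= -coeff
                    for sp, coeff in stoich.items()
                    if coeff < 0
                )
                if feasible:
                    props[rid] = self.parameters["rate"]
            wait, chosen = gillespie_draw(props, self.rng)
            if chosen is None or t + wait > timestep:
                break
            t += wait
            for sp, coeff in reactions[chosen].items():
                counts[sp] = counts.get(sp, 0) + coeff
                deltas[sp] += coeff
                if coeff > 0:
                    self._produced[sp] += coeff
        rule = self.parameters["export_rule"]
        if rule and self._produced[rule["trigger"]] >= rule.get("threshold", 1):
            free = counts.get(rule["export"], 0)
            bound = counts.get(rule["complex"], 0)
            if free > 0:
                deltas[rule["export"]] -= free
            if bound > 0:
                deltas[rule["complex"]] -= bound
                deltas[rule["release"]] += bound
        return {"molecules": {sp: d for sp, d in deltas.items() if d != 0}}


class Degradation(Process):
    """endoRNAse-mediated mRNA turnover reclaiming nucleotides.

    Degradation follows Michaelis-Menten kinetics in the transcript
    count, scaled by the endoRNAse level; whole transcripts are removed
    (a fractional carry accumulates between steps), each returning its
    nucleotide composition to the pools at a cost of one ATP per
    nucleotide. Proteins are never degraded; their loss is dilution.
    """

    defaults = {
        "time_step": 1.0,
        "chromosome": None,
        "endoRNAse": 1.0,
        "kcat": 0.005,  # transcripts/s per endoRNAse at saturation
        "km": 5.0,  # transcripts
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        self.chromosome: ChromosomeConfig = self.parameters["chromosome"]
        if self.chromosome is None:
            raise ValueError("Degradation requires a chromosome configuration")
        self._carry: Counter = Counter()

    def ports_schema(self):
        return {
            "pools": _pool_ports(),
            "transcripts": {
                pid: _count_schema() for pid in self.chromosome.promoters
            },
        }

    def next_update(self, states, timestep):
        pools = states["pools"]
        atp = pools.get("ATP", 0.0)
        pool_deltas: Counter = Counter()
        transcript_deltas = {}
        for pid in sorted(self.chromosome.promoters):
            count = states["transcripts"].get(pid, 0)
            if count <= 0:
                continue
            rate = (
                self.parameters["kcat"]
                * self.parameters["endoRNAse"]
                * count
                / (self.parameters["km"] + count)
            )
            self._carry[pid] += rate * timestep
            n = int(self._carry[pid])
            if n <= 0:
                continue
            n = min(n, int(count))
            operon = self.chromosome.promoters[pid].operon
            rna = transcript_sequence(
                self.chromosome.sequences[operon][: self.chromosome.transcript_length(pid)]
            )
            length = len(rna)
            affordable = int(atp // length) if length else n
            n = min(n, affordable)
            if n <= 0:
                continue
            self._carry[pid] -= n
            composition = Counter("nt_" + base for base in rna)
            for base, per in composition.items():
                pool_deltas[base] += per * n
            pool_deltas["ATP"] -= length * n
            pool_deltas["ADP"] += length * n
            atp -= length * n
            transcript_deltas[pid] = -n
        return {
            "pools": dict(pool_deltas),
            "transcripts": transcript_deltas,
        }
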