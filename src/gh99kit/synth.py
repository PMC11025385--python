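"""Synthetic GH99-like cohorts with planted ground truth.

The generator evolves the packaged reference along simple lineages and
plants known motif states, subfamily memberships and contaminants, so every
pipeline stage (motif extraction, annotation, ohnolog classification,
clustering, decontamination, prevalence) can be scored against truth.

Model: each subfamily descends from its own ancestor, itself evolved from
the shared root at ``ancestor_divergence`` per-site substitution
probability; members then evolve from the subfamily ancestor through
``depth`` independent steps at per-site probability ``p`` each (a star
phylogeny within the subfamily).  Substitutions draw uniformly from the 19
alternative residues.  Indels are off by default so reference coordinates
stay exact; after evolution the planted motif states are written onto their
positions, guaranteeing the truth labels.  Contaminants are generated
inside their true subfamily but labelled with a wrong taxogroup.  Identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, ProteinRecord, TaxonomyTable, load_reference

__all__ = [
    "PlantedState",
    "SubfamilySpec",
    "ContaminantSpec",
    "SimulationConfig",
    "simulate_family",
    "evolve_sequence",
    "taxonomy_from_truth",
]

# planted-state coordinates (human MANEA numbering)
POS_189 = 189
POS_197 = 197
ACTSITE_START = 404


@dataclass(frozen=True)
class PlantedState:
    """Motif states written onto every member after evolution."""

    p189: str = "Y"
    p197: str = "N"
    actsite: str = "EWHE"

    def __post_init__(self) -> None:
        if len(self.p189) != 1 or len(self.p197) != 1 or len(self.actsite) != 4:
            raise ValueError("planted states: p189/p197 single letters, actsite 4 letters")


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    n: int = 10
    p: float = 0.05  # per-site substitution probability per lineage step
    depth: int = 1
    planted: PlantedState = field(default_factory=PlantedState)
    taxogroup: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"substitution probability must be in [0, 1], got {self.p}")
        if self.n < 0 or self.depth < 1:
            raise ValueError("n must be >= 0 and depth >= 1")


@dataclass(frozen=True)
class ContaminantSpec:
    """A sequence generated inside ``source_subfamily`` but labelled
    ``labeled_taxogroup`` — the planted contamination truth."""

    count: int
    source_subfamily: str
    labeled_taxogroup: str


@dataclass
class SimulationConfig:
    subfamilies: list[SubfamilySpec]
    seed: int
    root_sequence: str | None = None  # default: packaged reference
    ancestor_divergence: float = 0.3
    contaminants: list[ContaminantSpec] = field(default_factory=list)
    records_per_species: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic run")
        if not (0.0 <= self.ancestor_divergence <= 1.0):
            raise ValueError("ancestor_divergence must be in [0, 1]")
        names = [s.name for s in self.subfamilies]
        if len(set(names)) != len(names):
            raise ValueError("subfamily names must be distinct")


def evolve_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """One evolution step: each site substitutes with probability ``p`` to a
    residue drawn uniformly from the 19 alternatives."""
    if p == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < p
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = [a for a in AMINO_ACIDS if a != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _plant(seq: str, state: PlantedState) -> str:
    chars = list(seq)
    chars[POS_189 - 1] = state.p189
    chars[POS_197 - 1] = state.p197
    chars[ACTSITE_START - 1:ACTSITE_START + 3] = list(state.actsite)
    return "".join(chars)


def simulate_family(config: SimulationConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a cohort with planted truth.

    Returns the records and a truth table (one row per record: subfamily,
    planted states, contaminant flag, species, taxogroup, lineage).
    """
    rng = np.random.default_rng(config.seed)
    root = config.root_sequence or load_reference().sequence
    if len(root) < ACTSITE_START + 3:
        raise ValueError("root sequence too short to hold the motif positions")

    ancestors: dict[str, str] = {}
    for spec in config.subfamilies:
        ancestors[spec.name] = evolve_sequence(root, config.ancestor_divergence, rng)

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []

    def emit(spec: SubfamilySpec, index: int, taxogroup: str, contaminant: bool,
             tag: str) -> None:
        seq = ancestors[spec.name]
        for _ in range(spec.depth):
            seq = evolve_sequence(seq, spec.p, rng)
        seq = _plant(seq, spec.planted)
        rec_id = f"{tag}_{spec.name}_{index:04d}"
        species_idx = index // max(config.records_per_species, 1)
        # dot separator: species names survive the FASTA header convention
        # that underscores encode spaces
        species = f"{taxogroup}.sp{species_idx:03d}"
        rec = ProteinRecord(
            id=rec_id,
            sequence=seq,
            species=species,
            clade_path=(taxogroup, spec.name),
        )
        records.append(rec)
        truth_rows.append(
            {
                "id": rec_id,
                "subfamily": spec.name,
                "species": species,
                "taxogroup": taxogroup,
                "true_taxogroup": spec.taxogroup or spec.name,
                "contaminant": contaminant,
                "p189": spec.planted.p189,
                "p197": spec.planted.p197,
                "actsite": spec.planted.actsite,
                "depth": spec.depth,
                "p": spec.p,
            }
        )

    for spec in config.subfamilies:
        group = spec.taxogroup or spec.name
        for i in range(spec.n):
            emit(spec, i, group, contaminant=False, tag="rec")

    by_name = {s.name: s for s in config.subfamilies}
    for cont in config.contaminants:
        if cont.source_subfamily not in by_name:
            raise ValueError(f"unknown source subfamily {cont.source_subfamily!r}")
        spec = by_name[cont.source_subfamily]
        for i in range(cont.count):
            emit(spec, 9000 + i, cont.labeled_taxogroup, contaminant=True, tag="cont")

    truth = pd.DataFrame(truth_rows).set_index("id")
    return records, truth


def taxonomy_from_truth(truth: pd.DataFrame) -> TaxonomyTable:
    """Build the matching taxonomy table (species -> taxogroup;subfamily)."""
    paths: dict[str, list[str]] = {}
    for _, row in truth.iterrows():
        paths.setdefault(row["species"], [row["taxogroup"], row["subfamily"]])
    return TaxonomyTable(paths)
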