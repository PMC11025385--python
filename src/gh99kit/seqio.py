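"""Sequence and taxonomy I/O.

Protein records are the unit every other module works on: an identifier, an
upper-case amino-acid sequence (20 standard letters plus ``X``), a species
name and an optional clade path (root-to-species list of clade names, e.g.
``["Opisthokonta", "Metazoa", "Vertebrata"]``).  Taxonomy tables map species
to clade paths and carry the per-clade universe of searched species used by
the prevalence reports.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = frozenset(AMINO_ACIDS + "X")

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "TaxonomyTable",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "load_reference",
]


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA entries or invalid record fields."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein sequence.

    ``clade_path`` may be empty when the species is not in the taxonomy.
    """

    id: str
    sequence: str
    species: str = ""
    clade_path: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("record id must be non-empty")
        if not self.sequence:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        bad = [
            (i + 1, ch)
            for i, ch in enumerate(self.sequence)
            if ch not in VALID_LETTERS
        ]
        if bad:
            pos, ch = bad[0]
            raise SequenceFormatError(
                f"record {self.id!r}: illegal character {ch!r} at position {pos}"
            )
        object.__setattr__(self, "clade_path", tuple(self.clade_path))

    def __len__(self) -> int:
        return len(self.sequence)

    def with_taxonomy(self, species: str, clade_path: Sequence[str]) -> "ProteinRecord":
        return replace(self, species=species, clade_path=tuple(clade_path))


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    # tolerate a single terminal stop symbol (translated transcripts)
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise SequenceFormatError(f"record {rec_id!r}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in VALID_LETTERS:
            raise SequenceFormatError(
                f"record {rec_id!r}: illegal character {ch!r} at position {i + 1}"
            )
    return seq


def _species_from_description(description: str) -> str:
    # header dialect: id then free text; species taken from a species= key only
    for token in description.split()[1:]:
        if token.startswith("species="):
            return token[len("species="):].replace("_", " ")
    if "species=" in description:
        # species= value with spaces: take everything after the key
        return description.split("species=", 1)[1].strip()
    return ""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The id is the first whitespace-delimited header token; a ``species=`` key
    in the remaining header text sets the species.  Letters are upper-cased
    and one terminal ``*`` is stripped; anything else outside the 20 amino
    acids plus ``X`` is an error.  Duplicate ids are an error.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceFormatError(f"{path}: FASTA entry with empty id")
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=_clean_sequence(str(rec.seq), rec.id),
                species=_species_from_description(rec.description),
            )
        )
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA, preserving species in the header."""
    seqrecords = []
    for r in records:
        desc = f"species={r.species.replace(' ', '_')}" if r.species else ""
        seqrecords.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


class TaxonomyTable:
    """Species -> clade path map with per-clade searched-species universes.

    A species counts toward a clade's universe when it was searched (the
    optional third TSV column, default true) and its path contains the clade.
    """

    def __init__(self, paths: Mapping[str, Sequence[str]],
                 searched: Mapping[str, bool] | None = None) -> None:
        self._paths: dict[str, tuple[str, ...]] = {}
        self._searched: dict[str, bool] = {}
        for sp, path in paths.items():
            path = tuple(path)
            if not path:
                raise ValueError(f"species {sp!r}: empty clade path")
            if sp in self._paths:
                raise ValueError(f"species {sp!r} appears more than once")
            self._paths[sp] = path
            self._searched[sp] = True if searched is None else bool(searched.get(sp, True))

    def __contains__(self, species: str) -> bool:
        return species in self._paths

    def __len__(self) -> int:
        return len(self._paths)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._paths)

    def clade_path(self, species: str) -> tuple[str, ...]:
        try:
            return self._paths[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in taxonomy") from None

    def was_searched(self, species: str) -> bool:
        return self._searched[species]

    def clades(self) -> tuple[str, ...]:
        out: list[str] = []
        seen: set[str] = set()
        for path in self._paths.values():
            for clade in path:
                if clade not in seen:
                    seen.add(clade)
                    out.append(clade)
        return tuple(out)

    def universe_count(self, clade: str) -> int:
        """Number of searched species whose clade path contains ``clade``."""
        return sum(
            1
            for sp, path in self._paths.items()
            if clade in path and self._searched[sp]
        )

    def species_in_clade(self, clade: str) -> tuple[str, ...]:
        return tuple(sp for sp, path in self._paths.items() if clade in path)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a TSV with columns species, clade_path (semicolon-separated),
    optional searched flag (1/0, true/false)."""
    paths: dict[str, list[str]] = {}
    searched: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "species":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            sp = fields[0].strip()
            if sp in paths:
                raise ValueError(f"{path}:{lineno}: repeated species {sp!r}")
            clade_path = [c.strip() for c in fields[1].split(";") if c.strip()]
            if not clade_path:
                raise ValueError(f"{path}:{lineno}: empty clade path for {sp!r}")
            paths[sp] = clade_path
            if len(fields) >= 3 and fields[2].strip():
                searched[sp] = fields[2].strip().lower() in ("1", "true", "yes")
    return TaxonomyTable(paths, searched)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tclade_path\tsearched\n")
        for sp in tax.species:
            fh.write(
                f"{sp}\t{';'.join(tax.clade_path(sp))}\t"
                f"{'1' if tax.was_searched(sp) else '0'}\n"
            )


def attach_taxonomy(records: Iterable[ProteinRecord], tax: TaxonomyTable,
                    strict: bool = False) -> list[ProteinRecord]:
    """Fill in clade paths for records whose species is in the taxonomy.

    Joins on exact species-name match only.  With ``strict`` a missing
    species is an error; otherwise the record is passed through unchanged.
    """
    out = []
    for r in records:
        if r.species in tax:
            out.append(r.with_taxonomy(r.species, tax.clade_path(r.species)))
        elif strict:
            raise KeyError(f"record {r.id!r}: species {r.species!r} not in taxonomy")
        else:
            out.append(r)
    return out


def load_reference() -> ProteinRecord:
    """Load the packaged reference sequence.

    This is a synthetic stand-in written on human MANEA (UniProt Q5SRI9)
    coordinates: a 462-residue sequence with the canonical GH99 motif
    residues (Y189, DENGE at 195-199, HIEPY at 222-226, Y323, EWHE at
    404-407) planted at the canonical positions.  Any real reference on the
    same numbering can be substituted via ``read_fasta``.
    """
    data = importlib.resources.files("gh99kit.data") / "manea_reference_synthetic.fasta"
    with importlib.resources.as_file(data) as p:
        return read_fasta(p)[0]
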