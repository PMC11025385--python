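"""The five diagnostic GH99 motifs, frequency matrices, logos and consensi.

Motif spans are fixed constants in human MANEA numbering:

* ``P189``    — position 189, the -2 subsite selector (Tyr = endomannosidase,
  glucose preferred in -2; Trp = endomannanase, mannose preferred).
* ``LOOP``    — 195-199, the "-2 loop" with consensus D[E/D]NGE; N197H is its
  diagnostic variant.
* ``HEPY``    — 222-226, consensus H[I/L]EPY.
* ``P323``    — position 323, a conserved tyrosine not required for catalysis.
* ``ACTSITE`` — 404-407, consensus EW[H/G]E with the catalytic glutamates
  E404 and E407.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import ReferenceMap, build_reference_map
from .seqio import AMINO_ACIDS, ProteinRecord

MOTIF_SPANS: dict[str, tuple[int, ...]] = {
    "P189": (189,),
    "LOOP": (195, 196, 197, 198, 199),
    "HEPY": (222, 223, 224, 225, 226),
    "P323": (323,),
    "ACTSITE": (404, 405, 406, 407),
}

MAX_IC_BITS = math.log2(20)

__all__ = [
    "MOTIF_SPANS",
    "MAX_IC_BITS",
    "MotifCall",
    "PositionFrequencyMatrix",
    "ConsensusSequence",
    "extract_motifs",
    "stack_reference_columns",
    "build_pfm",
    "consensus",
]


@dataclass(frozen=True)
class MotifCall:
    """Residues read at the five motif spans; ``?`` marks unmapped positions."""

    record_id: str
    residues: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, span in MOTIF_SPANS.items():
            got = self.residues.get(name, "")
            if len(got) != len(span):
                raise ValueError(
                    f"{self.record_id}: motif {name} has {len(got)} residues, "
                    f"expected {len(span)}"
                )

    @property
    def p189(self) -> str:
        return self.residues["P189"]

    @property
    def loop(self) -> str:
        return self.residues["LOOP"]

    @property
    def p197(self) -> str:
        return self.residues["LOOP"][2]

    @property
    def hepy(self) -> str:
        return self.residues["HEPY"]

    @property
    def p323(self) -> str:
        return self.residues["P323"]

    @property
    def actsite(self) -> str:
        return self.residues["ACTSITE"]


def extract_motifs(record: ProteinRecord, refmap: ReferenceMap | None) -> MotifCall:
    """Read the five motifs from a record through its reference map.

    Total on any record: unmapped positions (partial sequences, or a ``None``
    map from an unmappable record) yield ``?`` rather than an error.
    """
    residues: dict[str, str] = {}
    for name, span in MOTIF_SPANS.items():
        chars = []
        for rpos in span:
            qpos = refmap.to_query(rpos) if refmap is not None else None
            chars.append(record.sequence[qpos - 1] if qpos is not None else "?")
        residues[name] = "".join(chars)
    return MotifCall(record_id=record.id, residues=residues)


def stack_reference_columns(
    records: Sequence[ProteinRecord],
    reference: str | ProteinRecord,
    span: Sequence[int] | None = None,
    refmaps: Sequence[ReferenceMap | None] | None = None,
    **align_kwargs,
) -> tuple[list[str], list[int]]:
    """Reference-anchored column stack.

    Aligns every record to the reference and reads, for each reference
    position in ``span`` (default: the whole reference), the query residue at
    the mapped position, or ``-`` where unmapped.  Returns one row string per
    record plus the reference positions of the columns.  This stack is how
    logos, consensi and profiles define their columns — no multiple
    alignment is inferred.
    """
    ref_seq = reference.sequence if isinstance(reference, ProteinRecord) else str(reference)
    positions = list(span) if span is not None else list(range(1, len(ref_seq) + 1))
    if refmaps is None:
        refmaps = [build_reference_map(r, ref_seq, **align_kwargs) for r in records]
    rows: list[str] = []
    for record, rmap in zip(records, refmaps):
        chars = []
        for rpos in positions:
            qpos = rmap.to_query(rpos) if rmap is not None else None
            chars.append(record.sequence[qpos - 1] if qpos is not None else "-")
        rows.append("".join(chars))
    return rows, positions


class PositionFrequencyMatrix:
    """Per-column residue counts with pseudocounted frequencies and IC.

    Counts cover the 20 standard amino acids; gaps (``-``) and unknowns
    (``?``, ``X``) are excluded from the counts and tracked separately.
    Information content per column is ``log2(20) - H`` with ``H`` the Shannon
    entropy (bits) of the column frequencies; a column with no observations
    has undefined IC (NaN), not zero.
    """

    def __init__(self, counts: pd.DataFrame, gap_counts: np.ndarray,
                 pseudocount: float = 0.0) -> None:
        if list(counts.columns) != list(AMINO_ACIDS):
            raise ValueError("counts must have the 20 amino-acid columns")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.counts = counts
        self.gap_counts = np.asarray(gap_counts)
        self.pseudocount = float(pseudocount)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_observations(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        c = self.counts.to_numpy(dtype=float) + self.pseudocount / 20.0
        n = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, c / n, np.nan)
        return pd.DataFrame(f, columns=list(AMINO_ACIDS), index=self.counts.index)

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits; NaN where a column has zero observations."""
        f = self.frequencies().to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        h = -np.nansum(plogp, axis=1)
        ic = MAX_IC_BITS - h
        ic = np.where(np.isnan(f).all(axis=1), np.nan, ic)
        return ic

    def logo_data(self) -> pd.DataFrame:
        """Per-column letter heights (frequency x IC), the sequence-logo data."""
        ic = self.information_content()
        return self.frequencies().mul(ic, axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["gaps"] = self.gap_counts
        out["ic_bits"] = self.information_content()
        return out


def build_pfm(rows: Iterable[str], pseudocount: float = 0.0) -> PositionFrequencyMatrix:
    """Build a position frequency matrix from equal-length row strings.

    Rows typically come from :func:`stack_reference_columns` or from the
    per-motif strings of :class:`MotifCall` objects.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one sequence")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("all rows must have equal length")
    counts = np.zeros((width, 20), dtype=int)
    gaps = np.zeros(width, dtype=int)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for row in rows:
        for j, ch in enumerate(row):
            if ch in aa_index:
                counts[j, aa_index[ch]] += 1
            elif ch in "-?":
                gaps[j] += 1
            # X and anything else: unobserved
    return PositionFrequencyMatrix(
        pd.DataFrame(counts, columns=list(AMINO_ACIDS)), gaps, pseudocount
    )


@dataclass(frozen=True)
class ConsensusSequence:
    """Threshold consensus: modal residue where its non-gap frequency >= t.

    Columns that are majority-gap are dropped from the consensus string and
    listed in ``dropped_columns`` (indices into the input columns).
    """

    threshold: float
    sequence: str
    kept_columns: tuple[int, ...]
    dropped_columns: tuple[int, ...]
    coverage: tuple[int, ...]  # non-gap observations per kept column


def consensus(rows: Sequence[str], t: float) -> ConsensusSequence:
    """Threshold consensus over stacked columns.

    ``t`` must be in (0.5, 1].  Per column the frequencies are computed over
    non-gap observations; the modal residue is emitted if its frequency
    reaches ``t``, else ``X``.  Ties in the mode are broken alphabetically
    (irrelevant above t=0.5).
    """
    if not rows:
        raise ValueError("need at least one sequence")
    if not (0.5 < t <= 1.0):
        raise ValueError(f"threshold must be in (0.5, 1], got {t}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("all rows must have equal length")
    chars: list[str] = []
    kept: list[int] = []
    dropped: list[int] = []
    coverage: list[int] = []
    for j in range(width):
        col = [r[j] for r in rows]
        letters = [c for c in col if c not in "-?"]
        n_gap = len(col) - len(letters)
        if n_gap > len(letters):
            dropped.append(j)
            continue
        if not letters:
            dropped.append(j)
            continue
        counter = Counter(letters)
        modal, count = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        chars.append(modal if count / len(letters) >= t else "X")
        kept.append(j)
        coverage.append(len(letters))
    return ConsensusSequence(
        threshold=t,
        sequence="".join(chars),
        kept_columns=tuple(kept),
        dropped_columns=tuple(dropped),
        coverage=tuple(coverage),
    )
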