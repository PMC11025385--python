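"""Global pairwise alignment and reference coordinate maps.

All residue coordinates in this package are 1-based and refer to the human
MANEA numbering unless explicitly marked as catalytic-domain coordinates,
which are shifted by -97 (domain position 92 is full-length position 189).

The aligner is a global Needleman-Wunsch with affine gaps: a gap of length
``k`` costs ``gap_open + k * gap_extend``.  BLOSUM62 with conventional
protein defaults (open 11, extend 1) is the default scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

CATALYTIC_DOMAIN_OFFSET = 97

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

__all__ = [
    "CATALYTIC_DOMAIN_OFFSET",
    "AlignmentResult",
    "ReferenceMap",
    "load_matrix",
    "global_align",
    "build_reference_map",
    "shift_numbering",
]


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    """Load a symmetric substitution matrix (scores defined for X)."""
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with its score and identity measures."""

    aligned_a: str
    aligned_b: str
    score: float
    gap_open: float
    gap_extend: float
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def matches(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )

    @property
    def identity_aligned(self) -> float:
        """Matches over aligned columns (no double-gap columns occur)."""
        return self.matches / len(self.aligned_a)

    @property
    def identity_shorter(self) -> float:
        """Matches over the shorter input length (cd-hit-style identity)."""
        la = len(self.aligned_a.replace("-", ""))
        lb = len(self.aligned_b.replace("-", ""))
        return self.matches / min(la, lb)

    def unaligned(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # biopython charges open_gap_score for the first gap position, so a gap
    # of length k scores open + (k-1)*extend; shift to open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is returned.  End gaps are penalized like internal gaps.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else str(a)
    sb = b.sequence if isinstance(b, ProteinRecord) else str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    matrix_name = "BLOSUM62" if matrix is None else getattr(matrix, "name", "custom")
    if matrix is None:
        matrix = load_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = next(iter(aligner.align(sa, sb)))
    return AlignmentResult(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        gap_open=gap_open,
        gap_extend=gap_extend,
        matrix_name=matrix_name,
    )


class ReferenceMap:
    """Partial bidirectional map between query and reference positions.

    Contains exactly the match/mismatch columns of a global alignment; gap
    columns are unmapped.  Both coordinate systems are 1-based and the map is
    strictly increasing in both directions.
    """

    def __init__(self, query_to_ref: dict[int, int], identity: float = 1.0) -> None:
        items = sorted(query_to_ref.items())
        last_r = 0
        for q, r in items:
            if r <= last_r:
                raise ValueError("reference map must be strictly increasing")
            last_r = r
        self._q2r = dict(items)
        self._r2q = {r: q for q, r in items}
        self.identity = identity

    def __len__(self) -> int:
        return len(self._q2r)

    def to_reference(self, query_pos: int) -> int | None:
        return self._q2r.get(query_pos)

    def to_query(self, ref_pos: int) -> int | None:
        return self._r2q.get(ref_pos)

    @property
    def mapped_query_positions(self) -> tuple[int, ...]:
        return tuple(self._q2r)

    @property
    def mapped_reference_positions(self) -> tuple[int, ...]:
        return tuple(sorted(self._r2q))

    @classmethod
    def identity_map(cls, length: int) -> "ReferenceMap":
        return cls({i: i for i in range(1, length + 1)})


def build_reference_map(
    query: str | ProteinRecord,
    reference: str | ProteinRecord,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    identity_floor: float = 0.15,
) -> ReferenceMap | None:
    """Map query positions onto reference numbering via global alignment.

    Returns ``None`` (an "unmappable" signal, not an error) when the
    fractional identity over the shorter sequence falls below
    ``identity_floor``.
    """
    aln = global_align(query, reference, matrix=matrix,
                       gap_open=gap_open, gap_extend=gap_extend)
    if aln.identity_shorter < identity_floor:
        return None
    q2r: dict[int, int] = {}
    qpos = rpos = 0
    for cq, cr in zip(aln.aligned_a, aln.aligned_b):
        if cq != "-":
            qpos += 1
        if cr != "-":
            rpos += 1
        if cq != "-" and cr != "-":
            q2r[qpos] = rpos
    return ReferenceMap(q2r, identity=aln.identity_shorter)


def shift_numbering(
    pos: int, direction: Literal["domain_to_full", "full_to_domain"]
) -> int:
    """Convert between catalytic-domain and full-length MANEA numbering.

    The catalytic-domain numbering is shifted by -97 relative to full-length:
    domain 92 <-> full 189.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if direction == "domain_to_full":
        return pos + CATALYTIC_DOMAIN_OFFSET
    if direction == "full_to_domain":
        out = pos - CATALYTIC_DOMAIN_OFFSET
        if out < 1:
            raise ValueError(
                f"full-length position {pos} has no catalytic-domain equivalent"
            )
        return out
    raise ValueError(f"unknown direction {direction!r}")
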