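"""Position-specific scoring profiles for MANEA / MANEAL / CMANEAL.

The three vertebrate GH99 ohnologs are discriminated by catalytic-domain
profiles: per-position log-odds scores (base 2) built from reference-anchored
seed columns over the catalytic-domain span (full-length position 98 onward,
i.e. domain numbering shifted by -97).  A query is scored against each
profile by optimal global profile-to-sequence alignment with affine gaps and
labelled by the best profile when its lead over the runner-up reaches the
decision margin delta (in bits); otherwise it is left unclassified.  The
pairwise score-difference table is retained for export, since plotting score
differences is what separates the three ohnolog clusters (ancestral
single-copy sequences fall in with MANEA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import CATALYTIC_DOMAIN_OFFSET, DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN
from .motifs import build_pfm, stack_reference_columns
from .seqio import AMINO_ACIDS, ProteinRecord

# Robinson-Robinson style background amino-acid frequencies (normalized on use)
BACKGROUND_FREQUENCIES: dict[str, float] = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}

DEFAULT_ALPHA = 0.5
DEFAULT_DELTA = 2.0

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

__all__ = [
    "BACKGROUND_FREQUENCIES",
    "ProfileModel",
    "OhnologCall",
    "build_profile",
    "score_profile",
    "classify_ohnolog",
    "classify_cohort",
    "delta_table",
]


def _background_vector(background: dict[str, float] | None) -> np.ndarray:
    bg = BACKGROUND_FREQUENCIES if background is None else background
    q = np.array([bg[a] for a in AMINO_ACIDS], dtype=float)
    return q / q.sum()


@dataclass(frozen=True)
class ProfileModel:
    """Per-position log-odds scores (bits) over the 20 amino acids.

    ``scores[j, a]`` is the score of amino acid ``a`` at profile position
    ``j``; an ``X`` (or unseen column) scores 0, i.e. background.
    """

    name: str
    scores: np.ndarray  # (length, 20)
    alpha: float
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    reference_start: int = CATALYTIC_DOMAIN_OFFSET + 1
    n_seeds: int = 0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20 or scores.shape[0] == 0:
            raise ValueError("scores must be a non-empty (length, 20) array")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "alpha": self.alpha,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "reference_start": self.reference_start,
            "n_seeds": self.n_seeds,
            "alphabet": AMINO_ACIDS,
            "scores": self.scores.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileModel":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            scores=np.array(d["scores"], dtype=float),
            alpha=d["alpha"],
            gap_open=d["gap_open"],
            gap_extend=d["gap_extend"],
            reference_start=d["reference_start"],
            n_seeds=d.get("n_seeds", 0),
        )


def build_profile(
    seed_records: Sequence[ProteinRecord],
    name: str,
    reference: str | ProteinRecord,
    alpha: float = DEFAULT_ALPHA,
    background: dict[str, float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    **align_kwargs,
) -> ProfileModel:
    """Build a catalytic-domain profile from seed sequences.

    Columns come from reference-anchored stacking over full-length positions
    98..end (the catalytic domain under the -97 offset).  The score of amino
    acid ``a`` at column ``j`` is::

        log2( ((c_aj + alpha * q_a) / (n_j + alpha)) / q_a )

    with ``c_aj`` the seed count, ``n_j`` the column's observation count and
    ``q`` the background frequencies.  Columns with no observations score 0
    for every letter.
    """
    if len(seed_records) < 2:
        raise ValueError("need at least 2 seed sequences to build a profile")
    ref_seq = reference.sequence if isinstance(reference, ProteinRecord) else str(reference)
    span = list(range(CATALYTIC_DOMAIN_OFFSET + 1, len(ref_seq) + 1))
    rows, _ = stack_reference_columns(seed_records, ref_seq, span=span, **align_kwargs)
    pfm = build_pfm(rows)
    q = _background_vector(background)
    c = pfm.counts.to_numpy(dtype=float)
    n = c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (c + alpha * q) / (n + alpha)
        scores = np.log2(f / q)
    scores = np.where(n > 0, scores, 0.0)
    return ProfileModel(
        name=name,
        scores=scores,
        alpha=alpha,
        gap_open=gap_open,
        gap_extend=gap_extend,
        reference_start=CATALYTIC_DOMAIN_OFFSET + 1,
        n_seeds=len(seed_records),
    )


def score_profile(model: ProfileModel, record: ProteinRecord | str) -> float:
    """Bit score of the optimal global profile-to-sequence alignment.

    Affine gaps (cost ``open + k*ext`` for a gap of length ``k``) on both the
    profile and the sequence side; end gaps are penalized.  ``X`` and any
    letter outside the 20-letter alphabet score 0 at every position.
    Deterministic, and invariant to record metadata.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record)
    if not seq:
        raise ValueError("cannot score an empty sequence")
    S = model.scores
    m = S.shape[0]
    n = len(seq)
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in seq])
    known = idx >= 0
    open_, ext = float(model.gap_open), float(model.gap_extend)

    j = np.arange(n + 1, dtype=float)
    V = -(open_ + j * ext)
    V[0] = 0.0
    F = np.full(n + 1, -np.inf)
    jext = j * ext
    for i in range(1, m + 1):
        srow = np.where(known, S[i - 1, np.where(known, idx, 0)], 0.0)
        F = np.maximum(F - ext, V - open_ - ext)
        W = np.empty(n + 1)
        W[0] = -(open_ + i * ext)
        W[1:] = np.maximum(V[:-1] + srow, F[1:])
        # best horizontal-gap entry per column via running prefix max
        acc = np.maximum.accumulate(W + jext)
        V = W.copy()
        np.maximum(V[1:], acc[:-1] - open_ - jext[1:], out=V[1:])
    return float(V[n])


@dataclass(frozen=True)
class OhnologCall:
    """Per-model scores and the margin-gated best label."""

    record_id: str
    scores: dict[str, float]
    label: str  # model name or "unclassified"
    margin: float
    delta: float
    deltas: dict[str, float] = field(default_factory=dict)


def classify_ohnolog(
    record: ProteinRecord,
    models: Sequence[ProfileModel],
    delta: float = DEFAULT_DELTA,
) -> OhnologCall:
    """Classify a record among profiles (canonically the three ohnologs).

    The label is the best-scoring model's name when its lead over the
    runner-up is at least ``delta`` bits, else ``unclassified``.  The full
    pairwise score-difference table is retained.
    """
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("profile model names must be distinct")
    scores = {m.name: score_profile(m, record) for m in models}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else np.inf
    label = ranked[0][0] if margin >= delta else "unclassified"
    deltas = {
        f"{a}-{b}": scores[a] - scores[b]
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    return OhnologCall(
        record_id=record.id if isinstance(record, ProteinRecord) else "",
        scores=scores,
        label=label,
        margin=float(margin),
        delta=float(delta),
        deltas=deltas,
    )


def classify_cohort(
    records: Iterable[ProteinRecord],
    models: Sequence[ProfileModel],
    delta: float = DEFAULT_DELTA,
) -> list[OhnologCall]:
    return [classify_ohnolog(r, models, delta) for r in records]


def delta_table(calls: Iterable[OhnologCall]) -> pd.DataFrame:
    """Score/delta table (one row per record) for export and plotting."""
    rows = []
    for c in calls:
        row: dict[str, object] = {"id": c.record_id}
        row.update({f"score_{k}": v for k, v in c.scores.items()})
        row.update({f"delta_{k}": v for k, v in c.deltas.items()})
        row["margin"] = c.margin
        row["label"] = c.label
        rows.append(row)
    return pd.DataFrame(rows)
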