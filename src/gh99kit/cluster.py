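"""Greedy identity clustering with cd-hit semantics.

Records are sorted by length (descending, ties by id) and processed in
order; each record joins the best eligible existing cluster — the
representative with the highest identity at least ``c`` among those passing
the length-difference cutoff ``s`` (cd-hit's ``-g 1`` accurate mode) — or
founds a new cluster.  Identity is matches over the shorter sequence length,
computed from a full global alignment rather than cd-hit's short-word
filter: the filter is an accelerator, not part of the definition.
Defaults c=0.95, s=0.5 match ``cd-hit -c 0.95 -s 0.5 -g 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import global_align
from .seqio import ProteinRecord

__all__ = ["ClusterAssignment", "greedy_cluster"]


@dataclass
class ClusterAssignment:
    """Clusters as representative id -> member ids (representative included)."""

    threshold: float
    length_cutoff: float
    clusters: dict[str, list[str]] = field(default_factory=dict)
    identities: dict[str, float] = field(default_factory=dict)  # member -> identity to rep

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(self.clusters)

    def representative_of(self, member_id: str) -> str:
        for rep, members in self.clusters.items():
            if member_id in members:
                return rep
        raise KeyError(f"{member_id!r} not in any cluster")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (rep, members) in enumerate(self.clusters.items()):
            for m in members:
                rows.append(
                    {
                        "cluster_id": i,
                        "representative": rep,
                        "member": m,
                        "identity": self.identities[m],
                    }
                )
        return pd.DataFrame(rows)


def greedy_cluster(
    records: Sequence[ProteinRecord],
    c: float = 0.95,
    s: float = 0.5,
    **align_kwargs,
) -> ClusterAssignment:
    """Greedy incremental clustering at identity threshold ``c``.

    Canonical regardless of input order (records are sorted by length
    descending, ties by id ascending).  Ties between equally good clusters
    break by representative id ascending.
    """
    if not (0.0 < c <= 1.0):
        raise ValueError(f"identity threshold c must be in (0, 1], got {c}")
    if not (0.0 < s <= 1.0):
        raise ValueError(f"length cutoff s must be in (0, 1], got {s}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    by_id = {r.id: r for r in ordered}
    if len(by_id) != len(ordered):
        raise ValueError("duplicate record ids in input")
    assignment = ClusterAssignment(threshold=c, length_cutoff=s)
    for rec in ordered:
        best: tuple[float, str] | None = None
        for rep_id in assignment.clusters:
            rep = by_id[rep_id]
            if len(rec) < s * len(rep):
                continue
            identity = global_align(rec, rep, **align_kwargs).identity_shorter
            if identity < c:
                continue
            # higher identity wins; ties by representative id ascending
            if best is None or (identity, ) > (best[0], ) or (
                identity == best[0] and rep_id < best[1]
            ):
                best = (identity, rep_id)
        if best is None:
            assignment.clusters[rec.id] = [rec.id]
            assignment.identities[rec.id] = 1.0
        else:
            identity, rep_id = best
            assignment.clusters[rep_id].append(rec.id)
            assignment.identities[rec.id] = identity
    return assignment
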