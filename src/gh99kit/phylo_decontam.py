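"""Distance trees and taxonomy-incongruence decontamination.

Public survey databases mix sequences across samples, so a protein labelled
with one taxogroup occasionally nests, phylogenetically, deep inside another
— the signature of contamination.  This module builds neighbor-joining
trees from pairwise alignment distances and iteratively flags leaves whose
smallest enclosing clade of at least ``k`` leaves has a strict-majority
taxogroup different from the leaf's own (the leaf being in the minority
there).  Because NJ trees are unrooted, "enclosing clade" is defined
rooting-free as the smallest side, among all edge-induced splits, that
contains the leaf and has at least ``k`` leaves.  Flagged leaves are
removed, the tree is rebuilt from the remaining distances, and the
procedure repeats until a round flags nothing or ``max_rounds`` is reached.
The majority-clade rule is this package's explicit operationalization of
phylogeny-based decontamination and is recorded as such in report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import global_align
from .seqio import ProteinRecord, TaxonomyTable

__all__ = [
    "ContaminationReport",
    "pairwise_distance",
    "neighbor_joining",
    "flag_contaminants",
    "leaf_paths_from_records",
]

DECONTAMINATION_RULE = (
    "majority-clade rule: a leaf is flagged when its smallest enclosing "
    "clade (smallest split-side of the unrooted NJ tree containing the "
    "leaf, with >= k leaves) has a strict-majority taxogroup different "
    "from the leaf's, the leaf's taxogroup is a minority there, and the "
    "majority taxogroup also occurs on the other side of the split (the "
    "leaf is nested inside, not merely sister to, the foreign group)"
)


def pairwise_distance(records: Sequence[ProteinRecord], **align_kwargs) -> DistanceMatrix:
    """All-pairs distances d = 1 - fractional identity over aligned columns."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    dm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_align(records[i], records[j], **align_kwargs).identity_aligned
            dm[i][j] = dm[j][i] = d
    return DistanceMatrix(dm, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; negative branch lengths are clamped to 0.

    Exact on additive distance matrices (recovers topology and lengths).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry and zero diagonal
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    return nj(dm)


def leaf_paths_from_records(
    records: Sequence[ProteinRecord],
    tax: TaxonomyTable | None = None,
) -> dict[str, tuple[str, ...]]:
    """Map record ids to clade paths, via the taxonomy when given."""
    out: dict[str, tuple[str, ...]] = {}
    for r in records:
        if tax is not None and r.species in tax:
            out[r.id] = tax.clade_path(r.species)
        else:
            out[r.id] = r.clade_path
    return out


@dataclass
class ContaminationReport:
    """Per-round flags and the surviving leaf set."""

    flagged: list[dict] = field(default_factory=list)
    surviving: tuple[str, ...] = ()
    rounds: int = 0
    k: int = 3
    level: int = 0
    rule: str = DECONTAMINATION_RULE

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return tuple(f["id"] for f in self.flagged)


def _group_of(path: Sequence[str], level: int) -> str:
    return path[level] if level < len(path) else path[-1]


def _split_sides(tree: TreeNode) -> list[frozenset[str]]:
    """Every edge-induced leaf bipartition side of the (unrooted) tree."""
    all_tips = frozenset(t.name for t in tree.tips())
    sides: set[frozenset[str]] = set()
    for node in tree.postorder(include_self=False):
        sub = frozenset(
            t.name for t in (node.tips() if not node.is_tip() else [node])
        )
        if 0 < len(sub) < len(all_tips):
            sides.add(sub)
            sides.add(all_tips - sub)
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


def _flag_one_round(
    tree: TreeNode,
    groups: Mapping[str, str],
    k: int,
) -> list[dict]:
    sides = _split_sides(tree)
    all_tips = frozenset(t.name for t in tree.tips())
    flags = []
    for leaf in tree.tips():
        # smallest split-side containing the leaf with >= k leaves
        # (sides are pre-sorted by size, ties by leaf names: deterministic)
        clade = next(
            (s for s in sides if leaf.name in s and len(s) >= k), None
        )
        if clade is None:
            continue
        counts: dict[str, int] = {}
        for name in clade:
            counts[groups[name]] = counts.get(groups[name], 0) + 1
        majority_group, majority_count = max(
            counts.items(), key=lambda kv: (kv[1], kv[0])
        )
        leaf_group = groups[leaf.name]
        # nestedness: the majority group must also occur outside the split,
        # otherwise the leaf is merely sister to that group's whole clade
        witnesses = frozenset(
            name for name in all_tips - clade if groups[name] == majority_group
        )
        if (
            majority_count * 2 > len(clade)
            and majority_group != leaf_group
            and counts[leaf_group] < majority_count
            and witnesses
        ):
            flags.append(
                {
                    "id": leaf.name,
                    "leaf_taxogroup": leaf_group,
                    "majority_taxogroup": majority_group,
                    "clade_size": len(clade),
                    "witnesses": witnesses,
                }
            )
    # a flag whose nestedness witnesses are all themselves flagged this round
    # (e.g. a contaminant's wrong label vouching for its neighbours) is
    # suspect; void such claims one at a time, weakest backing first (fewest
    # unflagged members of the claimed majority group), so that a strongly
    # backed flag survives a cycle of mutually-supporting claims
    while True:
        flagged_ids = {f["id"] for f in flags}
        starved = [f for f in flags if not (f["witnesses"] - flagged_ids)]
        if not starved:
            break

        def backing(f: dict) -> int:
            return sum(
                1
                for name, g in groups.items()
                if g == f["majority_taxogroup"] and name not in flagged_ids
            )

        starved.sort(key=lambda f: (backing(f), f["id"]))
        flags.remove(starved[0])
    for f in flags:
        f["witnesses"] = ";".join(sorted(f["witnesses"]))
    return flags


def flag_contaminants(
    dm: DistanceMatrix,
    leaf_paths: Mapping[str, Sequence[str]],
    k: int = 3,
    level: int = 0,
    max_rounds: int = 5,
) -> ContaminationReport:
    """Iterative taxonomy-incongruence flagging over rebuilt NJ trees.

    ``leaf_paths`` maps every leaf id to its clade path; ``level`` picks the
    path depth used as the taxogroup (0 = top).  Idempotent on the surviving
    set: the procedure runs until a round flags nothing (or ``max_rounds``).
    """
    missing = [i for i in dm.ids if i not in leaf_paths]
    if missing:
        raise KeyError(f"leaf {missing[0]!r} missing from taxonomy")
    groups = {i: _group_of(leaf_paths[i], level) for i in dm.ids}
    report = ContaminationReport(k=k, level=level)
    current = dm
    for round_no in range(1, max_rounds + 1):
        if current.shape[0] < 3:
            break
        report.rounds = round_no
        tree = neighbor_joining(current)
        flags = _flag_one_round(tree, groups, k)
        if not flags:
            break
        for f in flags:
            f["round"] = round_no
        report.flagged.extend(flags)
        keep = [i for i in current.ids if i not in {f["id"] for f in flags}]
        current = current.filter(keep)
    report.surviving = tuple(current.ids)
    return report
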