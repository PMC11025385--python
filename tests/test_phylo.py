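"""Neighbor joining exactness and taxonomy-incongruence decontamination."""

import itertools
import random

import numpy as np
import pytest
from skbio import DistanceMatrix

from gh99kit.phylo_decontam import (
    flag_contaminants,
    leaf_paths_from_records,
    neighbor_joining,
    pairwise_distance,
)
from gh99kit.synth import (
    ContaminantSpec,
    SimulationConfig,
    SubfamilySpec,
    simulate_family,
)

# ---------------------------------------------------------------- oracle trees


def random_additive_tree(taxa, rng):
    """Random unrooted binary tree as an edge list with positive lengths."""
    nodes = list(taxa[:3])
    internal = ["I0"]
    edges = [(t, "I0", rng.uniform(0.5, 2.0)) for t in taxa[:3]]
    for i, taxon in enumerate(taxa[3:], start=1):
        u, v, w = edges.pop(rng.randrange(len(edges)))
        mid = f"I{i}"
        split = rng.uniform(0.2, 0.8) * w
        edges += [
            (u, mid, split),
            (mid, v, w - split),
            (taxon, mid, rng.uniform(0.5, 2.0)),
        ]
    return edges


def tree_distance_matrix(edges, taxa):
    """Leaf-to-leaf path lengths by Dijkstra-free BFS over the edge list."""
    adj = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(taxa)
    M = np.zeros((n, n))
    for i, start in enumerate(taxa):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    stack.append(nxt)
        for j, t in enumerate(taxa):
            M[i, j] = dist[t]
    np.fill_diagonal(M, 0.0)
    return (M + M.T) / 2.0  # exact symmetry despite float summation order


def tree_splits(edges, taxa):
    """Non-trivial leaf bipartitions induced by internal edges."""
    taxa_set = frozenset(taxa)
    adj = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v, _ in edges:
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt != v and nxt not in seen and not (node == u and nxt == v):
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(t for t in taxa if t in seen)
        if 1 < len(side) < len(taxa) - 1:
            splits.add(min(side, taxa_set - side, key=sorted))
    return splits


def skbio_splits(tree, taxa):
    taxa_set = frozenset(taxa)
    splits = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(min(side, taxa_set - side, key=sorted))
    return splits


def all_five_taxon_topologies(taxa):
    """All 15 labeled unrooted binary topologies on 5 taxa, as edge lists
    with unit lengths (lengths get assigned by the caller)."""
    a, b, c, d, e = taxa
    base = [(a, "I0", 1.0), (b, "I0", 1.0), (c, "I0", 1.0)]
    # 4-taxon trees: attach d to each of the 3 edges of the star
    four = []
    for i in range(3):
        edges = [tuple(x) for x in base]
        u, v, w = edges.pop(i)
        edges += [(u, "I1", 1.0), ("I1", v, 1.0), (d, "I1", 1.0)]
        four.append(edges)
    out = []
    for edges in four:
        for i in range(len(edges)):
            new = [tuple(x) for x in edges]
            u, v, w = new.pop(i)
            new += [(u, "I2", 1.0), ("I2", v, 1.0), (e, "I2", 1.0)]
            out.append(new)
    return out


def least_squares_sse(edges, taxa, target):
    """SSE of the best least-squares branch lengths for a fixed topology."""
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    adj = {}
    for idx, (u, v, _) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path_edges(s, t):
        prev = {s: None}
        stack = [s]
        while stack:
            node = stack.pop()
            for nxt, idx in adj[node]:
                if nxt not in prev:
                    prev[nxt] = (node, idx)
                    stack.append(nxt)
        out = []
        node = t
        while prev[node] is not None:
            node, idx = prev[node]
            out.append(idx)
        return out

    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for idx in path_edges(taxa[i], taxa[j]):
            A[row, idx] = 1.0
        y[row] = target[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


# ------------------------------------------------------------------- NJ tests


def test_three_taxa_closed_form():
    # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> a=1, b=2, c=3 via three-point formulas
    dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["A", "B", "C"])
    tree = neighbor_joining(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    td = tree.tip_tip_distances(["A", "B", "C"])
    assert np.allclose(td.data, dm.data)
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((A:1,B:2):1,(C:3,D:1))
    taxa = ["A", "B", "C", "D"]
    M = np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
    )
    tree = neighbor_joining(DistanceMatrix(M, taxa))
    td = tree.tip_tip_distances(taxa)
    assert np.allclose(td.data, M)
    assert skbio_splits(tree, taxa) == {frozenset(["A", "B"])}


def test_all_five_taxon_topologies_recovered_with_ls_oracle():
    """NJ recovers each of the 15 labeled 5-taxon topologies from additive
    matrices, agreeing with exhaustive least-squares topology search."""
    taxa = ["A", "B", "C", "D", "E"]
    rng = random.Random(42)
    topologies = all_five_taxon_topologies(taxa)
    assert len(topologies) == 15
    for edges in topologies:
        edges = [(u, v, rng.uniform(0.5, 2.0)) for u, v, _ in edges]
        M = tree_distance_matrix(edges, taxa)
        tree = neighbor_joining(DistanceMatrix(M, taxa))
        assert np.allclose(tree.tip_tip_distances(taxa).data, M, atol=1e-9)
        assert skbio_splits(tree, taxa) == tree_splits(edges, taxa)
        # independent oracle: the true topology is the unique SSE=0 fit
        sses = [least_squares_sse(t, taxa, M) for t in topologies]
        best = int(np.argmin(sses))
        assert tree_splits(topologies[best], taxa) == tree_splits(edges, taxa)
        assert sses[best] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n_taxa", [6, 7, 8])
def test_random_additive_matrices_recovered(n_taxa):
    rng = random.Random(n_taxa)
    taxa = [f"T{i}" for i in range(n_taxa)]
    for _ in range(12):
        edges = random_additive_tree(taxa, rng)
        M = tree_distance_matrix(edges, taxa)
        tree = neighbor_joining(DistanceMatrix(M, taxa))
        assert np.allclose(tree.tip_tip_distances(taxa).data, M, atol=1e-9)
        assert skbio_splits(tree, taxa) == tree_splits(edges, taxa)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]))
    with pytest.raises(Exception):
        DistanceMatrix([[0, 1, 2], [9, 0, 1], [2, 1, 0]], list("ABC"))


# ----------------------------------------------------------- distance matrix


def test_pairwise_distance_closed_cases():
    from gh99kit.seqio import ProteinRecord

    recs = [
        ProteinRecord(id="a", sequence="MKTWED"),
        ProteinRecord(id="b", sequence="MKTWED"),
        ProteinRecord(id="c", sequence="MKTWEL"),
    ]
    dm = pairwise_distance(recs)
    assert dm["a", "b"] == 0.0
    assert dm["a", "c"] == pytest.approx(1 / 6)


def test_pairwise_distance_matches_recompute(small_cohort):
    from gh99kit.align import global_align

    records, _ = small_cohort
    subset = records[:5]
    dm = pairwise_distance(subset)
    for i in range(5):
        for j in range(i + 1, 5):
            expected = 1.0 - global_align(subset[i], subset[j]).identity_aligned
            assert dm[subset[i].id, subset[j].id] == pytest.approx(expected)


def test_pairwise_distance_needs_three():
    from gh99kit.seqio import ProteinRecord

    with pytest.raises(ValueError):
        pairwise_distance([ProteinRecord(id="a", sequence="MK")] )


# ----------------------------------------------------------- decontamination


def test_homogeneous_group_nothing_flagged():
    config = SimulationConfig(subfamilies=[SubfamilySpec("A", n=8, p=0.05)], seed=4)
    records, _ = simulate_family(config)
    report = flag_contaminants(
        pairwise_distance(records), leaf_paths_from_records(records), k=3
    )
    assert report.flagged == []
    assert report.rounds == 1
    assert set(report.surviving) == {r.id for r in records}


def test_planted_contaminant_flagged_exactly(contaminated_cohort):
    records, truth = contaminated_cohort
    report = flag_contaminants(
        pairwise_distance(records), leaf_paths_from_records(records), k=3
    )
    planted = set(truth.index[truth.contaminant])
    assert set(report.flagged_ids) == planted
    assert report.flagged[0]["majority_taxogroup"] == "GroupA"
    assert report.flagged[0]["leaf_taxogroup"] == "GroupB"


def test_decontamination_idempotent(contaminated_cohort):
    records, _ = contaminated_cohort
    report = flag_contaminants(
        pairwise_distance(records), leaf_paths_from_records(records), k=3
    )
    survivors = [r for r in records if r.id in report.surviving]
    rerun = flag_contaminants(
        pairwise_distance(survivors), leaf_paths_from_records(survivors), k=3
    )
    assert rerun.flagged == []
    assert set(rerun.surviving) == set(report.surviving)


def test_balanced_groups_without_intermixing_never_flagged():
    for k in (3, 4, 5):
        config = SimulationConfig(
            subfamilies=[SubfamilySpec("A", n=6, p=0.05), SubfamilySpec("B", n=6, p=0.05)],
            seed=2,
        )
        records, _ = simulate_family(config)
        report = flag_contaminants(
            pairwise_distance(records), leaf_paths_from_records(records), k=k
        )
        assert report.flagged == []


def test_missing_leaf_taxonomy_is_error(contaminated_cohort):
    records, _ = contaminated_cohort
    dm = pairwise_distance(records)
    paths = leaf_paths_from_records(records)
    victim = records[0].id
    del paths[victim]
    with pytest.raises(KeyError, match=victim):
        flag_contaminants(dm, paths, k=3)
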