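import itertools
import random

import networkx as nx
import pytest

from srnapipe.annotate import AnnotationLabel
from srnapipe.network import (
    SimilarityGraph,
    build_similarity_graph,
    classify_conservation,
    connected_components,
    define_candidate_clusters,
    fast_greedy_communities,
    partition_modularity,
    select_abundant,
    select_representatives,
)
from srnapipe.records import ReadRecord, ReferenceSet
from srnapipe.similarity import align_pair

from conftest import end_variant_reads, random_sequence


def mkgraph(n, edges, counts=None):
    g = SimilarityGraph(
        nodes={
            f"n{i}": ReadRecord(
                f"n{i}", "ACGTACGTACGTACGTACGTAC", {"l": (counts or {}).get(i, i + 1)}
            )
            for i in range(n)
        }
    )
    for u, v in edges:
        g.add_edge(f"n{u}", f"n{v}")
    return g


def exhaustive_best_partition(g: SimilarityGraph):
    """Best modularity over all set partitions of the nodes (Bell-number search)."""
    nodes = sorted(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1 :]
            yield part + [{head}]

    best_q, best = float("-inf"), None
    for part in partitions(nodes):
        assignment = {u: i for i, block in enumerate(part) for u in block}
        q = partition_modularity(g, assignment)
        if q > best_q:
            best_q, best = q, part
    return best_q, {frozenset(b) for b in best}


class TestSelectAbundant:
    def test_inclusive_threshold(self):
        r99 = ReadRecord("a", "A" * 22, {"l": 99})
        r100 = ReadRecord("b", "C" * 22, {"l": 100})
        out = select_abundant([r99, r100], {}, min_reads=100)
        assert [r.id for r in out] == ["b"]

    def test_annotated_reads_excluded(self):
        big = ReadRecord("a", "A" * 22, {"l": 10**6})
        labels = {"a": AnnotationLabel("a", "known:miR-1")}
        assert select_abundant([big], labels) == []

    def test_truth_fixture_ids(self, tiny_dataset):
        combined = tiny_dataset.combined_reads()
        out = select_abundant(combined, None, min_reads=100)
        assert {r.id for r in out} == {r.id for r in combined if r.total_count >= 100}


class TestGraph:
    def test_identical_sequences_share_an_edge(self):
        a = ReadRecord("a", "TGTGATGTGCATGTGGGCTTTCC", {"l": 5})
        b = ReadRecord("b", "TGTGATGTGCATGTGGGCTTTCC", {"l": 9})
        g = build_similarity_graph([a, b])
        assert g.n_edges == 1

    def test_unrelated_sequences_unlinked(self):
        rng = random.Random(3)
        a = ReadRecord("a", random_sequence(rng, 22), {"l": 5})
        b = ReadRecord("b", random_sequence(rng, 22), {"l": 5})
        g = build_similarity_graph([a, b])
        assert g.n_edges == 0

    def test_edges_match_allpairs_oracle(self):
        reads = end_variant_reads(n_loci=4, n_variants=5, seed=21)
        g = build_similarity_graph(reads)
        expected = set()
        for x, y in itertools.combinations(reads, 2):
            if x.sequence == y.sequence:
                expected.add(frozenset((x.id, y.id)))
                continue
            pa = align_pair(x.sequence, y.sequence)
            if pa.identity >= 0.9 and pa.coverage >= 0.95 and pa.columns >= 16:
                expected.add(frozenset((x.id, y.id)))
        assert g.edges == expected

    def test_no_self_edges(self):
        g = mkgraph(2, [])
        with pytest.raises(ValueError):
            g.add_edge("n0", "n0")


class TestComponents:
    def test_edgeless_and_path(self):
        assert [len(c) for c in connected_components(mkgraph(5, []))] == [1] * 5
        comps = connected_components(mkgraph(3, [(0, 1), (1, 2)]))
        assert comps == [{"n0", "n1", "n2"}]

    def test_random_graph_matches_networkx(self):
        rng = random.Random(0)
        edges = {(rng.randrange(50), rng.randrange(50)) for _ in range(60)}
        edges = [(u, v) for u, v in edges if u != v]
        g = mkgraph(50, edges)
        ours = {frozenset(c) for c in connected_components(g)}
        G = nx.Graph()
        G.add_nodes_from(f"n{i}" for i in range(50))
        G.add_edges_from((f"n{u}", f"n{v}") for u, v in edges)
        theirs = {frozenset(c) for c in nx.connected_components(G)}
        assert ours == theirs


class TestModularity:
    def test_all_in_one_is_zero(self):
        g = mkgraph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (2, 4)])
        assert partition_modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        g = mkgraph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assignment = {f"n{i}": 0 if i < 3 else 1 for i in range(6)}
        assert partition_modularity(g, assignment) == pytest.approx(0.5)

    def test_triangle_singletons(self):
        g = mkgraph(3, [(0, 1), (1, 2), (0, 2)])
        assert partition_modularity(g, {f"n{i}": i for i in range(3)}) == pytest.approx(-1 / 3)

    def test_edgeless_graph_error(self):
        with pytest.raises(ValueError):
            partition_modularity(mkgraph(3, []), {f"n{i}": 0 for i in range(3)})


class TestFastGreedy:
    def test_bridged_triangles(self):
        g = mkgraph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        cp = fast_greedy_communities(g)
        parts = {}
        for n, c in cp.assignment.items():
            parts.setdefault(c, set()).add(n)
        assert {frozenset(p) for p in parts.values()} == {
            frozenset({"n0", "n1", "n2"}),
            frozenset({"n3", "n4", "n5"}),
        }
        assert cp.Q == pytest.approx(2 * (3 / 7 - 0.25))

    def test_complete_graph_single_community(self):
        g = mkgraph(4, list(itertools.combinations(range(4), 2)))
        cp = fast_greedy_communities(g)
        assert len(set(cp.assignment.values())) == 1

    def test_disjoint_cliques_one_community_each(self):
        edges = list(itertools.combinations(range(5), 2)) + [
            (i + 5, j + 5) for i, j in itertools.combinations(range(5), 2)
        ]
        cp = fast_greedy_communities(mkgraph(10, edges))
        assert len(set(cp.assignment.values())) == 2
        assert cp.Q == pytest.approx(0.5)

    def test_never_below_all_in_one(self):
        rng = random.Random(5)
        for trial in range(10):
            edges = {(rng.randrange(12), rng.randrange(12)) for _ in range(18)}
            edges = [(u, v) for u, v in edges if u != v]
            if not edges:
                continue
            g = mkgraph(12, edges)
            cp = fast_greedy_communities(g)
            assert cp.Q >= -1e-12

    def test_edgeless_component_is_single_community(self, caplog):
        g = mkgraph(4, [(0, 1)])
        cp = fast_greedy_communities(g)
        assert len(set(cp.assignment.values())) == 3

    def test_matches_networkx_on_bridged_cliques(self):
        edges = list(itertools.combinations(range(4), 2)) + [
            (i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)
        ] + [(3, 4)]
        g = mkgraph(8, edges)
        cp = fast_greedy_communities(g)
        ours = {}
        for n, c in cp.assignment.items():
            ours.setdefault(c, set()).add(n)
        G = nx.Graph((f"n{u}", f"n{v}") for u, v in edges)
        theirs = nx.community.greedy_modularity_communities(G)
        assert {frozenset(p) for p in ours.values()} == {frozenset(c) for c in theirs}


class TestRepresentatives:
    def test_most_abundant_wins(self):
        g = mkgraph(2, [(0, 1)], counts={0: 4_585_181, 1: 12})
        cp = fast_greedy_communities(g)
        table = select_representatives(g, cp)
        assert len(table.rows) == 1
        assert table.rows[0].candidate_id == "n0"
        assert table.rows[0].total_count == 4_585_181 + 12

    def test_singleton_represents_itself(self):
        g = mkgraph(1, [])
        cp = fast_greedy_communities(g)
        table = select_representatives(g, cp)
        assert table.rows[0].candidate_id == "n0"

    def test_tie_breaks_to_smaller_sequence(self):
        g = SimilarityGraph(
            nodes={
                "x": ReadRecord("x", "CCCCCCCCCCCCCCCCCCCCCC", {"l": 5}),
                "y": ReadRecord("y", "ACCCCCCCCCCCCCCCCCCCCC", {"l": 5}),
            }
        )
        g.add_edge("x", "y")
        table = select_representatives(g, fast_greedy_communities(g))
        assert table.rows[0].sequence.startswith("A")

    def test_counts_conserved_through_selection(self):
        reads = end_variant_reads(n_loci=5, n_variants=6, seed=2)
        g = build_similarity_graph(reads)
        cp = fast_greedy_communities(g)
        table = select_representatives(g, cp)
        assert sum(r.total_count for r in table.rows) == sum(r.total_count for r in reads)


class TestConservation:
    def test_exact_and_near_miss(self):
        seq = "TGTGATGTGCATGTGGGCTTTCC"
        mutated = seq[:5] + ("A" if seq[5] != "A" else "C") + seq[6:]
        from srnapipe.records import CandidateRow, CandidateTable

        table = CandidateTable(
            rows=[
                CandidateRow("c1", seq, {"l": 200}, "unassigned", "-"),
                CandidateRow("c2", mutated, {"l": 150}, "unassigned", "-"),
            ],
            libraries=["l"],
        )
        species = {"species:spA": ReferenceSet("species:spA", [("m1", seq)])}
        records = classify_conservation(table, species)
        by_id = {r.candidate_id: r for r in records}
        assert by_id["c1"].conservation == "conserved"
        assert by_id["c1"].species_tags == ["species:spA"]
        assert by_id["c2"].conservation == "specific"

    def test_empty_species_sets_all_specific(self):
        from srnapipe.records import CandidateRow, CandidateTable

        table = CandidateTable(
            rows=[CandidateRow("c1", "A" * 22, {"l": 200}, "unassigned", "-")],
            libraries=["l"],
        )
        records = classify_conservation(table, {})
        assert records[0].conservation == "specific"


def test_define_candidate_clusters_small_components_whole():
    # two triangles joined by a bridge (major) + one disjoint edge (minor)
    edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3), (6, 7)]
    g = mkgraph(8, edges)
    cp = define_candidate_clusters(g)
    parts = {}
    for n, c in cp.assignment.items():
        parts.setdefault(c, set()).add(n)
    groups = {frozenset(p) for p in parts.values()}
    assert frozenset({"n6", "n7"}) in groups  # minor component stays one cluster
    assert frozenset({"n0", "n1", "n2"}) in groups  # major component is split
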