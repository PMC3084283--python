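"""Novel-candidate definition by similarity networks and modularity.

Abundant reads that remain unannotated are candidate novel miRNAs, but
most of them are end-variants of one another. They are organised as an
unweighted graph (nodes = sequences, edges = pairs at >= 90% identity and
>= 95% coverage), whose connected components and modular communities
define non-redundant candidates: each community is represented by its most
abundant member.

Modularity of a partition is Q = sum_i (e_ii - a_i^2), with e_ii the
fraction of edges inside community i and a_i the fraction of edge
endpoints in i. Communities are found by fast-greedy agglomeration
(Clauset-Newman-Moore style): start from singletons and repeatedly merge
the connected pair of communities with the largest modularity gain
dQ = 2 (e_ij - a_i a_j) while a positive gain exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import CandidateRow, CandidateTable, ReadRecord
from .similarity import candidate_pairs, pair_passes

logger = logging.getLogger(__name__)


@dataclass
class SimilarityGraph:
    """Unweighted graph over candidate reads (no self or duplicate edges)."""

    nodes: dict[str, ReadRecord] = field(default_factory=dict)
    edges: set[frozenset[str]] = field(default_factory=set)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError("self-edges not allowed")
        if u not in self.nodes or v not in self.nodes:
            raise ValueError(f"edge endpoints {u!r},{v!r} must be nodes")
        self.edges.add(frozenset((u, v)))

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {u: set() for u in self.nodes}
        for e in self.edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def degrees(self) -> dict[str, int]:
        deg = {u: 0 for u in self.nodes}
        for e in self.edges:
            u, v = tuple(e)
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    Q: float


def select_abundant(
    reads: list[ReadRecord],
    labels: dict[str, "object"] | None = None,
    min_reads: int = 100,
) -> list[ReadRecord]:
    """Unassigned reads with total count >= min_reads ("at least" is inclusive).

    ``labels`` maps read id -> AnnotationLabel; reads already explained as
    known miRNA, star or contaminant are excluded. With no labels every read
    is treated as unassigned.
    """
    out = []
    for rec in reads:
        if labels is not None:
            lab = labels.get(rec.id)
            if lab is not None and lab.category != "unassigned":
                continue
        if rec.total_count >= min_reads:
            out.append(rec)
    return out


def build_similarity_graph(
    candidates: list[ReadRecord],
    min_identity: float = 0.90,
    min_coverage: float = 0.95,
    min_span: int = 16,
) -> SimilarityGraph:
    """Edge iff the optimal alignment meets identity, coverage and span floors."""
    if not candidates:
        raise ValueError("no candidate reads")
    graph = SimilarityGraph(nodes={r.id: r for r in candidates})
    ordered = sorted(candidates, key=lambda r: r.id)
    seqs = [r.sequence for r in ordered]
    pairs = (
        candidate_pairs(seqs)
        if min_identity >= 0.9
        else {(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))}
    )
    for i, j in pairs:
        a, b = ordered[i], ordered[j]
        if seqs[i] == seqs[j] or pair_passes(seqs[i], seqs[j], min_identity, min_coverage, min_span):
            graph.add_edge(a.id, b.id)
    return graph


def connected_components(graph: SimilarityGraph) -> list[set[str]]:
    """Standard components, sorted by descending size (ties: smallest member id)."""
    adj = graph.adjacency()
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in sorted(graph.nodes):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def partition_modularity(graph: SimilarityGraph, assignment: dict[str, int]) -> float:
    """Q = sum_i (e_ii - a_i^2) on the unweighted graph."""
    m = graph.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    if set(assignment) != set(graph.nodes):
        raise ValueError("assignment must cover exactly the graph nodes")
    intra: dict[int, int] = {}
    endpoints: dict[int, int] = {}
    for e in graph.edges:
        u, v = tuple(e)
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0) + 1
        endpoints[cu] = endpoints.get(cu, 0) + 1
        endpoints[cv] = endpoints.get(cv, 0) + 1
    return sum(
        intra.get(c, 0) / m - (endpoints.get(c, 0) / (2 * m)) ** 2
        for c in set(assignment.values())
    )


def _greedy_merge(
    graph: SimilarityGraph,
    nodes: set[str],
    m: int,
    next_cid: int,
) -> tuple[dict[str, int], int]:
    """CNM agglomeration on one component; ``m`` sets the dQ scale.

    Ties in dQ are broken by the smallest (cid, cid) pair, and a merged
    community keeps the smaller of the two ids, so the merge path is
    deterministic.
    """
    order = sorted(nodes)
    cid_of = {u: next_cid + i for i, u in enumerate(order)}
    next_cid += len(order)
    members: dict[int, set[str]] = {cid_of[u]: {u} for u in order}
    deg = graph.degrees()
    a: dict[int, float] = {cid_of[u]: deg[u] / (2 * m) for u in order}
    e: dict[int, dict[int, float]] = {cid: {} for cid in members}
    for edge in graph.edges:
        u, v = tuple(edge)
        if u not in nodes:
            continue
        cu, cv = cid_of[u], cid_of[v]
        if cu == cv:
            continue
        e[cu][cv] = e[cu].get(cv, 0.0) + 1.0 / m
        e[cv][cu] = e[cv].get(cu, 0.0) + 1.0 / m
    while len(members) > 1:
        best = None
        best_dq = 0.0
        for ci in sorted(e):
            for cj in sorted(e[ci]):
                if cj <= ci:
                    continue
                dq = 2.0 * (e[ci][cj] - a[ci] * a[cj])
                if dq > best_dq or (best is not None and dq == best_dq and (ci, cj) < best):
                    best_dq = dq
                    best = (ci, cj)
        if best is None or best_dq <= 0.0:
            break
        ci, cj = best  # merge cj into ci (ci < cj keeps the smaller id)
        members[ci] |= members.pop(cj)
        a[ci] += a.pop(cj)
        for ck, w in e.pop(cj).items():
            if ck == ci:
                continue
            e[ck].pop(cj, None)
            e[ci][ck] = e[ci].get(ck, 0.0) + w
            e[ck][ci] = e[ci][ck]
        e[ci].pop(cj, None)
    assignment = {u: cid for cid, us in members.items() for u in us}
    return assignment, next_cid


def fast_greedy_communities(graph: SimilarityGraph) -> CommunityPartition:
    """Greedy modularity communities, run per connected component.

    dQ uses the whole-graph edge count, and the reported Q is the global
    modularity of the combined assignment. Edgeless components become one
    community each (with a warning) and contribute 0 to Q.
    """
    m = graph.n_edges
    assignment: dict[str, int] = {}
    next_cid = 0
    for comp in connected_components(graph):
        if _component_edge_count(graph, comp) == 0:
            logger.warning("edgeless component of %d node(s) kept as one community", len(comp))
            for u in comp:
                assignment[u] = next_cid
            next_cid += 1
            continue
        sub_assignment, next_cid = _greedy_merge(graph, comp, m, next_cid)
        assignment.update(sub_assignment)
    q = partition_modularity(graph, assignment) if m > 0 else 0.0
    return CommunityPartition(assignment=assignment, Q=q)


def _component_edge_count(graph: SimilarityGraph, comp: set[str]) -> int:
    return sum(1 for e in graph.edges if e <= comp)


def define_candidate_clusters(
    graph: SimilarityGraph, q_threshold: float = 0.3
) -> CommunityPartition:
    """Candidate clusters: modules of the major component, whole components elsewhere.

    The largest component is split into its greedy-modularity communities.
    Every other component is one cluster, unless its own greedy partition
    (modularity computed on the subgraph) exceeds ``q_threshold``, in which
    case its communities are used instead.
    """
    comps = connected_components(graph)
    assignment: dict[str, int] = {}
    next_cid = 0
    for rank, comp in enumerate(comps):
        n_edges = _component_edge_count(graph, comp)
        if rank == 0 and n_edges > 0:
            sub_assignment, next_cid = _greedy_merge(graph, comp, graph.n_edges, next_cid)
            assignment.update(sub_assignment)
            continue
        if n_edges > 0 and len(comp) > 2:
            sub = _subgraph(graph, comp)
            local = fast_greedy_communities(sub)
            if len(set(local.assignment.values())) > 1 and local.Q > q_threshold:
                remap: dict[int, int] = {}
                for u in sorted(comp):
                    c = local.assignment[u]
                    if c not in remap:
                        remap[c] = next_cid
                        next_cid += 1
                    assignment[u] = remap[c]
                continue
        for u in comp:
            assignment[u] = next_cid
        next_cid += 1
    q = partition_modularity(graph, assignment) if graph.n_edges else 0.0
    return CommunityPartition(assignment=assignment, Q=q)


def _subgraph(graph: SimilarityGraph, nodes: set[str]) -> SimilarityGraph:
    sub = SimilarityGraph(nodes={u: graph.nodes[u] for u in nodes})
    sub.edges = {e for e in graph.edges if e <= nodes}
    return sub


def select_representatives(
    graph: SimilarityGraph, partition: CommunityPartition
) -> CandidateTable:
    """One row per community: its most abundant member (ties: smallest sequence)."""
    groups: dict[int, list[ReadRecord]] = {}
    for node, cid in partition.assignment.items():
        groups.setdefault(cid, []).append(graph.nodes[node])
    libraries: list[str] = sorted({lib for r in graph.nodes.values() for lib in r.counts})
    rows = []
    for cid in sorted(groups):
        recs = groups[cid]
        rep = min(recs, key=lambda r: (-r.total_count, r.sequence))
        counts: dict[str, int] = {}
        for r in recs:
            for lib, n in r.counts.items():
                counts[lib] = counts.get(lib, 0) + n
        rows.append(
            CandidateRow(
                candidate_id=rep.id,
                sequence=rep.sequence,
                counts=counts,
                status="unassigned",
                cluster_id=f"community_{cid}",
            )
        )
    return CandidateTable(rows=rows, libraries=libraries)


@dataclass
class CandidateRecord:
    candidate_id: str
    sequence: str
    counts: dict[str, int]
    conservation: str  # conserved | specific
    species_tags: list[str]


def classify_conservation(
    candidates: CandidateTable,
    species_sets: dict[str, "object"],
    min_identity: float = 1.00,
    min_coverage: float = 0.95,
) -> list[CandidateRecord]:
    """Conserved iff the candidate occurs in >= 1 other-species small-RNA set.

    A hit requires 100% identity over >= 95% of the candidate (exact
    windowed occurrence); anything less keeps the candidate specific.
    """
    from .annotate import _exact_windowed_hit

    texts = {
        name: "#".join(s for _, s in rs.sequences)
        for name, rs in species_sets.items()
        if len(rs.sequences)
    }
    out = []
    for row in candidates.sorted_rows():
        tags = []
        for name, text in texts.items():
            if min_identity >= 1.0:
                if _exact_windowed_hit(row.sequence, text, min_coverage) is not None:
                    tags.append(name)
            else:
                for _, ref_seq in species_sets[name].sequences:
                    if pair_passes(row.sequence, ref_seq, min_identity, min_coverage):
                        tags.append(name)
                        break
        out.append(
            CandidateRecord(
                candidate_id=row.candidate_id,
                sequence=row.sequence,
                counts=row.counts,
                conservation="conserved" if tags else "specific",
                species_tags=sorted(tags),
            )
        )
    return out
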