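"""Pairwise sequence similarity and identity/coverage clustering.

Reads from one miRNA locus differ mostly at their ends (imprecise Drosha/
Dicer processing, untemplated 3' tailing), so length variants of one
mature sequence are gathered by single-linkage clustering of all pairs
meeting 90% identity and 80% coverage, and each cluster is represented by
its predominant read.

Identity and coverage are computed from the optimal local alignment under
a fixed scoring scheme (match +1, mismatch -1, gap -2):

* identity = matching columns / aligned columns (gap columns included);
* coverage = fraction of the SHORTER sequence spanned by the alignment.

The heuristic seeded search of database tools is replaced by exact
Smith-Waterman optima; an exact k-mer prescreen keeps all-pairs clustering
fast: any pair reaching identity >= 0.9 over >= 16 aligned columns has at
most floor(0.1*C) non-match columns among C <= ~45, which forces a shared
exact 6-mer (pigeonhole), so pairs sharing no 6-mer are skipped without
loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .records import ReadRecord

PRESCREEN_K = 6


@dataclass(frozen=True)
class PairAlignment:
    """Identity/coverage summary of the optimal local alignment of two sequences."""

    identity: float
    coverage: float
    aligned_span_a: tuple[int, int]
    aligned_span_b: tuple[int, int]
    score: float
    columns: int

    @property
    def span_length(self) -> int:
        return self.columns


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=200_000)
def _align_canonical(a: str, b: str) -> PairAlignment:
    # inputs are pre-sorted so results are symmetric by construction
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return PairAlignment(0.0, 0.0, (0, 0), (0, 0), float(score), 0)
    aln = next(iter(_ALIGNER.align(a, b)))
    coords = aln.coordinates  # 2 x k path vertices of the alignment
    matches = 0
    columns = 0
    k = coords.shape[1]
    for s in range(k - 1):
        a0, a1 = int(coords[0, s]), int(coords[0, s + 1])
        b0, b1 = int(coords[1, s]), int(coords[1, s + 1])
        da, db = a1 - a0, b1 - b0
        if da and db:  # aligned block (no gaps inside)
            columns += da
            matches += sum(
                1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y and x != "N"
            )
        else:  # gap columns
            columns += da + db
    span_a = (int(coords[0, 0]), int(coords[0, -1]))
    span_b = (int(coords[1, 0]), int(coords[1, -1]))
    shorter = min(len(a), len(b))
    covered = min(span_a[1] - span_a[0], span_b[1] - span_b[0])
    return PairAlignment(
        identity=matches / columns,
        coverage=covered / shorter,
        aligned_span_a=span_a,
        aligned_span_b=span_b,
        score=float(score),
        columns=columns,
    )


def align_pair(a: str, b: str) -> PairAlignment:
    """Optimal local alignment of two sequences; symmetric in identity/coverage."""
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    if a <= b:
        return _align_canonical(a, b)
    pa = _align_canonical(b, a)
    return PairAlignment(
        identity=pa.identity,
        coverage=pa.coverage,
        aligned_span_a=pa.aligned_span_b,
        aligned_span_b=pa.aligned_span_a,
        score=pa.score,
        columns=pa.columns,
    )


def pair_passes(
    a: str,
    b: str,
    min_identity: float,
    min_coverage: float,
    min_span: int = 0,
) -> bool:
    """True iff the optimal alignment of a,b meets all three thresholds.

    A cheap exact pre-rejection uses the optimal score alone: a passing
    alignment over C columns has >= min_identity*C matches and <=
    (1-min_identity)*C error columns, so its score is at least
    C*(3*min_identity - 2) with C >= max(min_span, min_coverage*len_short);
    anything scoring below that bound cannot pass.
    """
    factor = 3.0 * min_identity - 2.0
    if factor > 0:
        shorter = min(len(a), len(b))
        bound = factor * max(min_span, min_coverage * shorter)
        key = (a, b) if a <= b else (b, a)
        if _ALIGNER.score(*key) < bound - 1e-9:
            return False
    pa = align_pair(a, b)
    return (
        pa.identity >= min_identity
        and pa.coverage >= min_coverage
        and pa.columns >= min_span
    )


def candidate_pairs(sequences: list[str], k: int = PRESCREEN_K) -> set[tuple[int, int]]:
    """Index pairs of sequences sharing at least one exact k-mer."""
    buckets: dict[str, list[int]] = {}
    for idx, seq in enumerate(sequences):
        seen = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer not in seen:
                seen.add(kmer)
                buckets.setdefault(kmer, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i, x in enumerate(members):
            for y in members[i + 1 :]:
                pairs.add((x, y))
    return pairs


@dataclass
class SequenceCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str
    representative_sequence: str
    counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def cluster_reads(
    reads: list[ReadRecord],
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
) -> list[SequenceCluster]:
    """Single-linkage clustering of reads at identity/coverage thresholds.

    Transitive closure over all pairs meeting both thresholds; every read
    lands in exactly one cluster. The representative is the member with the
    highest total count (ties: lexicographically smallest sequence). The
    result is invariant to the input order.
    """
    ordered = sorted(reads, key=lambda r: (r.sequence, r.id))
    seqs = [r.sequence for r in ordered]
    uf = UnionFind(len(ordered))
    # the 6-mer prescreen is only exact at identity >= 0.9
    pairs = (
        candidate_pairs(seqs)
        if min_identity >= 0.9
        else {(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))}
    )
    for i, j in pairs:
        if uf.find(i) == uf.find(j):
            continue
        if seqs[i] == seqs[j] or pair_passes(seqs[i], seqs[j], min_identity, min_coverage):
            uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for idx in range(len(ordered)):
        groups.setdefault(uf.find(idx), []).append(idx)
    clusters: list[SequenceCluster] = []
    for members in groups.values():
        recs = [ordered[i] for i in members]
        rep = max(recs, key=lambda r: (r.total_count, _neg_seq(r.sequence)))
        counts: dict[str, int] = {}
        for r in recs:
            for lib, n in r.counts.items():
                counts[lib] = counts.get(lib, 0) + n
        clusters.append(
            SequenceCluster(
                cluster_id="",
                member_ids=sorted(r.id for r in recs),
                representative_id=rep.id,
                representative_sequence=rep.sequence,
                counts=counts,
            )
        )
    clusters.sort(key=lambda c: (-c.total_count, c.representative_sequence))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"cl{i}"
    return clusters


class _neg_seq(str):
    """Inverts lexicographic order so max() picks the smallest sequence on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def clusters_to_reads(clusters: list[SequenceCluster]) -> list[ReadRecord]:
    """One ReadRecord per cluster: representative sequence, summed counts."""
    return [
        ReadRecord(
            id=c.representative_id, sequence=c.representative_sequence, counts=dict(c.counts)
        )
        for c in clusters
    ]
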