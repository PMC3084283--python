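"""End-to-end orchestration of the discovery pipeline.

Stage order mirrors the genome-free analysis: collapse and filter each
library independently; cluster end-variants (90% identity / 80% coverage)
and keep the predominant read of each cluster; annotate representatives
(contaminants, then known families by PSSM, then miRNA* against masked
hairpins); define novel candidates from the unassigned abundant sequences
via the 90/95 similarity network and its modular communities; classify
candidates as conserved or specific against other-species sets; and, when
contigs are available, call miRNA:miRNA* duplexes on folded precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import AnnotationLabel, annotate_reads, build_pssm, mask_hairpin_set
from .network import (
    CandidateRecord,
    CommunityPartition,
    SimilarityGraph,
    build_similarity_graph,
    classify_conservation,
    define_candidate_clusters,
    select_abundant,
    select_representatives,
)
from .precursor import Contig, ContigHit, DuplexCall, find_duplexes, map_candidates_to_contigs
from .preprocess import FilterParams, FilterReport, collapse_identical, filter_reads, flag_low_complexity_tail
from .records import CandidateRow, CandidateTable, ReadRecord, ReferenceSet
from .similarity import SequenceCluster, cluster_reads, clusters_to_reads


@dataclass
class PipelineParams:
    filter: FilterParams = field(default_factory=FilterParams)
    cluster_identity: float = 0.90
    cluster_coverage: float = 0.80
    scan_identity: float = 0.90
    candidate_min_reads: int = 100
    graph_identity: float = 0.90
    graph_coverage: float = 0.95
    graph_min_span: int = 16
    q_threshold: float = 0.3
    conservation_identity: float = 1.00
    conservation_coverage: float = 0.95
    artefact_length: int = 36


@dataclass
class PipelineResult:
    filter_reports: dict[str, FilterReport]
    clusters: list[SequenceCluster]
    representatives: list[ReadRecord]
    labels: dict[str, AnnotationLabel]
    candidates: list[ReadRecord]
    graph: SimilarityGraph | None
    partition: CommunityPartition | None
    candidate_records: list[CandidateRecord]
    table: CandidateTable
    hits: list[ContigHit]
    duplexes: dict[str, DuplexCall]
    libraries: list[str]


def run_pipeline(
    libraries: dict[str, list[ReadRecord]],
    family_alignments: dict[str, list[str]],
    reference_sets: dict[str, ReferenceSet],
    contigs: list[Contig] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    kept_all: list[ReadRecord] = []
    reports: dict[str, FilterReport] = {}
    for label, reads in libraries.items():
        collapsed = collapse_identical(reads)
        kept, report = filter_reads(collapsed, params.filter, library=label)
        reports[label] = report
        kept_all.extend(kept)
    combined = collapse_identical(kept_all)

    clusters = cluster_reads(combined, params.cluster_identity, params.cluster_coverage)
    reps = clusters_to_reads(clusters)

    profiles = [build_pssm(fam, seqs) for fam, seqs in sorted(family_alignments.items())]
    masked = (
        mask_hairpin_set(reference_sets["hairpin"])
        if "hairpin" in reference_sets and reference_sets["hairpin"].mature_coords
        else []
    )
    labels = annotate_reads(reps, profiles, masked, reference_sets, params.scan_identity)

    # Novel candidates are defined on the abundant unassigned unique reads
    # (not on cluster representatives): the 90/95 network then resolves the
    # remaining end-variant redundancy through its components and modules.
    rep_label_of_cluster = {c.cluster_id: labels[c.representative_id] for c in clusters}
    cluster_of_read: dict[str, SequenceCluster] = {}
    read_labels: dict[str, AnnotationLabel] = {}
    for c in clusters:
        for mid in c.member_ids:
            cluster_of_read[mid] = c
            lab = rep_label_of_cluster[c.cluster_id]
            read_labels[mid] = AnnotationLabel(mid, lab.category, lab.identity, lab.coverage)
    candidates = select_abundant(combined, read_labels, params.candidate_min_reads)
    graph = None
    partition = None
    records: list[CandidateRecord] = []
    if candidates:
        graph = build_similarity_graph(
            candidates, params.graph_identity, params.graph_coverage, params.graph_min_span
        )
        partition = define_candidate_clusters(graph, params.q_threshold)
        communities = select_representatives(graph, partition)
        species_sets = {
            name: rs for name, rs in reference_sets.items() if name.startswith("species:")
        }
        records = classify_conservation(
            communities, species_sets,
            params.conservation_identity, params.conservation_coverage,
        )

    table = _final_table(
        reps, labels, records, partition, graph, cluster_of_read, sorted(libraries), params
    )

    hits: list[ContigHit] = []
    duplexes: dict[str, DuplexCall] = {}
    if contigs and records:
        cand_seqs = [(r.candidate_id, r.sequence) for r in records]
        hits = map_candidates_to_contigs(cand_seqs, contigs)
        duplexes = find_duplexes(contigs, hits)

    return PipelineResult(
        filter_reports=reports,
        clusters=clusters,
        representatives=reps,
        labels=labels,
        candidates=candidates,
        graph=graph,
        partition=partition,
        candidate_records=records,
        table=table,
        hits=hits,
        duplexes=duplexes,
        libraries=sorted(libraries),
    )


def _final_table(
    reps: list[ReadRecord],
    labels: dict[str, AnnotationLabel],
    records: list[CandidateRecord],
    partition: CommunityPartition | None,
    graph: SimilarityGraph | None,
    cluster_of_read: dict[str, "SequenceCluster"],
    libraries: list[str],
    params: PipelineParams,
) -> CandidateTable:
    """One row per candidate community plus one per remaining cluster.

    Community rows carry the summed counts of their member reads; cluster
    rows whose reads were absorbed into communities keep only the residual
    (sub-threshold variant) counts, so total reads are conserved.
    """
    rows = []
    if partition is not None and graph is not None:
        for rec in records:
            rows.append(
                CandidateRow(
                    candidate_id=rec.candidate_id,
                    sequence=rec.sequence,
                    counts=dict(rec.counts),
                    status=f"{rec.conservation}_candidate",
                    cluster_id=f"community_{partition.assignment[rec.candidate_id]}",
                )
            )
    absorbed_counts: dict[str, dict[str, int]] = {}
    if graph is not None:
        for node_id, rec in graph.nodes.items():
            cl = cluster_of_read.get(node_id)
            if cl is None:
                continue
            acc = absorbed_counts.setdefault(cl.cluster_id, {})
            for lib, n in rec.counts.items():
                acc[lib] = acc.get(lib, 0) + n
    artefact_flags = flag_low_complexity_tail(
        [r for r in reps if len(r.sequence) == params.artefact_length]
    )
    cluster_id_of_rep = {
        cl.representative_id: cl.cluster_id for cl in cluster_of_read.values()
    }
    for rep in reps:
        label = labels[rep.id]
        base = label.base_category
        if base in ("known", "star"):
            status = label.category
        elif base == "unassigned":
            status = "artefact" if artefact_flags.get(rep.id) else "unassigned"
        else:
            status = f"contaminant:{label.category}"
        counts = dict(rep.counts)
        removed = absorbed_counts.get(cluster_id_of_rep.get(rep.id, ""), {})
        for lib, n in removed.items():
            counts[lib] = counts.get(lib, 0) - n
        if not any(v > 0 for v in counts.values()):
            continue
        counts = {lib: max(0, n) for lib, n in counts.items()}
        rows.append(
            CandidateRow(
                candidate_id=rep.id,
                sequence=rep.sequence,
                counts=counts,
                status=status,
                cluster_id="-",
            )
        )
    return CandidateTable(rows=rows, libraries=libraries)


# ---------------------------------------------------------------------------
# scoring against a synthetic truth manifest

def score_against_truth(dataset, result: PipelineResult) -> dict[str, float]:
    """Recovery metrics of a pipeline run on a synthetic dataset.

    * candidate_recovery: fraction of planted novel hairpins whose mature
      sequence is matched by a candidate representative at >= 90% identity
      and >= 80% coverage;
    * duplex_recovery: fraction of planted novel hairpins whose contig got a
      duplex verdict;
    * untraceable_fraction: candidate representatives whose sequence cannot
      be traced to any emitted read in the truth manifest.
    """
    from .similarity import pair_passes

    novel = dataset.planted_novel()
    cand_seqs = [r.sequence for r in result.candidate_records]
    recovered = 0
    for hp in novel:
        if any(
            s == hp.mature_seq or pair_passes(s, hp.mature_seq, 0.9, 0.8)
            for s in cand_seqs
        ):
            recovered += 1
    contig_of = {c.source_tags[0]: c.id for c in dataset.contigs if c.source_tags}
    duplexed = sum(
        1
        for hp in novel
        if contig_of.get(hp.id) in result.duplexes
        and result.duplexes[contig_of[hp.id]].verdict == "duplex"
    )
    manifest_seqs = set(dataset.manifest["sequence"])
    untraceable = sum(1 for s in cand_seqs if s not in manifest_seqs)
    n_novel = len(novel) or 1
    return {
        "candidate_recovery": recovered / n_novel,
        "duplex_recovery": duplexed / n_novel,
        "untraceable_fraction": untraceable / (len(cand_seqs) or 1),
        "n_candidates": float(len(cand_seqs)),
        "n_planted_novel": float(len(novel)),
    }
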