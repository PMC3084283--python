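# Methods

This note records the models behind `srnapipe`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Reads, counts and coordinates

The unit of analysis is the unique sequence with per-library read
counts (`ReadRecord`). Sequences are stored in the DNA alphabet (U→T on
input; writers can re-emit RNA), and all coordinates are 0-based
half-open internally. Collapsed FASTA counts are accepted in both common
header dialects (`id-N` and `id_xN`, the latter winning when both
parse); FASTQ records count one read each.

## Filtering

Three read filters, applied per library (libraries are filtered
independently):

| parameter | default | meaning |
|---|---|---|
| `min_length` | 19 nt | shorter reads are adapter/degradation debris |
| `max_ambiguous` | 0 | any N disqualifies a read |
| `min_count` | 6 reads | "more than 5 reads": singletons and near-singletons are dominated by sequencing noise |

The "more than 5" rule is read strictly (keep iff count ≥ 6); the
threshold is a parameter so the inclusive convention is one keyword away.
The 36-nt artefact class is recognised by its 3′-terminal 10-nt window
containing ≥50% U (inclusive comparison; tails at exactly the threshold
are flagged). Reads shorter than the window are scored on their full
length and counted in the report.

## Pairwise similarity

Identity and coverage derive from the optimal Smith–Waterman local
alignment under a fixed scheme: match +1, mismatch −1, gap −2 (linear).
Identity = matching columns / aligned columns (gap columns included);
coverage = fraction of the *shorter* sequence spanned — the right
convention when the variants being clustered are length variants of one
mature sequence. The heuristic seeded search of database tools is
replaced by exact alignment; where a database search would use an
e-value cut-off, a minimum aligned span of 16 columns is required
instead, since e-values depend on database size and are not reproducible
outside the original search engine. Alignments are computed by
`Bio.Align.PairwiseAligner`; when co-optimal alignments exist the first
(deterministic) traceback is used, and inputs are canonically ordered so
the reported identity and coverage are exactly symmetric.

Two exact shortcuts keep all-pairs clustering fast without changing any
decision:

* **6-mer prescreen** — a pair passing ≥90% identity over C ≥ 16 aligned
  columns has at most ⌊0.1·C⌋ non-match columns, which forces an exact
  match run of ≥ ⌈(C−e)/(e+1)⌉ ≥ 6 for all C ≤ ~45 (worst case C = 20,
  e = 2). Pairs sharing no exact 6-mer are skipped. The prescreen is
  bypassed automatically if a caller lowers the identity threshold below
  0.9.
* **Score bound** — a passing alignment scores at least
  C·(3·identity − 2); anything scoring below
  0.7·max(min_span, min_coverage·len_short) cannot pass and is rejected
  from the score alone.

Both are verified against brute-force all-pairs in the test suite.

## Clustering and representatives

End-variant clustering is single-linkage (transitive closure) over pairs
at ≥90% identity / ≥80% coverage. The representative of a cluster, and
later of a network community, is the member with the highest total read
count, with the lexicographically smallest sequence breaking ties — a
deterministic stand-in for "the predominant read".

## Known-miRNA annotation

Per-family PSSMs are built from aligned family sequences: column score
log₂(((n_b + 0.25)/(n + 1))/0.25) against a uniform background, with the
consensus taking each column's most frequent base (ties alphabetic).
Reads are slid along the consensus at offsets −3…+3 to absorb the
documented 5′/3′ end heterogeneity; identity is computed over the
overlap positions at each offset (the open convention "identity over
read or profile length" is resolved this way, and the compared-positions
rule is what the tests pin down). A read is assigned to the family with
the best identity, ties broken by PSSM score and then family name, if
identity ≥ 0.90.

miRNA★ detection aligns reads to hairpin references whose mature
interval is replaced by N. N matches nothing, so aligned mask columns
count as mismatches; the star-scan identity is measured over the full
read length (matches / read length) with a span floor of 16, which makes
a read straddling the mask fail and a read inside the mask score zero.

Contaminant labelling (rRNA > tRNA > snRNA > piRNA/transposon >
endosymbiont, first match wins) requires 100% identity over ≥95% of the
read, implemented as exact occurrence of a ≥⌈0.95·L⌉-nt read window in a
reference sequence. Structural RNA is labelled before miRNA calling, so
the contaminant categories take precedence over profile hits.

## Candidate network

Novel candidates are defined on the *unassigned unique reads* with ≥100
total reads (inclusive threshold), not on cluster representatives: the
point of the network stage is to resolve exactly the redundancy that
survives annotation, and its nodes must therefore be the abundant
sequences themselves. Edges require ≥90% identity, ≥95% coverage and
span ≥16; the graph is unweighted.

Communities come from fast-greedy agglomeration: starting from
singletons, repeatedly merge the connected pair of communities with the
largest ΔQ = 2(e_ij − a_i·a_j), stopping when no merge has positive
gain. Ties in ΔQ are broken by the smallest (community-id, community-id)
pair and a merged community keeps the smaller id, so the merge path is
deterministic. Merging runs per connected component with ΔQ on the
whole-graph edge count, and the reported Q is the global modularity of
the combined assignment. Components other than the largest are kept as
single clusters unless their own greedy partition (modularity computed
on the subgraph) exceeds a configurable Q threshold (default 0.3) — the
largest component gets the full modular treatment, echoing how a major
variant cloud needs splitting while small satellite components are
already clean clusters.

The greedy optimiser is validated against exhaustive Bell-number search
over all partitions on every bridged two-clique graph with ≤10 nodes,
and against an independent graph library's implementation; the
modularity formula against hand-computed values (two disjoint triangles
→ 0.5; all-in-one → 0; triangle singletons → −1/3).

Conservation calls use the same exact-window rule as contaminants (100%
identity, ≥95% coverage) against other-species small-RNA sets; one hit
in any set makes a candidate *conserved*, otherwise it is *specific*.

## Precursor folding and duplex calling

Thermodynamic folding is deliberately replaced by nested base-pair
maximisation (Nussinov dynamic programme): Watson–Crick plus G·U wobble
pairs, minimum loop 3, deterministic traceback preferring to pair
position i with the smallest admissible partner. This keeps the
precursor screen dependency-free and bit-reproducible while preserving
the decision structure (fold, locate arms, test the duplex); the pair
count is validated against exhaustive enumeration of nested pairings.
Note that base-pair maximisation is degenerate: co-optimal structures
can recruit loop bases, so even a perfect inverted repeat is only
guaranteed its full stem *count*, not one canonical pair set — all
downstream thresholds are therefore stated on pairedness fractions, not
exact structures.

Arms are located by taking the largest hairpin loop (the largest
unpaired interval directly closed by a pair) and walking the enclosing
stem outward until a branch point. A contig is screened in (two distinct
candidates, strictly non-overlapping intervals — "different regions" is
not quantified in the source workflow, so strict non-overlap is the
documented choice), its hit-spanning window ±15 nt is folded (windows
are clipped to 40–200 nt), and a duplex verdict requires one hit ≥80%
inside the 5′ arm, a distinct hit ≥80% inside the 3′ arm, and ≥60% of
each hit's positions paired into the other hit's interval. The 0.8/0.6
fractions are documented knobs with no counterpart in the original
description.

Candidate-to-contig mapping is exact full-length matching on both
strands by default (the contigs are assembled from the same reads); an
identity ≥0.95 alignment mode exists for noisy contigs.

## Statistics

* **Shannon diversity** H′ = −Σ pᵢ ln pᵢ over read proportions (natural
  log, the classical convention; the base is a parameter in the sense
  that callers can rescale).
* **Reads vs qPCR**: Pearson R with two-sided significance from
  t = R·√((n−2)/(1−R²)), n−2 df, after restricting to sequences with
  more than 100 reads (strict: ≥101). The candidate-definition filter
  "at least 100" stays inclusive; both are parameters.
* **Knockdown validation**: the efficiency-corrected ratio
  E_t^(mean Ct_t,ctrl − mean Ct_t,trt) / E_r^(mean Ct_r,ctrl − mean Ct_r,trt)
  with E = 2 by default (perfect doubling; configurable per gene). The
  p-value is a two-sided randomization test on |log ratio|: a sample is
  one paired (target, reference) Ct observation, and group labels of
  whole samples are permuted — the pairing within a sample is never
  broken, and replicate values are never re-matched across samples. All
  C(n, n_ctrl) reallocations are enumerated when that count is below the
  randomization budget (default 10 000), otherwise that many are sampled
  with the caller's seed and the observed labelling is counted in.

A discreteness fact worth knowing: with 3 replicates per group the
exhaustive two-sided p can never fall below 2/C(6,3) = 0.1, because the
label-swapped mirror of the observed allocation always ties it. A 5%
test therefore has zero rejection probability at n = 3. The type-I-error
calibration in the tests and the acceptance script consequently runs at
5 replicates per group (C(10,5) = 252 reallocations, attainable p ≤
0.05), where the measured null rejection rate at α = 0.05 lands near
0.05 as it should. Knockdown calls on 3-replicate data are still
reported with their exact p (0.1 at best) — that is a property of the
design, not of the implementation.

* **Library comparison**: per-library read fractions over the classes
  {known miRNA, miRNA★, conserved candidate, specific candidate, other
  small RNAs, unassigned}, where "other small RNAs" pools the
  structural/foreign categories; flagged 36-nt artefacts are reported
  under "unassigned" since they are neither annotated nor candidate
  material. Within-class Shannon H′ is reported for known miRNAs and
  both candidate classes.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
helper. Per planted hairpin: a 21–23-nt mature arm (lengths weighted
0.2/0.6/0.2, matching the observation that most candidates are 22-mers),
a perfect reverse-complement star arm, an 8–15-nt loop, 4–10-nt pads,
and a total length of 60–100 nt. A draw is accepted only if the
package's own folder recovers both arms at pairedness ≥0.8 **and** the
planted mature/star intervals pass the duplex test — the generator
certifies that every planted precursor is recoverable in principle, so a
recovery failure downstream indicts the pipeline, not the fixture.

Locus expression follows a discrete power law with exponent 1.5
truncated to [500, 50 000] reads. The lower bound encodes that planted
loci represent the *abundant* expressed fraction an ≥100-read candidate
rule targets (a law reaching down to 1 read would place ~90% of planted
loci below any such threshold and make recovery meaningless); the upper
bound keeps any single locus from dominating the read-weighted length
mixture (which would make the 21–23-nt calibration swing with the seed)
and keeps desk-scale runs in seconds. The extreme skew of real libraries
is retained in the artefact and contaminant count law, which does run
on [1, 1000] with ~99% singletons among 36-nt artefacts.

Star:mature expression ratios are uniform on [0.25, 0.9] — star reads at
a substantial fraction of mature reads, consistent with star sequences
being observed at comparable (sometimes higher) read numbers than their
mature partners.

End heterogeneity: 5′ and 3′ ends shift independently by
{−2…+2} nt with probabilities {0.02, 0.09, 0.78, 0.09, 0.02}; an
untemplated 3′ base is added with probability 0.20, drawn U 0.6 / A 0.3 /
G 0.05 / C 0.05 (U then A favoured, as observed). These values, together
with the two library presets below, were calibrated once so the
21–23-nt read fraction of the presets lands at the empirically reported
72% (whole-body) and 63% (ovary), then frozen.

Library presets (multiplier on known-family loci, multiplier on novel
loci, artefact read fraction, contaminant read fraction):

| preset | known | novel | artefact | contaminant |
|---|---|---|---|---|
| `whole_body` | 2.0 | 0.085 | 0.13 | 0.005 |
| `ovary` | 0.085 | 2.0 | 0.22 | 0.005 |

The ~24-fold known/novel contrast reproduces the observed composition
flip between a whole-body and an ovary library; the artefact fractions
are the reported 13%/22%; per-library lognormal jitter (σ = 0.3) keeps
the two libraries from being exact rescalings of each other.

Contigs embed each novel precursor in 20–60-nt random flanks and are
certified callable at generation (flanks are redrawn if they break the
duplex call); decoy contigs are dinucleotide-preserving shuffles
(Eulerian-walk construction) screened to contain no planted mature
sequence on either strand. Simulated qPCR sets
Ct = baseline − log_E(abundance) + N(0, σ) with σ = 0.15 cycles and
E = 2, a U6-like reference at fixed abundance, and per-gene treated-group
effects (e.g. 0.5 for a dicer-1-style 2-fold mature-miRNA knockdown).

### What the benchmark does not show

The generator works at the unique-sequence level (counts are assigned to
variant sequences directly); it has no per-base sequencing-error model,
no adapter remnants, no assembly errors in contigs, and its references
are synthetic rather than curated databases. Perfect recovery on these
libraries therefore demonstrates the correctness of the pipeline's
decision logic under the stated noise structure — end heterogeneity,
tailing, artefacts, contamination, composition skew — not performance on
instrument-level noise or on the taxonomic breadth of real reference
sets. Real-data headline counts additionally depend on the reference
snapshot used, which a synthetic benchmark cannot emulate.

## Problem sizes

Default study conditions: 20 known-family, 15 novel-conserved and 25
novel-specific hairpins; two libraries of roughly 0.3–1.2 million reads
(tens to hundreds of thousands of unique sequences); ~60 contigs. The
full pipeline runs in well under a minute on one CPU at these sizes, and
the acceptance script (including the 2000-trial null calibration of the
randomization test) in about half a minute.

## Known limitations

* Base-pair maximisation has no notion of stability: a thermodynamically
  marginal hairpin with many weak pairs folds as readily as a stable
  one. An external folder's dot-bracket can be substituted where that
  distinction matters.
* Single-linkage clustering can chain distinct loci through intermediate
  variants if their matures are unusually similar; the modularity stage
  downstream is the corrective for exactly this situation.
* The exact-occurrence implementation of "100% identity / 95% coverage"
  does not allow indels inside the matched window; a gapped match at
  100% identity over 95% of the read is counted only through the
  alignment fallback used at sub-1.0 identity thresholds.
* With 3 qPCR replicates per group the randomization p-value is bounded
  below by 0.1 (see above); significance claims at α = 0.05 need ≥4
  replicates per group.
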