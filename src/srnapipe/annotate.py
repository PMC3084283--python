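"""Known-miRNA annotation, miRNA* detection and contaminant labelling.

Known mature miRNAs are recognised by per-family position-specific scoring
matrices (PSSMs) built from family alignments: a read is assigned to the
family whose consensus it matches at >= 90% identity, scanned over small
offsets to absorb 5'/3' end heterogeneity, with the PSSM log-odds score as
tie-breaker.

miRNA* (star) sequences come from the precursor arm opposite the mature
miRNA, so they are found by aligning reads against hairpin references whose
mature region has been masked with N (N matches nothing): whatever still
aligns well must sit on the star arm or loop.

Structural and foreign RNA (rRNA, tRNA, snRNA, piRNA/transposon fragments,
endosymbiont genome fragments) is labelled first, by near-exact matching,
and excluded from miRNA calling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .records import ReadRecord, ReferenceSet
from .similarity import align_pair

logger = logging.getLogger(__name__)

BASES = "ACGT"
PSEUDOCOUNT = 0.25

#: contaminant sets in precedence order (first match wins)
CONTAMINANT_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "piRNA_transposon", "endosymbiont")


@dataclass(frozen=True)
class AnnotationLabel:
    read_id: str
    category: str  # known:<family> | star:<family> | <contaminant set> | unassigned
    identity: float = 0.0
    coverage: float = 0.0

    @property
    def base_category(self) -> str:
        return self.category.split(":", 1)[0]


@dataclass
class PSSMProfile:
    """Log-odds matrix over {A,C,G,T} for one miRNA family alignment."""

    family: str
    matrix: list[dict[str, float]]
    consensus: str
    source_count: int

    def __len__(self) -> int:
        return len(self.matrix)

    def score(self, seq: str, offset: int = 0) -> float:
        """Sum of column scores for seq laid on the matrix at ``offset``."""
        total = 0.0
        for i, base in enumerate(seq):
            col = i + offset
            if 0 <= col < len(self.matrix) and base in self.matrix[col]:
                total += self.matrix[col][base]
        return total


def build_pssm(family: str, family_sequences: list[str]) -> PSSMProfile:
    """Build a PSSM from an aligned family ('-' gaps allowed, must be equal length).

    Column scores are log2 odds against a uniform background with a
    pseudocount of 0.25 per base:
    score(b) = log2(((n_b + 0.25) / (n + 1)) / 0.25). The consensus takes the
    most frequent base per column (ties: alphabetic).
    """
    if not family_sequences:
        raise ValueError(f"empty family {family!r}")
    seqs = [s.upper().replace("U", "T") for s in family_sequences]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError(f"ragged alignment for family {family!r}")
    matrix: list[dict[str, float]] = []
    consensus = []
    for col in range(width):
        counts = {b: 0 for b in BASES}
        for s in seqs:
            if s[col] in counts:
                counts[s[col]] += 1
        total = sum(counts.values())
        denom = total + 4 * PSEUDOCOUNT
        matrix.append(
            {b: math.log2(((counts[b] + PSEUDOCOUNT) / denom) / 0.25) for b in BASES}
        )
        consensus.append(max(BASES, key=lambda b: (counts[b], -ord(b))))
    return PSSMProfile(
        family=family, matrix=matrix, consensus="".join(consensus),
        source_count=len(seqs),
    )


def _best_offset_match(read: str, profile: PSSMProfile, max_offset: int) -> tuple[float, float]:
    """Best (identity, pssm score) of the read slid over the consensus.

    Identity is computed over the overlap (compared positions) at each
    offset in [-max_offset, +max_offset].
    """
    cons = profile.consensus
    best = (-1.0, -math.inf)
    for off in range(-max_offset, max_offset + 1):
        lo = max(0, -off)
        hi = min(len(read), len(cons) - off)
        compared = hi - lo
        if compared <= 0:
            continue
        matches = sum(1 for i in range(lo, hi) if read[i] == cons[i + off])
        ident = matches / compared
        score = profile.score(read, offset=off)
        if (ident, score) > best:
            best = (ident, score)
    return best


def scan_profiles(
    reads: list[ReadRecord],
    profiles: list[PSSMProfile],
    min_identity: float = 0.90,
    max_offset: int = 3,
) -> list[AnnotationLabel]:
    """Assign each read to its best-matching known family, if good enough.

    Best family by overlap identity to the consensus; ties broken by PSSM
    score, then family name. Reads below ``min_identity`` stay unassigned.
    """
    labels = []
    for rec in reads:
        best_family = None
        best_key = (-1.0, -math.inf, "")
        for prof in profiles:
            ident, score = _best_offset_match(rec.sequence, prof, max_offset)
            key = (ident, score, prof.family)
            if key > best_key:
                best_key = key
                best_family = prof.family
        if best_family is not None and best_key[0] >= min_identity:
            labels.append(
                AnnotationLabel(rec.id, f"known:{best_family}", identity=best_key[0], coverage=1.0)
            )
        else:
            labels.append(AnnotationLabel(rec.id, "unassigned"))
    return labels


@dataclass
class MaskedHairpin:
    hairpin_id: str
    sequence: str
    mature_interval: tuple[int, int]


def mask_mature(hairpin_id: str, sequence: str, mature: tuple[int, int]) -> MaskedHairpin:
    """Replace the mature interval of a hairpin with N (length preserved)."""
    start, end = mature
    if not (0 <= start < end <= len(sequence)):
        raise ValueError(f"mature interval {mature} outside hairpin {hairpin_id!r}")
    if end - start == len(sequence):
        logger.warning("hairpin %s fully masked by its mature interval", hairpin_id)
    masked = sequence[:start] + "N" * (end - start) + sequence[end:]
    return MaskedHairpin(hairpin_id=hairpin_id, sequence=masked, mature_interval=(start, end))


def mask_hairpin_set(hairpins: ReferenceSet) -> list[MaskedHairpin]:
    if not hairpins.mature_coords:
        raise ValueError(f"reference set {hairpins.name!r} has no mature coordinates")
    out = []
    for hid, seq in hairpins.sequences:
        if hid not in hairpins.mature_coords:
            raise ValueError(f"hairpin {hid!r} missing mature coordinates")
        out.append(mask_mature(hid, seq, hairpins.mature_coords[hid]))
    return out


def scan_star(
    reads: list[ReadRecord],
    masked_hairpins: list[MaskedHairpin],
    min_identity: float = 0.90,
    min_span: int = 16,
) -> list[AnnotationLabel]:
    """Label reads aligning to the unmasked part of a hairpin as miRNA*.

    Identity here is over the FULL read length (matches / read length), so
    the whole read must sit in the star arm or loop; aligned N columns count
    as mismatches, which automatically rejects reads inside the mask.
    """
    labels = []
    for rec in reads:
        best = None
        best_key = (-1.0, "")
        for mh in masked_hairpins:
            pa = align_pair(rec.sequence, mh.sequence)
            if pa.columns < min_span:
                continue
            matches = round(pa.identity * pa.columns)
            full_identity = matches / len(rec.sequence)
            key = (full_identity, mh.hairpin_id)
            if key > best_key:
                best_key = key
                best = mh
        if best is not None and best_key[0] >= min_identity:
            labels.append(
                AnnotationLabel(rec.id, f"star:{best.hairpin_id}", identity=best_key[0], coverage=1.0)
            )
        else:
            labels.append(AnnotationLabel(rec.id, "unassigned"))
    return labels


def _exact_windowed_hit(read: str, ref_text: str, min_coverage: float) -> float | None:
    """Longest read window (>= coverage floor) occurring exactly in ref_text.

    Returns the coverage achieved, or None. Exactness encodes the 100%
    identity requirement.
    """
    min_len = math.ceil(min_coverage * len(read))
    for w in range(len(read), min_len - 1, -1):
        for start in range(0, len(read) - w + 1):
            if read[start : start + w] in ref_text:
                return w / len(read)
    return None


def annotate_contaminants(
    reads: list[ReadRecord],
    reference_sets: dict[str, ReferenceSet],
    min_identity: float = 1.00,
    min_coverage: float = 0.95,
) -> list[AnnotationLabel]:
    """Label reads matching structural/foreign RNA references.

    At the default 100% identity, a hit is an exact occurrence of >= 95% of
    the read in a reference sequence; set precedence is
    rRNA > tRNA > snRNA > piRNA_transposon > endosymbiont.
    """
    texts = {}
    for name in CONTAMINANT_PRECEDENCE:
        rs = reference_sets.get(name)
        if rs and len(rs):
            texts[name] = "#".join(s for _, s in rs.sequences)
    labels = []
    for rec in reads:
        hit = None
        for name, text in texts.items():
            if min_identity >= 1.0:
                cov = _exact_windowed_hit(rec.sequence, text, min_coverage)
                if cov is not None:
                    hit = AnnotationLabel(rec.id, name, identity=1.0, coverage=cov)
                    break
            else:
                for _, ref_seq in reference_sets[name].sequences:
                    pa = align_pair(rec.sequence, ref_seq)
                    if pa.identity >= min_identity and pa.coverage >= min_coverage:
                        hit = AnnotationLabel(rec.id, name, identity=pa.identity, coverage=pa.coverage)
                        break
                if hit:
                    break
        labels.append(hit or AnnotationLabel(rec.id, "unassigned"))
    return labels


def annotate_reads(
    reads: list[ReadRecord],
    profiles: list[PSSMProfile],
    masked_hairpins: list[MaskedHairpin],
    reference_sets: dict[str, ReferenceSet],
    min_identity: float = 0.90,
) -> dict[str, AnnotationLabel]:
    """One best label per read: contaminants, then known families, then stars.

    Structural/foreign RNA is removed before miRNA calling, hence its
    precedence over the profile scan.
    """
    result: dict[str, AnnotationLabel] = {}
    cont = {l.read_id: l for l in annotate_contaminants(reads, reference_sets)}
    remaining = [r for r in reads if cont[r.id].category == "unassigned"]
    for rec in reads:
        if cont[rec.id].category != "unassigned":
            result[rec.id] = cont[rec.id]
    known = {l.read_id: l for l in scan_profiles(remaining, profiles, min_identity)}
    remaining2 = [r for r in remaining if known[r.id].category == "unassigned"]
    for rec in remaining:
        if known[rec.id].category != "unassigned":
            result[rec.id] = known[rec.id]
    star = {l.read_id: l for l in scan_star(remaining2, masked_hairpins, min_identity)}
    for rec in remaining2:
        result[rec.id] = star[rec.id]
    return result
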