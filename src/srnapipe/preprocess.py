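"""Read collapsing, quality/length/abundance filtering and length profiles.

The filtering rules mirror a deep-sequencing small-RNA workflow on a
species without a reference genome: drop reads with ambiguous bases,
drop anything shorter than 19 nt, and keep only sequences seen more
than 5 times (i.e. total count >= 6) in the library being processed —
rare sequences are overwhelmingly sequencing noise. The 36-nt artefact
class is recognised by its U-rich low-complexity 3' tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Thresholds for read filtering.

    min_count = 6 encodes the "more than 5 reads" rule; set 5 for an
    inclusive reading.
    """

    min_length: int = 19
    min_count: int = 6
    max_ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_count < 1:
            raise ValueError("min_length and min_count must be >= 1")


@dataclass
class FilterReport:
    input_records: int = 0
    input_reads: int = 0
    kept_records: int = 0
    kept_reads: int = 0
    removed_short: int = 0
    removed_ambiguous: int = 0
    removed_rare: int = 0
    removed_reads: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def collapse_identical(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Merge records with identical sequences, summing counts per library.

    The surviving id is the id of the first record carrying the sequence.
    Total read count is conserved. Output is ordered by descending total
    count, then sequence, so collapsing is order-independent.
    """
    merged: dict[str, ReadRecord] = {}
    for rec in reads:
        hit = merged.get(rec.sequence)
        if hit is None:
            merged[rec.sequence] = ReadRecord(
                id=rec.id, sequence=rec.sequence, counts=dict(rec.counts)
            )
        else:
            for lib, n in rec.counts.items():
                hit.counts[lib] = hit.counts.get(lib, 0) + n
    out = list(merged.values())
    out.sort(key=lambda r: (-r.total_count, r.sequence))
    return out


def filter_reads(
    reads: list[ReadRecord],
    params: FilterParams | None = None,
    library: str | None = None,
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply length / ambiguity / abundance filters to collapsed reads.

    The count threshold applies to the count in ``library`` when given
    (libraries are filtered independently), otherwise to the total.
    Removal is attributed to the first failing criterion in the order
    short > ambiguous > rare. Idempotent.
    """
    params = params or FilterParams()
    report = FilterReport(input_records=len(reads), input_reads=_total(reads, library))
    kept: list[ReadRecord] = []
    for rec in reads:
        n = rec.count_in(library) if library else rec.total_count
        if library and n == 0:
            continue  # not observed in this library
        if len(rec.sequence) < params.min_length:
            report.removed_short += 1
            report.removed_reads += n
        elif rec.sequence.count("N") > params.max_ambiguous:
            report.removed_ambiguous += 1
            report.removed_reads += n
        elif n < params.min_count:
            report.removed_rare += 1
            report.removed_reads += n
        else:
            kept.append(rec)
    report.kept_records = len(kept)
    report.kept_reads = _total(kept, library)
    return kept, report


def _total(reads: list[ReadRecord], library: str | None) -> int:
    if library:
        return sum(r.count_in(library) for r in reads)
    return sum(r.total_count for r in reads)


@dataclass
class LengthHistogram:
    library: str
    reads: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.reads.values())

    @property
    def fractions(self) -> dict[int, float]:
        t = self.total
        return {length: n / t for length, n in sorted(self.reads.items())}

    def fraction_in(self, lo: int, hi: int) -> float:
        """Fraction of reads with lo <= length <= hi (inclusive range)."""
        t = self.total
        return sum(n for length, n in self.reads.items() if lo <= length <= hi) / t

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame(
            {"length": list(fr), "reads": [self.reads[k] for k in fr], "fraction": list(fr.values())}
        )


def length_distribution(reads: list[ReadRecord], library: str | None = None) -> LengthHistogram:
    """Per-length read totals and fractions, weighted by read counts."""
    hist: dict[int, int] = {}
    for rec in reads:
        n = rec.count_in(library) if library else rec.total_count
        if n:
            hist[len(rec.sequence)] = hist.get(len(rec.sequence), 0) + n
    if not hist:
        raise ValueError("length_distribution on empty input")
    return LengthHistogram(library=library or "all", reads=hist)


def flag_low_complexity_tail(
    reads: list[ReadRecord], window: int = 10, u_fraction: float = 0.5
) -> dict[str, bool]:
    """Flag reads whose 3'-terminal ``window`` is U(T)-rich (fraction >= threshold).

    Reads shorter than the window are scored on their full length and noted.
    The inclusive comparison matters at the boundary: a tail at exactly the
    threshold is flagged.
    """
    flags: dict[str, bool] = {}
    short = 0
    for rec in reads:
        tail = rec.sequence[-window:]
        if len(rec.sequence) < window:
            short += 1
        flags[rec.id] = tail.count("T") / len(tail) >= u_fraction
    if short:
        logger.warning("%d read(s) shorter than the %d-nt tail window", short, window)
    return flags
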