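"""Core value types shared across the pipeline.

The atom of everything downstream is :class:`ReadRecord`: one distinct
small-RNA sequence together with how many times it was read in each
library. Sequences are stored internally in the DNA alphabet (U is
normalised to T on input); an output flag in the writers renders RNA.
All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")

_RNA_TO_DNA = str.maketrans("Uu", "Tt")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U->T. Raises on non-IUPAC-N residues."""
    s = seq.translate(_RNA_TO_DNA).upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"sequence contains unsupported residues {sorted(bad)}: {seq!r}")
    return s


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class ReadRecord:
    """A unique small-RNA sequence with per-library read counts."""

    id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for read {self.id!r}")
        self.sequence = normalize_sequence(self.sequence)
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"negative count for read {self.id!r}")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError(f"read {self.id!r} has no positive library count")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count_in(self, library: str) -> int:
        return self.counts.get(library, 0)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """A named collection of reference sequences (contaminants, hairpins, species sets).

    ``mature_coords`` maps hairpin id -> (start, end) of the mature arm,
    0-based half-open, and is only meaningful for hairpin sets.
    """

    name: str
    sequences: list[tuple[str, str]] = field(default_factory=list)
    mature_coords: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.sequences]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in reference set {self.name!r}")
        self.sequences = [(i, normalize_sequence(s)) for i, s in self.sequences]
        if self.mature_coords:
            lengths = {i: len(s) for i, s in self.sequences}
            for hid, (start, end) in self.mature_coords.items():
                if hid not in lengths:
                    raise ValueError(f"mature_coords references unknown hairpin {hid!r}")
                if not (0 <= start < end <= lengths[hid]):
                    raise ValueError(
                        f"mature interval ({start}, {end}) outside hairpin {hid!r} "
                        f"of length {lengths[hid]}"
                    )

    def get(self, seq_id: str) -> str:
        for i, s in self.sequences:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def __len__(self) -> int:
        return len(self.sequences)


#: categories a read / candidate row may carry in reports
CANDIDATE_STATUSES = (
    "known",
    "star",
    "conserved_candidate",
    "specific_candidate",
    "contaminant",
    "artefact",
    "unassigned",
)


@dataclass
class CandidateRow:
    candidate_id: str
    sequence: str
    counts: dict[str, int]
    status: str
    cluster_id: str

    def __post_init__(self) -> None:
        base = self.status.split(":", 1)[0]
        if base not in CANDIDATE_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        self.sequence = normalize_sequence(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class CandidateTable:
    """Non-redundant candidate rows, one per representative sequence."""

    rows: list[CandidateRow]
    libraries: list[str]

    def sorted_rows(self) -> list[CandidateRow]:
        # deterministic report order: most abundant first, ties by sequence
        return sorted(self.rows, key=lambda r: (-r.total_count, r.sequence))
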