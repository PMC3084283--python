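"""Readers and writers for the formats the pipeline touches.

Collapsed small-RNA FASTA conventionally encodes the read count in the
header; both common dialects are accepted:

* ``>name-N``   (count suffix after a dash)
* ``>name_xN``  (count suffix after ``_x``; takes precedence)

Headers matching neither dialect get count 1. FASTQ records always count 1
per record. Candidate tables, qPCR Ct tables and cluster maps are plain TSV.
"""

from __future__ import annotations

import logging
import re
import tomllib
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import CandidateRow, CandidateTable, ReadRecord, ReferenceSet, to_rna

logger = logging.getLogger(__name__)

_COUNT_X = re.compile(r"^(?P<id>.+)_x(?P<n>\d+)$")
_COUNT_DASH = re.compile(r"^(?P<id>.+)-(?P<n>\d+)$")


class ParseError(ValueError):
    pass


def parse_count_header(header: str) -> tuple[str, int]:
    """Split a FASTA id into (label, count); ``_xN`` wins over ``-N``."""
    m = _COUNT_X.match(header)
    if m:
        return m.group("id"), int(m.group("n"))
    m = _COUNT_DASH.match(header)
    if m:
        return m.group("id"), int(m.group("n"))
    return header, 1


def read_sequences(path: str | Path, format: str = "fasta", library: str = "lib") -> list[ReadRecord]:
    """Read small-RNA reads from FASTA/FASTQ into :class:`ReadRecord` objects.

    Identical sequences are NOT merged here (see ``preprocess.collapse_identical``).
    U is normalised to T. Records with residues outside {A,C,G,T,N} are
    rejected and reported, not fatal.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[ReadRecord] = []
    rejected = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            if format == "fasta":
                label, count = parse_count_header(rec.id)
            else:
                label, count = rec.id, 1
            try:
                records.append(
                    ReadRecord(id=label, sequence=str(rec.seq), counts={library: count})
                )
            except ValueError as exc:
                rejected += 1
                logger.warning("rejected record %s (#%d in %s): %s", rec.id, i + 1, path, exc)
    except ValueError as exc:  # Bio.SeqIO signals malformed records with ValueError
        raise ParseError(f"malformed {format} in {path}: {exc}") from exc
    if not records:
        logger.warning("no usable records read from %s", path)
    if rejected:
        logger.warning("%d record(s) rejected from %s", rejected, path)
    return records


def write_sequences(records: list[ReadRecord], path: str | Path, library: str | None = None,
                    rna: bool = False) -> None:
    """Write reads as collapsed FASTA with ``id_xN`` count headers."""
    with open(path, "w") as fh:
        for rec in records:
            n = rec.count_in(library) if library else rec.total_count
            if n <= 0:
                continue
            seq = to_rna(rec.sequence) if rna else rec.sequence
            fh.write(f">{rec.id}_x{n}\n{seq}\n")


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# reference bundles

#: reference-set names with a reserved meaning in the pipeline
KNOWN_SET_NAMES = (
    "rRNA", "tRNA", "snRNA", "piRNA_transposon", "endosymbiont",
    "known_mature", "hairpin",
)


def load_reference_sets(config_path: str | Path) -> dict[str, ReferenceSet]:
    """Load reference FASTA sets named in a TOML config.

    The config has a ``[references]`` table mapping set name -> FASTA path and
    optionally ``hairpin_mature_coords`` -> TSV (hairpin_id, start, end;
    0-based half-open). Species sets use names like ``species:lmi``. Paths are
    resolved relative to the config file. Missing optional files yield empty
    sets with a warning; a mature-coords row naming an unknown hairpin is an
    error.
    """
    config_path = Path(config_path)
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)
    refs_cfg = cfg.get("references", {})
    base = config_path.parent
    coords_path = refs_cfg.pop("hairpin_mature_coords", None)
    sets: dict[str, ReferenceSet] = {}
    for name, rel in refs_cfg.items():
        p = base / rel
        if not p.exists():
            logger.warning("reference set %s: %s missing, loaded empty", name, p)
            sets[name] = ReferenceSet(name=name, sequences=[])
            continue
        sets[name] = ReferenceSet(name=name, sequences=read_fasta_sequences(p))
    if coords_path is not None and "hairpin" in sets:
        coords = read_mature_coords(base / coords_path)
        hp = sets["hairpin"]
        sets["hairpin"] = ReferenceSet(
            name="hairpin", sequences=hp.sequences, mature_coords=coords
        )
    return sets


def read_mature_coords(path: str | Path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"hairpin_id": str})
    return {
        str(r.hairpin_id): (int(r.start), int(r.end)) for r in df.itertuples(index=False)
    }


def write_mature_coords(coords: dict[str, tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(
        [(h, s, e) for h, (s, e) in coords.items()],
        columns=["hairpin_id", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate table

_FIXED_COLUMNS = ["candidate_id", "sequence", "status", "cluster_id"]


def write_candidate_table(table: CandidateTable, path: str | Path) -> None:
    """Write a candidate table as TSV with a fixed column order.

    Columns: candidate_id, sequence, status, cluster_id, then one count
    column per library (``reads_<label>``). Rows are ordered by descending
    total count with lexicographic sequence as tie-break.
    """
    rows = []
    for r in table.sorted_rows():
        row = {
            "candidate_id": r.candidate_id,
            "sequence": r.sequence,
            "status": r.status,
            "cluster_id": r.cluster_id,
        }
        for lib in table.libraries:
            row[f"reads_{lib}"] = r.counts.get(lib, 0)
        rows.append(row)
    cols = _FIXED_COLUMNS + [f"reads_{lib}" for lib in table.libraries]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path) -> CandidateTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"candidate_id": str, "cluster_id": str})
    libs = [c[len("reads_"):] for c in df.columns if c.startswith("reads_")]
    rows = [
        CandidateRow(
            candidate_id=str(r["candidate_id"]),
            sequence=str(r["sequence"]),
            status=str(r["status"]),
            cluster_id=str(r["cluster_id"]),
            counts={lib: int(r[f"reads_{lib}"]) for lib in libs},
        )
        for _, r in df.iterrows()
    ]
    return CandidateTable(rows=rows, libraries=libs)


# ---------------------------------------------------------------------------
# qPCR Ct tables

QPCR_COLUMNS = ["gene", "group", "replicate", "Ct"]


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct TSV (gene, group in {control, treated}, replicate, Ct)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"qPCR table {path} missing columns {sorted(missing)}")
    bad = set(df["group"].unique()) - {"control", "treated"}
    if bad:
        raise ParseError(f"qPCR table {path}: unknown groups {sorted(bad)}")
    return df


def write_qpcr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_run_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
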