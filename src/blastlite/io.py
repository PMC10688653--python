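"""FASTA input and tabular hit output.

The hit table is BLAST outfmt-6-like TSV/CSV with two extra trailing
columns (strand and CIGAR). Identity is written as a percentage with one
decimal; coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Tuple, Union

from .alphabet import Alphabet, Sequence, get_alphabet

PathOrStream = Union[str, Path, IO[str]]


class MalformedFastaError(ValueError):
    pass


class MalformedHitTableError(ValueError):
    pass


HIT_COLUMNS = (
    "query_id", "target_id", "identity", "alignment_length", "mismatches",
    "gap_openings", "q_start", "q_end", "t_start", "t_end", "strand", "cigar",
)


@dataclass(frozen=True)
class HitRecord:
    """One accepted query-target match.

    ``identity_fraction`` is kept as an exact fraction internally and
    printed as a percentage with one decimal. Coordinates are 1-based
    inclusive on the sequence as stored; minus-strand hits keep
    query_start <= query_end on the original query and set strand "-".
    Strand is "n/a" exactly for protein searches.
    """

    query_id: str
    target_id: str
    identity_fraction: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    cigar: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_fraction <= 1.0):
            raise ValueError("identity_fraction outside [0, 1]")
        if self.query_start > self.query_end or self.target_start > self.target_end:
            raise ValueError("hit coordinates must satisfy start <= end")
        if self.strand not in {"+", "-", "n/a"}:
            raise ValueError(f"bad strand {self.strand!r}")


def _open_for(source: PathOrStream, mode: str):
    """Return (stream, should_close)."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta_raw(source: PathOrStream) -> Iterator[Tuple[str, str, str]]:
    """Yield (identifier, description, raw residue text) per record.

    Validates structure only (header lines, non-empty records); residue
    validation happens in :func:`read_fasta` when sequences are built.
    """
    stream, close = _open_for(source, "r")
    try:
        ident: Optional[str] = None
        desc = ""
        chunks: List[str] = []
        saw_any = False
        for lineno, line in enumerate(stream, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                if ident is not None:
                    if not chunks:
                        raise MalformedFastaError(
                            f"record {ident!r} has an empty sequence"
                        )
                    yield ident, desc, "".join(chunks)
                header = line[1:].strip()
                if not header:
                    raise MalformedFastaError(
                        f"empty FASTA header at line {lineno}"
                    )
                parts = header.split(None, 1)
                ident = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                saw_any = True
            else:
                if ident is None:
                    raise MalformedFastaError(
                        "FASTA input does not start with a '>' header"
                    )
                chunks.append(line.strip())
        if ident is not None:
            if not chunks:
                raise MalformedFastaError(f"record {ident!r} has an empty sequence")
            yield ident, desc, "".join(chunks)
        elif not saw_any:
            return
    finally:
        if close:
            stream.close()


def read_fasta(
    source: PathOrStream, alphabet: Union[str, Alphabet] = "dna"
) -> List[Sequence]:
    """Parse FASTA text into a list of :class:`Sequence`, in file order.

    Multi-line records are concatenated; the first whitespace-delimited
    header token is the identifier, the remainder the description.
    """
    alpha = get_alphabet(alphabet)
    return [
        Sequence(ident, residues, alpha, desc)
        for ident, desc, residues in parse_fasta_raw(source)
    ]


def write_fasta(
    sequences: Iterable[Sequence], sink: PathOrStream, width: int = 70
) -> None:
    stream, close = _open_for(sink, "w")
    try:
        for seq in sequences:
            header = seq.identifier
            if seq.description:
                header += " " + seq.description
            stream.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                stream.write(seq.residues[i:i + width] + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def _hit_row(hit: HitRecord) -> List[str]:
    return [
        hit.query_id,
        hit.target_id,
        f"{hit.identity_fraction * 100:.1f}",
        str(hit.alignment_length),
        str(hit.mismatches),
        str(hit.gap_openings),
        str(hit.query_start),
        str(hit.query_end),
        str(hit.target_start),
        str(hit.target_end),
        hit.strand,
        hit.cigar,
    ]


def write_hits(
    hits: Iterable[HitRecord], sink: PathOrStream, dialect: str = "tsv"
) -> None:
    """Write hits as TSV (default) or CSV with a header row.

    Output is byte-identical for identical inputs: fixed column order,
    fixed identity formatting, '\\n' line endings.
    """
    if dialect not in {"tsv", "csv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    stream, close = _open_for(sink, "w")
    try:
        writer = csv.writer(stream, delimiter=delim, lineterminator="\n")
        writer.writerow(HIT_COLUMNS)
        for hit in hits:
            writer.writerow(_hit_row(hit))
    finally:
        if close:
            stream.close()


def hits_to_text(hits: Iterable[HitRecord], dialect: str = "tsv") -> str:
    buf = _stdio.StringIO()
    write_hits(hits, buf, dialect)
    return buf.getvalue()


def read_hits(source: PathOrStream, dialect: str = "tsv") -> List[HitRecord]:
    """Inverse of :func:`write_hits` (identity at 0.1% precision)."""
    delim = "\t" if dialect == "tsv" else ","
    stream, close = _open_for(source, "r")
    try:
        reader = csv.reader(stream, delimiter=delim)
        rows = list(reader)
    finally:
        if close:
            stream.close()
    if not rows:
        raise MalformedHitTableError("empty hit table (missing header)")
    if tuple(rows[0]) != HIT_COLUMNS:
        raise MalformedHitTableError(f"unexpected header: {rows[0]!r}")
    hits: List[HitRecord] = []
    for i, row in enumerate(rows[1:], 2):
        if len(row) != len(HIT_COLUMNS):
            raise MalformedHitTableError(
                f"line {i}: expected {len(HIT_COLUMNS)} columns, got {len(row)}"
            )
        try:
            hits.append(
                HitRecord(
                    query_id=row[0],
                    target_id=row[1],
                    identity_fraction=float(row[2]) / 100.0,
                    alignment_length=int(row[3]),
                    mismatches=int(row[4]),
                    gap_openings=int(row[5]),
                    query_start=int(row[6]),
                    query_end=int(row[7]),
                    target_start=int(row[8]),
                    target_end=int(row[9]),
                    strand=row[10],
                    cigar=row[11],
                )
            )
        except ValueError as exc:
            raise MalformedHitTableError(f"line {i}: {exc}") from exc
    return hits
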