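"""Sequence, alignment and interval I/O.

Thin readers/writers over Biopython for the plain-text formats the pipeline
touches (FASTA, FASTQ, aligned FASTA, BED6, headered TSV) plus the small
record/alignment containers shared by all stages.

All coordinates are 0-based half-open internally; 1-based numbers appear only
in human-readable reports. ``U`` and ``T`` are interchangeable everywhere:
sequences are normalized to ``T`` on ingest (RNA can be echoed back with
:func:`to_rna`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SeqRecord",
    "AlignmentBlock",
    "BedInterval",
    "ParseError",
    "AlignmentError",
    "read_sequences",
    "write_sequences",
    "write_alignment",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "revcomp",
    "complement_base",
    "normalize",
    "to_rna",
]

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv-",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb-")

# IUPAC letters accepted on ingest (plus gap)
_VALID = set("ACGTUNRYSWKMBDHV-")


class ParseError(ValueError):
    """A record failed to parse under the named dialect."""


class AlignmentError(ValueError):
    """Rows of an alignment block disagree in length or identity."""


def normalize(seq: str) -> str:
    """Uppercase and fold U onto T (RNA and DNA compare transparently)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Echo a (normalized) sequence in RNA alphabet."""
    return seq.upper().replace("T", "U")


def complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement; tolerant of IUPAC ambiguity codes and gaps."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with per-base qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        self.seq = normalize(self.seq)
        bad = set(self.seq) - _VALID
        if bad:
            raise ParseError(f"record {self.id!r}: invalid characters {sorted(bad)}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(f"record {self.id!r}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        q = self.qual[::-1] if self.qual is not None else None
        return SeqRecord(self.id, revcomp(self.seq), q)


@dataclass
class AlignmentBlock:
    """Equal-width rows with unique ids; the unit the covariation stage eats."""

    rows: list[SeqRecord]
    reference_row_id: str | None = None
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            self.width = 0
            return
        widths = {len(r.seq) for r in self.rows}
        if len(widths) != 1:
            raise AlignmentError(f"mixed row lengths in alignment: {sorted(widths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate row ids in alignment")
        self.width = widths.pop()

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, row_id: str) -> SeqRecord:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(row_id)


@dataclass(frozen=True)
class BedInterval:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.name!r}: start {self.start} >= end {self.end}"
            )


def _phred(letters: str) -> list[int]:
    return [ord(c) - 33 for c in letters]


def read_sequences(path, format: str = "fasta"):
    """Read ``fasta``/``fastq`` into records, or ``aligned-fasta`` into a block.

    Malformed records raise :class:`ParseError` naming the offending line;
    ragged aligned-fasta raises :class:`AlignmentError`.
    """
    path = Path(path)
    if format in ("fasta", "aligned-fasta"):
        records = _read_fasta(path)
        if format == "aligned-fasta":
            return AlignmentBlock(records)
        for r in records:
            if "-" in r.seq:
                raise ParseError(f"record {r.id!r}: gaps outside an alignment block")
        return records
    if format == "fastq":
        out = []
        try:
            for rec in SeqIO.parse(str(path), "fastq"):
                out.append(
                    SeqRecord(rec.id, str(rec.seq),
                              _phred(rec.format("fastq").splitlines()[3]))
                )
        except ValueError as e:  # Biopython's fastq errors carry context
            raise ParseError(f"{path}: {e}") from e
        return out
    raise ValueError(f"unknown format {format!r}")


def _read_fasta(path: Path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    cur_id: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    records.append(SeqRecord(cur_id, "".join(chunks)))
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line.strip())
        if cur_id is not None:
            records.append(SeqRecord(cur_id, "".join(chunks)))
    for r in records:
        if not r.seq:
            raise ParseError(f"{path}: record {r.id!r} has empty sequence")
    return records


def write_sequences(records: Iterable[SeqRecord], path, format: str = "fasta",
                    width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "fasta":
            for r in records:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.seq), width):
                    fh.write(r.seq[i : i + width] + "\n")
        elif format == "fastq":
            for r in records:
                qual = r.qual if r.qual is not None else [30] * len(r.seq)
                fh.write(f"@{r.id}\n{r.seq}\n+\n")
                fh.write("".join(chr(q + 33) for q in qual) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def write_alignment(block: AlignmentBlock, path) -> None:
    """Aligned FASTA, one line per row (rows keep their gaps)."""
    with open(path, "w") as fh:
        for r in block.rows:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_bed(sites: Sequence[BedInterval], path) -> None:
    """Standard 6-column BED, tab-separated, sorted by (contig, start)."""
    ordered = sorted(sites, key=lambda s: (s.contig, s.start, s.end))
    with open(path, "w") as fh:
        for s in ordered:
            score = int(s.score) if float(s.score).is_integer() else s.score
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.name}\t{score}\t{s.strand}\n")


def read_tsv(path, **kwargs):
    import pandas as pd

    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)
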