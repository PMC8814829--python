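"""On-disk format boundary: FASTQ, FASTA, mature GFF3, BED6, TSV.

Conventions enforced here and nowhere else:

* DNA alphabet in memory — U is mapped to T on every ingest.
* Hairpin-relative (GFF3) and genomic coordinates are 1-based inclusive
  in memory; BED6 on disk is 0-based half-open and converted on read and
  write.
* FASTQ is strict 4-line records; parse errors name the offending line.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GenomicInterval
from .quantify import Hairpin, MatureAnnotation

__all__ = [
    "ReadRecord",
    "FastqParseError",
    "normalize_seq",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_mature_gff3",
    "write_mature_gff3",
    "read_bed6",
    "write_bed6",
]


def normalize_seq(seq: str) -> str:
    """Uppercase and map U to T (RNA to DNA representation)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, sequence, per-base quality."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


class FastqParseError(ValueError):
    """Malformed FASTQ; carries the 1-based line number of the offence."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Iterate strict 4-line FASTQ records (gzip transparent)."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(path, lineno, "expected '@' header line")
            block = [fh.readline() for _ in range(3)]
            if any(line == "" for line in block):
                first_missing = lineno + 1 + [b == "" for b in block].index(True)
                raise FastqParseError(
                    path, first_missing,
                    "truncated record (FASTQ requires 4 lines per read)",
                )
            seq, plus, qual = (line.rstrip("\n") for line in block)
            if not plus.startswith("+"):
                raise FastqParseError(path, lineno + 2, "expected '+' separator line")
            if len(seq) != len(qual):
                raise FastqParseError(
                    path, lineno + 3, "quality length differs from sequence length"
                )
            lineno += 3
            yield ReadRecord(id=header[1:], sequence=normalize_seq(seq), quality=qual)


def write_fastq(path, reads: Iterable[ReadRecord]) -> int:
    """Write 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA as (name, sequence) pairs, U->T normalized."""
    return [
        (rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> int:
    seqs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    return SeqIO.write(seqs, str(path), "fasta")


def write_mature_gff3(path, matures: Sequence[MatureAnnotation]) -> None:
    """Mature annotations as GFF3 with hairpin-relative 1-based coordinates.

    Column 1 is the hairpin name; attributes carry ``ID`` (mature name)
    and ``hairpin``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in matures:
            fh.write(
                f"{m.hairpin}\texomir\tmiRNA\t{m.x}\t{m.y}\t.\t+\t.\t"
                f"ID={m.name};hairpin={m.hairpin}\n"
            )


def read_mature_gff3(path, hairpins: Sequence[Hairpin]) -> list[MatureAnnotation]:
    """Read mature GFF3 back; sequences are extracted from the hairpins."""
    by_name = {h.name: h.sequence for h in hairpins}
    matures: list[MatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, _, start, end, _, _, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr:
                raise ValueError(f"{path}:{lineno}: missing ID attribute")
            if seqid not in by_name:
                raise ValueError(f"{path}:{lineno}: unknown hairpin {seqid!r}")
            x, y = int(start), int(end)
            hp_seq = by_name[seqid]
            if not (1 <= x <= y <= len(hp_seq)):
                raise ValueError(
                    f"{path}:{lineno}: span [{x}, {y}] outside hairpin {seqid} "
                    f"(length {len(hp_seq)})"
                )
            matures.append(
                MatureAnnotation(
                    name=attr["ID"], hairpin=seqid, x=x, y=y,
                    sequence=hp_seq[x - 1 : y],
                )
            )
    return matures


def write_bed6(path, intervals: Sequence[GenomicInterval]) -> None:
    """BED6 (0-based half-open on disk) from 1-based inclusive intervals."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


def read_bed6(path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _, strand = fields[:6]
            intervals.append(
                GenomicInterval(
                    chrom=chrom, start=int(start) + 1, end=int(end),
                    strand=strand, name=name,
                )
            )
    return intervals
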