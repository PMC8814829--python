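"""Raw small-RNA read cleaning with per-filter accounting.

The cascade applied to every raw read, in order, attributing removal to
the first failing stage:

1. **3′ adapter trimming** — the read is cut at the leftmost occurrence
   of an adapter prefix of length >= ``min_overlap`` (default 5, exact
   match).  A read that becomes empty is removed as ``adapter_only``.
2. **Length bounds** — shorter than 18 nt (``too_short``) or longer than
   34 nt (``too_long``).
3. **Composition filters** — the low-complexity rules typical of
   small-RNA pipelines: >= 80 % of a single base (``mono_composition``);
   alphabet restricted to {A,C} (``ac_only``) or {G,T} (``gt_only``);
   whole-read tandem repeats of a 2-mer (``dimer_repeat``) or 3-mer
   (``trimer_repeat``), allowing one trailing partial unit; any ambiguous
   base (``ambiguous_base``).
4. **Contaminant subtraction** — reads that are exact substrings of any
   contaminant ncRNA sequence (rRNA/tRNA/snRNA/repeats; either strand)
   are removed as ``contaminant``.

Survivors are the "clean reads" passed to quantification.  The
:class:`QCReport` satisfies the exact accounting identity
``input = surviving + sum(removed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import ReadRecord, read_fastq

__all__ = [
    "REASONS",
    "QCReport",
    "ContaminantIndex",
    "trim_adapter",
    "composition_flags",
    "length_filter",
    "contaminant_filter",
    "clean_reads",
    "clean_library",
]

REASONS = (
    "adapter_only",
    "too_short",
    "too_long",
    "mono_composition",
    "ac_only",
    "gt_only",
    "dimer_repeat",
    "trimer_repeat",
    "contaminant",
    "ambiguous_base",
)

# attribution priority among co-occurring composition flags
_COMPOSITION_PRIORITY = (
    "mono_composition",
    "ac_only",
    "gt_only",
    "dimer_repeat",
    "trimer_repeat",
    "ambiguous_base",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class QCReport:
    """Per-reason removal accounting for one library."""

    input_reads: int = 0
    surviving_reads: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )

    def check(self) -> None:
        if self.input_reads != self.surviving_reads + sum(self.removed.values()):
            raise AssertionError("QC accounting identity violated")

    def to_dict(self) -> dict:
        return {
            "input_reads": self.input_reads,
            "surviving_reads": self.surviving_reads,
            **{f"removed_{k}": v for k, v in self.removed.items()},
        }


def trim_adapter(
    read: ReadRecord, adapter: str, min_overlap: int = 5
) -> ReadRecord:
    """Remove the read suffix starting at the leftmost adapter-prefix hit.

    A hit is an exact match of ``adapter[:k]`` at read position *i* with
    ``k = min(len(adapter), len(read) − i) >= min_overlap``.  The quality
    string is truncated in lockstep.  Returns the read unchanged when no
    hit exists; the returned read may be empty (caller marks it
    ``adapter_only``).
    """
    adapter = adapter.upper().replace("U", "T")
    if len(adapter) < min_overlap:
        raise ValueError(
            f"adapter length {len(adapter)} below min_overlap {min_overlap}"
        )
    seq = read.sequence
    cut = None
    for i in range(0, len(seq) - min_overlap + 1):
        k = min(len(adapter), len(seq) - i)
        if seq[i : i + k] == adapter[:k]:
            cut = i
            break
    if cut is None:
        return read
    return ReadRecord(id=read.id, sequence=seq[:cut], quality=read.quality[:cut])


def _is_tandem(seq: str, unit_len: int) -> bool:
    """Whole-read tandem repeat of ``seq[:unit_len]`` with >= 2 full units,
    allowing one trailing partial unit."""
    if len(seq) < 2 * unit_len:
        return False
    unit = seq[:unit_len]
    full, rem = divmod(len(seq), unit_len)
    return seq == unit * full + unit[:rem]


def composition_flags(sequence: str) -> set[str]:
    """All composition-filter flags triggered by a sequence.

    Flags are independent and may co-occur; see the module docstring for
    definitions.  Empty input is an error.
    """
    if not sequence:
        raise ValueError("composition_flags requires a non-empty sequence")
    seq = sequence.upper().replace("U", "T")
    flags: set[str] = set()
    alphabet = set(seq)
    if not alphabet <= {"A", "C", "G", "T"}:
        flags.add("ambiguous_base")
    # >= 80 % of one base, inclusive threshold, exact integer arithmetic
    n = len(seq)
    if max(seq.count(b) for b in "ACGT") * 5 >= 4 * n:
        flags.add("mono_composition")
    if alphabet <= {"A", "C"}:
        flags.add("ac_only")
    if alphabet <= {"G", "T"}:
        flags.add("gt_only")
    if _is_tandem(seq, 2):
        flags.add("dimer_repeat")
    if _is_tandem(seq, 3):
        flags.add("trimer_repeat")
    return flags


def length_filter(sequence: str, min_len: int = 18, max_len: int = 34) -> str:
    """Classify a sequence as ``keep``, ``too_short`` or ``too_long``."""
    if len(sequence) < min_len:
        return "too_short"
    if len(sequence) > max_len:
        return "too_long"
    return "keep"


class ContaminantIndex:
    """Substring index over named contaminant sequences, both strands."""

    def __init__(self, contaminants: Iterable[tuple[str, str]]):
        self.names: list[str] = []
        texts: list[str] = []
        for name, seq in contaminants:
            seq = seq.upper().replace("U", "T")
            self.names.append(name)
            texts.append(seq)
            texts.append(_revcomp(seq))
        # '#' separators prevent matches spanning two contaminants
        self._text = "#".join(texts)

    def __contains__(self, read_sequence: str) -> bool:
        if not read_sequence or not self._text:
            return False
        return read_sequence in self._text


def contaminant_filter(sequence: str, contaminants: ContaminantIndex) -> str:
    """``contaminant`` iff the read is an exact substring of any
    contaminant (either strand), else ``pass``."""
    return "contaminant" if sequence in contaminants else "pass"


def clean_reads(
    reads: Iterable[ReadRecord],
    adapter: str,
    contaminants: ContaminantIndex | None = None,
    min_len: int = 18,
    max_len: int = 34,
    min_overlap: int = 5,
) -> tuple[list[ReadRecord], QCReport]:
    """Run the full cascade over an iterable of reads."""
    contaminants = contaminants or ContaminantIndex([])
    report = QCReport()
    clean: list[ReadRecord] = []
    for read in reads:
        report.input_reads += 1
        trimmed = trim_adapter(read, adapter, min_overlap=min_overlap)
        if not trimmed.sequence:
            report.removed["adapter_only"] += 1
            continue
        verdict = length_filter(trimmed.sequence, min_len=min_len, max_len=max_len)
        if verdict != "keep":
            report.removed[verdict] += 1
            continue
        flags = composition_flags(trimmed.sequence)
        if flags:
            for reason in _COMPOSITION_PRIORITY:
                if reason in flags:
                    report.removed[reason] += 1
                    break
            continue
        if contaminant_filter(trimmed.sequence, contaminants) == "contaminant":
            report.removed["contaminant"] += 1
            continue
        report.surviving_reads += 1
        clean.append(trimmed)
    report.check()
    return clean, report


def clean_library(
    fastq_path,
    adapter: str,
    contaminants: ContaminantIndex | None = None,
    min_len: int = 18,
    max_len: int = 34,
    min_overlap: int = 5,
) -> tuple[list[ReadRecord], QCReport]:
    """Clean one FASTQ library from disk (gzip transparent)."""
    return clean_reads(
        read_fastq(fastq_path),
        adapter,
        contaminants=contaminants,
        min_len=min_len,
        max_len=max_len,
        min_overlap=min_overlap,
    )
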