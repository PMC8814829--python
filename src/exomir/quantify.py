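"""Mature-miRNA quantification against pre-miRNA hairpins.

Clean reads are matched exactly (0 mismatches) as substrings of hairpin
sequences.  A read aligned to hairpin *h* at span ``[s, e]`` (1-based
inclusive, hairpin-relative) is counted as expression of a mature miRNA
annotated at ``[x, y]`` on *h* iff the whole read span lies inside the
tolerance window ``[x−2, y+5]`` — i.e. ``s >= x−2`` and ``e <= y+5``.
The window absorbs the 5′/3′ end heterogeneity (isomiRs) typical of
small-RNA libraries while excluding reads from elsewhere on the hairpin.

Multi-mapping is resolved deterministically: a read matching several
hairpins goes to the lexicographically smallest hairpin name, then the
leftmost position; a read eligible for several matures on one hairpin is
counted toward the mature with the smallest ``|s − x|``, ties to the
lower ``x``.  Counts are therefore reproducible and independent of read
order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotation import GenomicInterval

__all__ = [
    "Hairpin",
    "MatureAnnotation",
    "HairpinAlignment",
    "CountMatrix",
    "align_reads",
    "count_mature",
    "mapping_stats",
]


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA: the mapping substrate, optionally genomically placed."""

    name: str
    sequence: str
    genomic: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"hairpin {self.name} has empty sequence")


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA as a 1-based inclusive span ``[x, y]`` on its hairpin."""

    name: str
    hairpin: str
    x: int
    y: int
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.x <= self.y):
            raise ValueError(f"mature {self.name}: bad span [{self.x}, {self.y}]")
        if len(self.sequence) != self.y - self.x + 1:
            raise ValueError(
                f"mature {self.name}: sequence length {len(self.sequence)} "
                f"does not match span [{self.x}, {self.y}]"
            )


def validate_mature(mature: MatureAnnotation, hairpin: Hairpin) -> None:
    """Check that a mature annotation lies inside its hairpin and matches it."""
    if mature.hairpin != hairpin.name:
        raise ValueError(f"mature {mature.name} does not reference {hairpin.name}")
    if mature.y > len(hairpin.sequence):
        raise ValueError(
            f"mature {mature.name}: y={mature.y} beyond hairpin length "
            f"{len(hairpin.sequence)}"
        )
    if hairpin.sequence[mature.x - 1 : mature.y] != mature.sequence:
        raise ValueError(
            f"mature {mature.name}: sequence differs from hairpin[{mature.x}..{mature.y}]"
        )


@dataclass(frozen=True)
class HairpinAlignment:
    """An exact-substring placement of a read sequence on a hairpin."""

    sequence: str
    hairpin: str
    start: int  # 1-based inclusive
    end: int
    count: int  # read multiplicity behind this unique sequence


def align_reads(
    reads: Iterable[str], hairpins: Sequence[Hairpin]
) -> tuple[list[HairpinAlignment], int]:
    """Exact-match reads to hairpins; returns (alignments, n_unaligned_reads).

    Reads are collapsed to unique sequences first; each unique sequence is
    assigned to at most one (hairpin, position) by the deterministic
    tie-break (lowest hairpin name, then leftmost occurrence).
    """
    names = [h.name for h in hairpins]
    if len(set(names)) != len(names):
        raise ValueError("hairpin names are not unique")
    ordered = sorted(hairpins, key=lambda h: h.name)

    multiplicity = Counter(reads)
    alignments: list[HairpinAlignment] = []
    unaligned = 0
    for seq, n in multiplicity.items():
        hit = None
        for h in ordered:
            pos = h.sequence.find(seq)
            if pos >= 0:
                hit = (h.name, pos + 1, pos + len(seq))
                break
        if hit is None:
            unaligned += n
        else:
            alignments.append(
                HairpinAlignment(sequence=seq, hairpin=hit[0], start=hit[1], end=hit[2], count=n)
            )
    return alignments, unaligned


@dataclass
class CountMatrix:
    """Mature-miRNA × sample raw counts plus per-sample mapping totals.

    ``lib_sizes`` is the number of hairpin-aligned reads per sample (the
    normalization denominator), ``unique_counts`` the number of distinct
    aligned read sequences, and ``hairpin_of`` maps each mature name to
    its hairpin for census statistics.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series
    unique_counts: pd.Series
    hairpin_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if self.counts[s].sum() > self.lib_sizes[s]:
                raise ValueError(
                    f"sample {s}: counted reads exceed aligned library size"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def concat(cls, parts: Sequence["CountMatrix"]) -> "CountMatrix":
        counts = pd.concat([p.counts for p in parts], axis=1).fillna(0).astype(int)
        lib = pd.concat([p.lib_sizes for p in parts])
        uniq = pd.concat([p.unique_counts for p in parts])
        hairpin_of: dict[str, str] = {}
        for p in parts:
            hairpin_of.update(p.hairpin_of)
        return cls(counts=counts, lib_sizes=lib, unique_counts=uniq, hairpin_of=hairpin_of)


def _eligible_mature(
    alignment: HairpinAlignment, matures: Sequence[MatureAnnotation]
) -> MatureAnnotation | None:
    """The mature this alignment counts toward, or None.

    Window rule: read span ``[s, e]`` must satisfy ``s >= x−2`` and
    ``e <= y+5``; among several eligible matures the one with smallest
    ``|s − x|`` wins, ties to the lower ``x``.
    """
    s, e = alignment.start, alignment.end
    best: MatureAnnotation | None = None
    best_key: tuple[int, int] | None = None
    for m in matures:
        if m.hairpin != alignment.hairpin:
            continue
        if s >= m.x - 2 and e <= m.y + 5:
            key = (abs(s - m.x), m.x)
            if best_key is None or key < best_key:
                best, best_key = m, key
    return best


def count_mature(
    alignments: Sequence[HairpinAlignment],
    matures: Sequence[MatureAnnotation],
    sample: str = "sample",
    hairpins: Sequence[Hairpin] | None = None,
) -> CountMatrix:
    """Count aligned reads into mature windows for one sample.

    Every mature appears as a row (zero-filled when unobserved).  If
    ``hairpins`` is given, each mature is validated against its hairpin;
    a mature referencing an unknown hairpin raises.
    """
    if hairpins is not None:
        by_name = {h.name: h for h in hairpins}
        for m in matures:
            if m.hairpin not in by_name:
                raise KeyError(f"mature {m.name} references unknown hairpin {m.hairpin}")
            validate_mature(m, by_name[m.hairpin])

    counts = {m.name: 0 for m in matures}
    for a in alignments:
        m = _eligible_mature(a, matures)
        if m is not None:
            counts[m.name] += a.count

    lib_size = sum(a.count for a in alignments)
    unique = len({a.sequence for a in alignments})
    df = pd.DataFrame({sample: pd.Series(counts, dtype=int)})
    return CountMatrix(
        counts=df,
        lib_sizes=pd.Series({sample: lib_size}, dtype=int),
        unique_counts=pd.Series({sample: unique}, dtype=int),
        hairpin_of={m.name: m.hairpin for m in matures},
    )


def mapping_stats(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample census: expressed pre-miRNAs and matures, mapping totals."""
    rows = []
    for s in cm.samples:
        col = cm.counts[s]
        expressed = col[col > 0]
        premirnas = {cm.hairpin_of.get(m, m) for m in expressed.index}
        rows.append(
            {
                "sample": s,
                "n_premirna": len(premirnas),
                "n_mature": int((col > 0).sum()),
                "unique_srna_mapped": int(cm.unique_counts[s]),
                "total_srna_mapped": int(cm.lib_sizes[s]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "n_premirna", "n_mature", "unique_srna_mapped", "total_srna_mapped"],
    )
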