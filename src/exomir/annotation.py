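"""Genomic clustering and seed-family classification of miRNAs.

Two annotation layers are applied to a set of (upregulated) miRNAs:

* **Genomic clusters** — pre-miRNAs whose genomic intervals lie within a
  fixed distance (default 10 kb) of one another are chained into clusters
  by single linkage per chromosome.  Clusters require at least two
  members; strand is ignored for linking and reported per member.
* **Seed families** — mature miRNAs sharing an identical seed (positions
  2–8 of the mature sequence, 1-based, a 7-mer) belong to one family.
  Family names come from an optional user-supplied seed→name table
  (e.g. TargetScan-derived); unnamed seeds get a synthesized
  ``seed:<7-mer>`` label.

Coordinates are 1-based inclusive in memory; BED conversion happens in
:mod:`exomir.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "MiRNACluster",
    "SeedFamily",
    "parse_locus_string",
    "find_clusters",
    "seed_of",
    "assign_families",
    "clusters_table",
    "families_table",
]

_STRAND_NORM = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


@dataclass(frozen=True)
class GenomicInterval:
    """A named, stranded genomic interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"degenerate interval {self.name}: start={self.start} end={self.end}"
            )
        norm = _STRAND_NORM.get(self.strand)
        if norm is None:
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        object.__setattr__(self, "strand", norm)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MiRNACluster:
    """A chain of >= 2 pre-miRNAs on one chromosome, linked by gap <= max_gap."""

    cluster_id: str
    chrom: str
    members: list[GenomicInterval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]


@dataclass
class SeedFamily:
    """Mature miRNAs sharing one 7-mer seed (mature positions 2-8)."""

    seed: str
    name: str
    matures: list[str] = field(default_factory=list)
    hairpins: list[str] = field(default_factory=list)


_LOCUS_RE = re.compile(
    r"^\s*(?P<name>\S+)\s*\(\s*(?P<chrom>[^_\s()]+)_(?P<start>\d+)_(?P<end>\d+)_"
    r"(?P<strand>[+\-−])\s*\)\s*$"
)


def parse_locus_string(text: str) -> GenomicInterval:
    """Parse a ``name (chrom_start_end_strand)`` locus string.

    This is the compact pre-miRNA placement notation used in published
    cluster tables, e.g. ``"ssc-mir-34c-1 (9_44166873_44166952_-)"``.
    """
    m = _LOCUS_RE.match(text)
    if m is None:
        raise ValueError(f"malformed locus string: {text!r}")
    return GenomicInterval(
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=m.group("strand"),
        name=m.group("name"),
    )


def find_clusters(
    intervals: Iterable[GenomicInterval], max_gap: int = 10_000
) -> list[MiRNACluster]:
    """Single-linkage chaining of intervals within ``max_gap`` per chromosome.

    Intervals are sorted by start per chromosome and consecutive intervals
    are linked when the gap between the running chain end and the next
    start (``next.start − chain_end − 1``, floored at 0 for overlaps) is at
    most ``max_gap``.  Only chains with >= 2 members are reported; strand
    plays no role in linking.  Output is independent of input order.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    clusters: list[MiRNACluster] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end, iv.name))
        chain: list[GenomicInterval] = []
        chain_end = None
        for iv in ivs:
            if chain and iv.start - chain_end - 1 <= max_gap:
                chain.append(iv)
                chain_end = max(chain_end, iv.end)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(len(clusters), chrom, chain))
                chain = [iv]
                chain_end = iv.end
        if len(chain) >= 2:
            clusters.append(_make_cluster(len(clusters), chrom, chain))
    return clusters


def _make_cluster(index: int, chrom: str, chain: list[GenomicInterval]) -> MiRNACluster:
    return MiRNACluster(cluster_id=f"Cluster {index + 1}", chrom=chrom, members=list(chain))


def seed_of(mature_sequence: str) -> str:
    """Seed region of a mature miRNA: positions 2-8, 1-based (a 7-mer).

    The sequence is uppercased and U is normalized to T.
    """
    seq = mature_sequence.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(
            f"mature sequence of length {len(seq)} has no complete 2-8 seed"
        )
    return seq[1:8]


def assign_families(
    matures: Sequence,
    family_names: Mapping[str, str] | None = None,
) -> list[SeedFamily]:
    """Partition mature miRNAs into families by exact 7-mer seed identity.

    ``matures`` is a sequence of objects with ``name``, ``hairpin`` and
    ``sequence`` attributes (e.g. :class:`exomir.quantify.MatureAnnotation`).
    ``family_names`` optionally maps seeds to published family names.
    """
    family_names = family_names or {}
    by_seed: dict[str, SeedFamily] = {}
    for m in matures:
        seed = seed_of(m.sequence)
        fam = by_seed.get(seed)
        if fam is None:
            fam = SeedFamily(
                seed=seed, name=family_names.get(seed, f"seed:{seed}")
            )
            by_seed[seed] = fam
        fam.matures.append(m.name)
        fam.hairpins.append(m.hairpin)
    return [by_seed[s] for s in sorted(by_seed)]


def clusters_table(clusters: Sequence[MiRNACluster]) -> pd.DataFrame:
    """Cluster table: one row per cluster with member loci strings."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster": c.cluster_id,
                "n_premirna": len(c.members),
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "pre_mirnas": " | ".join(
                    f"{m.name} ({m.chrom}_{m.start}_{m.end}_{m.strand})"
                    for m in c.members
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster", "n_premirna", "chrom", "start", "end", "pre_mirnas"]
    )


def families_table(families: Sequence[SeedFamily]) -> pd.DataFrame:
    """Family table: one row per (mature, pre-miRNA) membership."""
    rows = []
    for fam in families:
        for mature, hairpin in zip(fam.matures, fam.hairpins):
            rows.append(
                {
                    "mature_mirna": mature,
                    "pre_mirna": hairpin,
                    "seed": fam.seed,
                    "family": fam.name,
                }
            )
    df = pd.DataFrame(rows, columns=["mature_mirna", "pre_mirna", "seed", "family"])
    df.insert(0, "number", range(1, len(df) + 1))
    return df
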