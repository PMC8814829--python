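"""miRNA target prediction in 3′ UTRs: seed scan + duplex free energy.

Candidate sites are found by scanning each UTR for reverse complements
of the miRNA seed (mature positions 2–8, 1-based):

* ``7mer-m8`` — exact reverse complement of positions 2–8;
* ``8mer``    — the same with an ``A`` in the UTR opposite mature
  position 1 (the position immediately 3′ of the seed match in the UTR);
* ``7mer-A1`` — reverse complement of positions 2–7 with the ``A``
  opposite position 1.

Each candidate is extended by 15 nt upstream in the UTR (covering the
miRNA 3′-pairing region) and scored against the full mature sequence
with an intermolecular nearest-neighbor dynamic program over
Watson–Crick and G·U wobble stacks with bulge/internal-loop penalties
and a duplex-initiation term (no intramolecular structure, no target
accessibility).  Sites with duplex ΔG below a threshold (default
−20 kcal/mol) are retained; a gene is a predicted target of a miRNA iff
it has at least one retained site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import nn_params
from .readqc import _revcomp

__all__ = [
    "UTRRecord",
    "TargetSite",
    "TargetSummary",
    "find_seed_sites",
    "duplex_energy",
    "predict_targets",
    "summarize_targets",
]

_MAXLOOP = 10  # max unpaired bases per strand between consecutive pairs


@dataclass(frozen=True)
class UTRRecord:
    """A 3′ UTR sequence, keyed by gene and transcript identifiers."""

    gene: str
    transcript: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"UTR {self.transcript}: empty sequence")


@dataclass(frozen=True)
class TargetSite:
    """One predicted miRNA binding site on a UTR (1-based inclusive span)."""

    mirna: str
    gene: str
    transcript: str
    start: int
    end: int
    site_class: str  # 8mer | 7mer-m8 | 7mer-A1
    dg: float | None = None  # kcal/mol; None before energy scoring


def find_seed_sites(
    utr: UTRRecord, mirna: str, mature_sequence: str
) -> list[TargetSite]:
    """All seed-complementary sites of one mature miRNA in one UTR.

    Overlapping sites are all reported; a 7mer-A1 that is merely the
    inner part of an 8mer/7mer-m8 match at the same locus is not
    double-reported.
    """
    m = mature_sequence.upper().replace("U", "T")
    if len(m) < 8:
        raise ValueError(f"mature {mirna} shorter than 8 nt")
    u = utr.sequence.upper().replace("U", "T")
    rc7 = _revcomp(m[1:8])  # complement of positions 2-8
    rc6 = _revcomp(m[1:7])  # complement of positions 2-7
    comp_m8 = _revcomp(m[7])

    sites: list[TargetSite] = []
    # 7mer-m8 / 8mer scan
    p = u.find(rc7)
    while p >= 0:
        if p + 7 < len(u) and u[p + 7] == "A":
            sites.append(
                TargetSite(mirna, utr.gene, utr.transcript, p + 1, p + 8, "8mer")
            )
        else:
            sites.append(
                TargetSite(mirna, utr.gene, utr.transcript, p + 1, p + 7, "7mer-m8")
            )
        p = u.find(rc7, p + 1)
    # 7mer-A1 scan; skip loci already covered by an m8 match one base 5'
    p = u.find(rc6)
    while p >= 0:
        if p + 6 < len(u) and u[p + 6] == "A":
            part_of_m8 = p >= 1 and u[p - 1] == comp_m8
            if not part_of_m8:
                sites.append(
                    TargetSite(
                        mirna, utr.gene, utr.transcript, p + 1, p + 7, "7mer-A1"
                    )
                )
        p = u.find(rc6, p + 1)
    sites.sort(key=lambda s: (s.start, s.site_class))
    return sites


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def duplex_energy(
    seq1: str,
    seq2: str,
    stack: Mapping | None = None,
    initiation: float | None = None,
) -> float:
    """Hybridization free energy (kcal/mol) of an intermolecular duplex.

    ``seq1`` and ``seq2`` are the two strands, each written 5′→3′ and
    hybridized antiparallel.  Dynamic programming over nearest-neighbor
    stacks (Watson–Crick + G·U wobble) with bulge and internal-loop
    penalties; unpaired overhangs are free; no intramolecular structure.
    More negative is more stable.  If no base pair can form, only the
    initiation term is returned.
    """
    stack = stack if stack is not None else nn_params.STACK
    init = initiation if initiation is not None else nn_params.INITIATION
    a = _to_rna(seq1)
    b = _to_rna(seq2)[::-1]  # align antiparallel strand 5'->3' vs 3'->5'
    for name, s in (("seq1", a), ("seq2", b)):
        if not s:
            raise ValueError(f"{name} is empty")
        if len(s) > 40:
            raise ValueError(f"{name} longer than 40 nt ({len(s)})")
        if set(s) - {"A", "C", "G", "U"}:
            raise ValueError(f"{name} contains non-ACGT/U characters")

    INF = float("inf")
    n1, n2 = len(a), len(b)
    # H[i][j]: min energy of a duplex whose last pair is (a[i], b[j])
    H = [[INF] * n2 for _ in range(n1)]
    best = INF
    for i in range(n1):
        ai = a[i]
        for j in range(n2):
            if not nn_params.can_pair(ai, b[j]):
                continue
            e = 0.0  # open a new helix; 5' overhangs are free
            for pi in range(max(0, i - _MAXLOOP - 1), i):
                row = H[pi]
                gi = i - pi - 1
                for pj in range(max(0, j - _MAXLOOP - 1), j):
                    prev = row[pj]
                    if prev == INF:
                        continue
                    gj = j - pj - 1
                    if gi == 0 and gj == 0:
                        cost = stack[((a[pi], b[pj]), (ai, b[j]))]
                    elif gi == 0 or gj == 0:
                        cost = nn_params.bulge_penalty(gi + gj)
                    else:
                        cost = nn_params.internal_penalty(gi + gj)
                    if prev + cost < e:
                        e = prev + cost
            H[i][j] = e
            if e < best:
                best = e
    if best == INF:
        best = 0.0  # no pairing at all
    return best + init


def predict_targets(
    matures: Mapping[str, str] | Iterable[tuple[str, str]],
    utrs: Sequence[UTRRecord],
    dg_max: float = -20.0,
    upstream: int = 15,
) -> list[TargetSite]:
    """Seed-scan all (miRNA, UTR) pairs and retain sites with ΔG < dg_max.

    For each candidate seed site the UTR window is the site span plus
    ``upstream`` nt toward the UTR 5′ end (capped at the UTR boundary),
    scored against the full mature sequence.
    """
    if not isinstance(matures, Mapping):
        matures = dict(matures)
    retained: list[TargetSite] = []
    for mirna, mseq in matures.items():
        mseq = mseq.upper().replace("U", "T")
        for utr in utrs:
            for site in find_seed_sites(utr, mirna, mseq):
                lo = max(1, site.start - upstream)
                window = utr.sequence[lo - 1 : site.end]
                dg = duplex_energy(mseq, window)
                if dg < dg_max:
                    retained.append(
                        TargetSite(
                            mirna=site.mirna,
                            gene=site.gene,
                            transcript=site.transcript,
                            start=site.start,
                            end=site.end,
                            site_class=site.site_class,
                            dg=dg,
                        )
                    )
    return retained


@dataclass
class TargetSummary:
    """Gene-by-miRNA-count ranking and the miRNA-count histogram."""

    per_gene: pd.DataFrame  # gene, n_mirnas, mirnas (pipe-separated)
    per_mirna: pd.DataFrame  # mirna, n_genes
    histogram: pd.DataFrame  # n_mirnas, n_genes


def summarize_targets(predictions: Sequence[TargetSite]) -> TargetSummary:
    """Distinct (miRNA, gene) pairs tabulated per gene and per miRNA.

    Duplicate sites for the same pair count once.  The per-gene table is
    ranked by descending miRNA count (ties by gene id); the histogram
    bins genes by how many distinct miRNAs target them.
    """
    pairs = sorted({(p.mirna, p.gene) for p in predictions})
    by_gene: dict[str, list[str]] = {}
    by_mirna: dict[str, set[str]] = {}
    for mirna, gene in pairs:
        by_gene.setdefault(gene, []).append(mirna)
        by_mirna.setdefault(mirna, set()).add(gene)

    per_gene = pd.DataFrame(
        [
            {"gene": g, "n_mirnas": len(ms), "mirnas": " | ".join(sorted(ms))}
            for g, ms in by_gene.items()
        ],
        columns=["gene", "n_mirnas", "mirnas"],
    )
    if not per_gene.empty:
        per_gene = per_gene.sort_values(
            ["n_mirnas", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    per_mirna = pd.DataFrame(
        [{"mirna": m, "n_genes": len(gs)} for m, gs in sorted(by_mirna.items())],
        columns=["mirna", "n_genes"],
    )

    if per_gene.empty:
        histogram = pd.DataFrame(columns=["n_mirnas", "n_genes"])
    else:
        counts = per_gene["n_mirnas"].value_counts().sort_index()
        histogram = pd.DataFrame(
            {"n_mirnas": counts.index.to_numpy(), "n_genes": counts.to_numpy()}
        )
    return TargetSummary(per_gene=per_gene, per_mirna=per_mirna, histogram=histogram)
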