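"""Published reference values from a porcine milk exosome small-RNA study.

Small printed tables used as worked-example inputs: the six mature
miRNAs most strongly enriched in milk exosomes relative to whole milk
(sequence, printed length, raw counts, exact-test p-value and reported
fold ratio), and the locus strings of the four upregulated pre-miRNAs
that form the two genomic clusters (chromosomes 9 and X).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EnrichedMiRNA", "ENRICHED_MIRNAS", "CLUSTER_LOCI"]


@dataclass(frozen=True)
class EnrichedMiRNA:
    name: str
    sequence: str
    length: int
    milk_count: int
    exosome_count: int
    p_value: float
    ratio: float


ENRICHED_MIRNAS: tuple[EnrichedMiRNA, ...] = (
    EnrichedMiRNA("ssc-miR-193a-3p", "AACTGGCCTACAAAGTCCCAGT", 22, 75, 67154, 1.33e-32, 1467.35),
    EnrichedMiRNA("ssc-miR-423-5p", "TGAGGGGCAGAGAGCGAGACTTT", 23, 1302, 22588, 4.23e-16, 30.06),
    EnrichedMiRNA("ssc-miR-551a", "GCGACCCACTCTTGGTTTCC", 20, 11, 225, 3.75e-14, 25.43),
    EnrichedMiRNA("ssc-miR-138", "AGCTGGTGTTGTGAATCAGGC", 21, 1, 42, 1.90e-9, 13.95),
    EnrichedMiRNA("ssc-miR-1", "TGGAATGTAAAGAAGTATGTA", 21, 3, 58, 8.12e-11, 13.94),
    EnrichedMiRNA("ssc-miR-124a", "TAAGGCACGCGGTGAATGCCA", 21, 0, 33, 1.83e-8, 13.58),
)

# pre-miRNA genomic placements of the two reported exosome-upregulated clusters
CLUSTER_LOCI: tuple[str, ...] = (
    "ssc-mir-34c-1 (9_44166873_44166952_-)",
    "ssc-mir-34c-2 (9_44166877_44166950_-)",
    "ssc-mir-221 (X_45274873_45274942_-)",
    "ssc-mir-222 (X_45275613_45275692_-)",
)
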