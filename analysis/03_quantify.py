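#!/usr/bin/env python
"""Map clean reads to hairpins and count mature-miRNA expression.

Exact-match alignment to the hairpin set, then window counting
([x−2, y+5] around each annotated mature), yielding the raw count
matrix and a per-sample mapping census.
"""

from pathlib import Path

import pandas as pd

from exomir.io import read_fasta, read_fastq, read_mature_gff3
from exomir.quantify import CountMatrix, Hairpin, align_reads, count_mature, mapping_stats

DATA = Path("scratch/analysis/data")
CLEAN = Path("scratch/analysis/qc")
RESULTS = Path("results/analysis")


def main() -> None:
    data = DATA
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)

    hairpins = [Hairpin(n, s) for n, s in read_fasta(data / "hairpins.fasta")]
    matures = read_mature_gff3(data / "matures.gff3", hairpins)
    sheet = pd.read_csv(data / "samples.tsv", sep="\t")

    parts = []
    dropped = {}
    for sample in sheet["sample"]:
        reads = read_fastq(CLEAN / f"{sample}.clean.fastq")
        alignments, unaligned = align_reads((r.sequence for r in reads), hairpins)
        dropped[sample] = unaligned
        parts.append(count_mature(alignments, matures, sample=sample))
    cm = CountMatrix.concat(parts)

    cm.counts.rename_axis("mirna").to_csv(out / "counts.tsv", sep="\t")
    stats = mapping_stats(cm)
    stats.to_csv(out / "mapping_stats.tsv", sep="\t", index=False)

    print(f"{len(matures)} matures on {len(hairpins)} hairpins")
    print(stats.to_string(index=False))
    if any(dropped.values()):
        print("unaligned clean reads:", dropped)


if __name__ == "__main__":
    main()
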