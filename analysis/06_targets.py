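#!/usr/bin/env python
"""Predict 3' UTR targets of the upregulated miRNAs.

Seed-complementarity scan (8mer / 7mer-m8 / 7mer-A1) followed by
nearest-neighbor duplex free-energy scoring; sites below −20 kcal/mol
are retained and summarized as a gene-by-miRNA-count ranking and a
histogram of genes by how many miRNAs target them.
"""

from pathlib import Path

import pandas as pd

from exomir.io import read_fasta, read_mature_gff3
from exomir.quantify import Hairpin
from exomir.targets import UTRRecord, predict_targets, summarize_targets

DATA = Path("scratch/analysis/data")
RESULTS = Path("results/analysis")


def main() -> None:
    data = DATA
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)

    results = pd.read_csv(RESULTS / "de_results.tsv", sep="\t")
    up = set(results.loc[results.mark2 == "UP", "mirna"])
    hairpins = [Hairpin(n, s) for n, s in read_fasta(data / "hairpins.fasta")]
    matures = {
        m.name: m.sequence
        for m in read_mature_gff3(data / "matures.gff3", hairpins)
        if m.name in up
    }
    utrs = []
    for header, seq in read_fasta(data / "utrs.fasta"):
        gene, _, tx = header.partition("|")
        utrs.append(UTRRecord(gene=gene, transcript=tx or gene, sequence=seq))

    sites = predict_targets(matures, utrs, dg_max=-20.0)
    summary = summarize_targets(sites)

    pd.DataFrame(
        [
            {"mirna": s.mirna, "gene": s.gene, "transcript": s.transcript,
             "start": s.start, "end": s.end, "site_class": s.site_class,
             "dg_kcal_mol": round(s.dg, 2)}
            for s in sites
        ],
        columns=["mirna", "gene", "transcript", "start", "end", "site_class", "dg_kcal_mol"],
    ).to_csv(out / "target_sites.tsv", sep="\t", index=False)
    summary.per_gene.to_csv(out / "target_summary.tsv", sep="\t", index=False)
    summary.histogram.to_csv(out / "target_histogram.tsv", sep="\t", index=False)

    n_genes = len(summary.per_gene)
    print(f"{len(sites)} sites below -20 kcal/mol for {len(matures)} miRNAs; "
          f"{n_genes} target genes")
    if n_genes:
        print("top genes by distinct targeting miRNAs:")
        print(summary.per_gene.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
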