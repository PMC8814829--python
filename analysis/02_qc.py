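#!/usr/bin/env python
"""Clean every raw library: adapter, length, composition, contaminants.

Applies the filter cascade to each replicate FASTQ, writes the cleaned
reads and a per-sample accounting table, and reports how many reads each
filter removed.
"""

from pathlib import Path

import pandas as pd

from exomir.io import read_fasta, write_fastq
from exomir.readqc import ContaminantIndex, clean_library

DATA = Path("scratch/analysis/data")
CLEAN = Path("scratch/analysis/qc")  # cleaned FASTQs are bulky
RESULTS = Path("results/analysis")


def main() -> None:
    data = DATA
    CLEAN.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    sheet = pd.read_csv(data / "samples.tsv", sep="\t")
    import json

    manifest = json.loads((data / "manifest.json").read_text())
    index = ContaminantIndex(read_fasta(data / "contaminants.fasta"))

    rows = []
    for _, row in sheet.iterrows():
        reads, report = clean_library(
            data / row.fastq, adapter=manifest["adapter"], contaminants=index
        )
        write_fastq(CLEAN / f"{row['sample']}.clean.fastq", reads)
        rows.append({"sample": row["sample"], **report.to_dict()})
    qc = pd.DataFrame(rows)
    qc.to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False)

    removed = qc.filter(like="removed_").sum()
    total_in = int(qc.input_reads.sum())
    total_out = int(qc.surviving_reads.sum())
    print(f"{total_in} raw reads -> {total_out} clean "
          f"({100 * total_out / total_in:.1f} % survive)")
    for reason, n in removed[removed > 0].items():
        print(f"  {reason.removeprefix('removed_')}: {int(n)}")


if __name__ == "__main__":
    main()
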