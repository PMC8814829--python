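# exomir

Small-RNA sequencing analysis of **miRNA enrichment in milk exosomes
versus whole milk**, rebuilt as a tested, reusable pipeline with a
synthetic-data generator carrying known ground truth.

Milk exosomes selectively package miRNAs; comparing the small-RNA
content of exosomes against whole milk asks which mature miRNAs are
concentrated by that packaging. Answering it from raw reads takes five
steps, each implemented here as an importable module:

| stage | module | what it does |
| --- | --- | --- |
| read cleaning | `exomir.readqc` | 3′ adapter trimming, 18–34 nt length bounds, low-complexity composition filters (≥80 % one base, {A,C}-only, {G,T}-only, tandem di-/trinucleotide repeats, ambiguous bases), contaminant ncRNA subtraction — with exact per-filter accounting |
| quantification | `exomir.quantify` | exact-match alignment to pre-miRNA hairpins; a read spanning `[s, e]` counts toward a mature annotated at `[x, y]` iff `s ≥ x−2` and `e ≤ y+5` (the isomiR tolerance window) |
| differential abundance | `exomir.differential` | CPM normalization, pooled method-of-moments NB dispersion, a conditional exact test on condition sums (binomial split when φ = 0), pseudocounted fold ratios, and two-tier calls: **>2× at p < 0.05** = different, **>10×** = strongly different |
| annotation | `exomir.annotation` | genomic miRNA clusters by 10 kb single-linkage chaining; seed families by the 7-mer at mature positions 2–8 |
| target prediction | `exomir.targets` | seed-complementarity scan (8mer / 7mer-m8 / 7mer-A1) plus nearest-neighbor duplex free energy; sites kept below **−20 kcal/mol**, summarized as gene-by-miRNA-count rankings |

The exact test conditions on the total `s = A + B` of library-size-
scaled condition sums: under the null each condition sum is negative
binomial with mean ∝ replicate number and variance `μ + (φ/n)μ²`, and
the two-sided p sums the probabilities of all splits no more likely
than the observed one. The synthetic generator (`exomir.simulate`)
emulates the study design — 3 + 3 replicate libraries, log-normal
baselines, enrichment folds resampled from the six reported magnitudes
(13.58× to 1467.35×), 18–34 nt reads peaked at 22 nt, 3′ adapter, and
junk reads planted to trigger every cleaning filter — and records the
truth table every downstream check is audited against.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 17; 30 hairpins, 6 × 20 000-read libraries), writing tables
to `results/analysis/` and bulky intermediates to `scratch/`:

```bash
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/03_quantify.py
python analysis/04_differential.py
python analysis/05_annotate.py
python analysis/06_targets.py
```

The differential stage prints:

```
30 miRNAs tested (dispersion 0.0159)
6 upregulated >2x, 1 upregulated >10x (p < 0.05)
planted >2x proportion shifts: 6; recovered: 6; spurious: 0
     mirna      ratio      p_value mark2 mark10
syn-miR-14 541.747082 0.000000e+00    UP     UP
 syn-miR-1   4.682623 2.007848e-35    UP     NS
...
```

Every miRNA whose planted exosome-vs-milk proportion shift exceeds 2×
is recovered (6/6) with no spurious calls; `syn-miR-14`, planted with
an extreme enrichment fold, clears the 10× tier. Note the pipeline sees
*relative* abundance: the DOWN calls are unchanged miRNAs diluted by
the enriched ones — the compositional flip side of enrichment.
Annotation then finds the one genomic cluster planted among the
upregulated pre-miRNAs (the sub-10 kb pair) and six seed families, and
target prediction recovers the three perfect-complement UTR sites
planted for upregulated miRNAs (duplex ΔG ≈ −40 kcal/mol, well below
the −20 threshold):

```
1 genomic clusters (10 kb rule), 6 seed families
3 sites below -20 kcal/mol for 6 miRNAs; 3 target genes
```

The same pipeline is scriptable end-to-end (`exomir run --seed 17
--out run/`) or stage-by-stage (`exomir simulate|qc|quant|de|annotate|
targets`) on user-supplied FASTQ/FASTA/GFF3/BED inputs.

## Layout

```
src/exomir/        library: simulate, readqc, quantify, differential,
                   annotation, targets, nn_params, io, pipeline, cli
analysis/          numbered drivers reproducing the study on synthetic data
tests/             pytest suite incl. oracle and calibration checks
scripts/           acceptance.py (see above)
docs/methods.md    model, assumptions, parameter choices, limitations
results/           small output tables (regenerated by the drivers)
```
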