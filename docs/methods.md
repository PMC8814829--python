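# Methods

`exomir` re-implements, as a tested pipeline over synthetic data with
known ground truth, the computational analysis of a two-condition small
RNA sequencing experiment comparing milk **exosomes** against **whole
milk**: read cleaning, mature-miRNA quantification against pre-miRNA
hairpins, differential abundance with two-tier fold-change calls,
genomic cluster and seed-family annotation of the upregulated set, and
free-energy-thresholded target prediction in 3′ UTRs.

All sequences are handled in DNA alphabet (U→T on every ingest).
Hairpin-relative and genomic coordinates are 1-based inclusive in
memory; BED on disk is 0-based half-open, converted only in the I/O
layer.

## Read cleaning (`exomir.readqc`)

Raw reads pass a fixed cascade; a read is removed at the first failing
stage and the removal is attributed to that stage, so the accounting
identity `input = surviving + Σ removed` holds exactly.

1. **3′ adapter trimming.** The read is cut at the leftmost exact
   occurrence of an adapter prefix of length ≥ `min_overlap`
   (default 5, 0 mismatches). The quality string is truncated in
   lockstep. Reads reduced to nothing are `adapter_only`. No named
   trimming algorithm is prescribed for this protocol; exact
   prefix-matching with a 5 nt floor is the simplest rule that is fully
   oracle-testable.
2. **Length bounds.** < 18 nt → `too_short`; > 34 nt → `too_long`
   (the observed small-RNA length range, inclusive on both ends).
3. **Composition filters**, evaluated on the trimmed read:
   - `mono_composition`: any single base ≥ 80 % of the read
     (inclusive threshold, integer arithmetic — `5·count ≥ 4·len`);
   - `ac_only` / `gt_only`: alphabet ⊆ {A,C} or ⊆ {G,T};
   - `dimer_repeat` / `trimer_repeat`: the whole read is a tandem
     repeat of one 2-mer / 3-mer with at least two full units and at
     most one trailing partial unit. This reading of "continuous
     nucleotide dimers or trimers" matches standard low-complexity
     small-RNA filters; homopolymers are caught by the 80 % rule first;
   - `ambiguous_base`: any non-ACGT character.
   Flags are independent and may co-occur; attribution picks the first
   flag in a fixed priority order (mono, ac, gt, dimer, trimer,
   ambiguous). The cascade order itself (length before composition
   before contaminants) is a package choice, stated here because the
   underlying protocol does not fix one.
4. **Contaminant subtraction.** A read is `contaminant` iff it is an
   exact substring of any contaminant ncRNA (rRNA/tRNA/snRNA/repeat
   surrogates), on either strand. mRNA subtraction is folded into the
   user-supplied contaminant set.

## Quantification (`exomir.quantify`)

Clean reads are matched exactly (0 mismatches) as substrings of hairpin
sequences. Multi-mapping is resolved deterministically — lowest
lexicographic hairpin name, then leftmost position — so counts are
reproducible and invariant to read order; fractional assignment was
rejected for testability.

A mature miRNA is annotated as a span `[x, y]` on its hairpin. A read
aligned at `[s, e]` counts toward that mature iff `s ≥ x−2` and
`e ≤ y+5` — full containment of the read in the tolerance window
`[x−2, y+5]`. Containment (rather than a start-only rule) is chosen
because it makes the generator's 5′ offsets {−2..0} and 3′ offsets
{0..+5} reproduce the rule exactly, absorbing isomiR end heterogeneity
while excluding reads from elsewhere on the hairpin. A read eligible
for several matures on one hairpin goes to the mature with the smallest
`|s − x|`, ties to the lower `x`. Library size is the number of
hairpin-aligned reads; the census table reports per sample the number
of expressed pre-miRNAs and matures plus unique/total mapped reads.

## Differential abundance (`exomir.differential`)

Counts are normalized as CPM (counts per million hairpin-mapped reads).
Normalization is by library size only — no trimmed-mean scaling — the
simplest defensible choice for a two-condition design.

**Dispersion.** A single common negative-binomial dispersion φ
(variance μ + φμ²) is estimated by pooled method of moments on counts
rescaled to the geometric-mean library size: with within-condition
sample mean m over n replicates and sample variance v,
`E[v] = f·μ + φ·μ²` (f the mean rescaling factor) and
`E[m² − v/n] = μ²`, so

    φ̂ = max(0, Σ(v − f·m) / Σ(m² − v/n))

pooled over miRNAs and conditions. The denominator correction removes
the upward bias of m² as an estimator of μ² (≈ 8 % downward bias in φ̂
at n = 3 without it); a parameter-recovery simulation in the test suite
checks recovery of a planted φ.

**Exact test.** Replicate counts are rescaled to the common effective
library size and summed per condition. Conditional on the grand total
`s = A + B`, the null probability of a split `(s−k, k)` is proportional
to `NB(s−k; μ_a, φ/n_a) · NB(k; μ_b, φ/n_b)`, with means proportional
to the replicate numbers `n_a : n_b` (a sum of n i.i.d. NB(μ/n, φ)
variables is NB(μ, φ/n)). The two-sided p-value sums the probabilities
of all splits no more likely than the observed one; with φ = 0 this is
the exact binomial split test. p ∈ (0, 1] always; the observed split
being the mode returns exactly 1. The test is verified against
brute-force enumeration for every total s ≤ 200 at φ ∈ {0, 0.1, 0.5}.

**Fold change and calls.** Ratios are pseudocounted,
`ratio = (CPM_B + c) / (CPM_A + c)` with `c` the CPM equivalent of 0.5
reads at the smallest library, so zero counts give finite ratios.
Classification is two-tier at α = 0.05: `mark2` = UP/DOWN for ratio
beyond 2× (or below 1/2), `mark10` likewise at 10×; testing is
two-sided and marks are symmetric in direction. No multiple-testing
correction is applied, matching the analysis being reproduced. The
reported "ratio" in the original tables is not reconcilable with its
printed raw counts under any count- or CPM-based formula, so this
package defines its ratio explicitly as above and does not claim to
reproduce those ratio values from those counts.

## Annotation (`exomir.annotation`)

**Clusters.** Pre-miRNA genomic intervals are chained per chromosome by
single linkage: sort by start, link when `next.start − chain_end − 1 ≤
max_gap` (default 10 kb; overlaps count as gap 0). The gap is measured
end-to-start (not start-to-start) — "within 10 kb" is ambiguous, and
both published worked-example clusters (gaps 0 and 670 bp) satisfy the
end-to-start reading. Strand is ignored for linking and reported per
member; clusters need ≥ 2 members. Chaining provably equals the
transitive closure of the pairwise gap relation, and the test suite
checks that equality on random interval sets.

**Families.** The seed is mature positions 2–8 (1-based), a 7-mer — the
TargetScan convention. Matures partition by exact seed identity; family
names come from an optional seed→name table, otherwise `seed:<7-mer>`.

## Target prediction (`exomir.targets`)

No specific prediction tool is prescribed by the analysis being
reproduced — only the free-energy default of −20 kcal/mol — so the
package defines a transparent two-stage predictor:

1. **Seed scan.** UTRs are scanned for reverse complements of the seed:
   `7mer-m8` (complement of positions 2–8), `8mer` (the same plus an A
   opposite position 1, i.e. immediately 3′ of the match in the UTR),
   and `7mer-A1` (complement of 2–7 plus the A). Overlapping sites are
   all reported; a 7mer-A1 that is just the inner part of an m8 match at
   the same locus is not double-reported.
2. **Duplex scoring.** Each candidate site is extended 15 nt upstream in
   the UTR (covering the miRNA 3′-pairing region while keeping the DP
   small) and scored against the full mature sequence by intermolecular
   nearest-neighbor dynamic programming: Watson–Crick and G·U wobble
   stack free energies (ΔG°37, Turner-group values embedded as versioned
   configuration in `nn_params.py`), bulge and internal-loop penalties
   from a coarse size table, one duplex-initiation term, free overhangs,
   loops capped at 10 nt per strand, no intramolecular structure, no
   target accessibility, no conservation. The stack table is symmetric
   under reading the duplex from the other end, making the energy
   invariant under strand exchange (asserted at import and in tests).
   Terminal AU/GU end penalties are omitted: for the short, stack-
   dominated duplexes scored here they shift ΔG by well under the
   ~18 kcal/mol margin between a perfect ~22-mer duplex (≈ −40) and the
   −20 threshold.

Sites with ΔG < −20 kcal/mol are retained; a gene is a target of a
miRNA iff ≥ 1 retained site (per transcript, summarized per gene by
union). Summaries report per-gene distinct-miRNA counts (ranked), per-
miRNA distinct-gene counts, and the histogram of genes by miRNA count.
A perfect-complement planted site scores ≈ −40 kcal/mol and passes the
threshold; a seed-only match with non-pairing flanks scores ≈ −8 and is
rejected — both are asserted by computation in the tests, not assumed.

## Synthetic data (`exomir.simulate`)

The generator defines the study conditions; everything downstream is
validated against its recorded truth.

- **Reference.** `make_reference(n_hairpins, n_utrs, seed)` builds
  random hairpins of 60–120 nt, each embedding one mature of 18–24 nt
  placed so the whole window `[x−2, y+5]` stays inside the hairpin.
  Mature lengths cycle a fixed pattern with 40 % 22-mers at every
  reference size — a deterministic composition, because an i.i.d. draw
  can miss its own mode at small n and the 22 nt peak is a contract.
  Hairpins 1–2 form a sub-10 kb genomic pair, hairpin 3 is isolated,
  the rest are spaced ≥ 12 kb so only the designated pair clusters.
  UTRs (200–2000 nt) carry planted perfect-complement sites for the
  first three matures; four contaminant surrogates (rRNA/tRNA/snRNA/
  repeat) are generated free of any mature window.
- **Truth.** Baseline abundances are log-normal (σ = 1.2), normalized.
  About 1/6 of miRNAs are strongly enriched in the exosome condition
  with folds resampled from the six reported enrichment magnitudes
  {1467.35, 30.06, 25.43, 13.95, 13.94, 13.58} — the printed multiset,
  five modest values and one extreme, rather than a log-uniform over
  the range, which would overweight the extreme and distort library
  composition; ~1/12 are mildly enriched (2–10×, log-uniform). The
  enriched set is anchored on matures 1–3 (the genomic pair plus the
  planted-target mature) so the annotation and target stages see
  non-trivial upregulated input; enriched miRNAs draw their baselines
  from the low tail and the largest fold pairs with the smallest
  baseline, mirroring the observed pattern (the ~1467× species was
  rare in whole milk) and bounding the compositional shift of the
  enriched library.
- **Libraries.** Per replicate (default 3 per condition), per-miRNA
  expected proportions are baseline × fold (enriched condition),
  perturbed by replicate-level gamma factors (mean 1, variance φ,
  default dispersion 0.05 — no noise model is prescribed by the
  original design, which has only 3 replicates per condition) and
  drawn multinomially at the configured depth. Genuine reads take 5′
  offsets in {−2..0} and 3′ offsets in {0..+5} around `[x, y]`, peaked
  at the annotated ends so the read-length mode is 22 nt; a
  configurable straggler fraction (default 2 %) falls outside the
  window to test exclusion. Each read gets the 3′ adapter appended and
  is truncated to the 36-cycle instrument length; qualities are
  constant 'I' (Phred 40), since no filter uses them. Junk reads are
  planted per class (defaults ~10 % of depth in total) such that each
  triggers exactly its own filter; the adapter's first five bases are
  excluded by construction from hairpins, contaminants and junk
  inserts so trimming is exact and truth labels survive the cascade.
  Read identifiers carry truth labels (`mir=`, `straggler=`, `junk=`).
  Output is byte-deterministic for fixed (reference, truth, seed);
  default per-replicate depth is 10⁵ (a desk-scale stand-in for the
  ~10⁷-read libraries of a real run).

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: sequencing errors and quality decay,
PCR duplication bias, adapter dimers with partial-degradation variants,
genuinely multi-mapping miRNA paralogs, novel-miRNA loci, and real
contaminant taxonomies. Exact-substring alignment and trimming are
adequate for this error-free regime; real libraries need
mismatch-tolerant tools.

## Problem sizes used in validation

The statistical checks run at 2000 miRNAs, 3 vs 3 replicates, φ = 0.1:
a null arm (all folds 1; type-I fraction at α = 0.05 expected in
[0.03, 0.07]) and a power arm planting the six reported (milk CPM,
fold) pairs at their observed prevalence (6 strong per 326 miRNAs,
scaled), requiring ≥ 90 % `mark10 = UP` among planted folds ≥ 10 with
baseline CPM ≥ 50. The end-to-end round trip simulates 10⁵ reads per
replicate (dispersion 0 so expectations are binomial), cleans,
quantifies, and requires every per-miRNA count within 4 binomial SE of
truth and every planted junk read removed under its planted reason.
Oracle-equivalence suites cover all exact-test totals ≤ 200, 1000
random window configurations, 500-interval clustering, and exhaustive
seed-site scans.

## Known limitations

- The common-dispersion model has no tagwise shrinkage; genes with
  outlying dispersion are tested at the pooled φ.
- Library-size normalization is compositional: strong enrichment of
  abundant species deflates the apparent ratios of everything else
  (visible in the analysis drivers as DOWN calls for unchanged miRNAs).
  This is inherent to relative-abundance data, not an artifact.
- The duplex energy model is a minimal nearest-neighbor DP; it is not
  ViennaRNA/RNAhybrid and its ΔG values should not be compared to
  theirs beyond the threshold's order of magnitude.
- Exact-substring matching (alignment, contaminants) is by design for
  the error-free synthetic regime.
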