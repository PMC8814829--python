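"""Synthetic reference and library generator: contracts and round trips."""

import collections
from pathlib import Path

import numpy as np
import pytest

from exomir.io import read_fastq
from exomir.quantify import align_reads, validate_mature
from exomir.readqc import REASONS, ContaminantIndex, clean_reads, composition_flags, trim_adapter
from exomir.simulate import (
    ADAPTER,
    EnrichmentTruth,
    default_truth,
    make_reference,
    simulate_libraries,
)


class TestMakeReference:
    def test_minimal_reference(self):
        ref = make_reference(1, 1, seed=7)
        assert len(ref.hairpins) == 1 and len(ref.matures) == 1
        m, h = ref.matures[0], ref.hairpins[0]
        validate_mature(m, h)
        assert 60 <= len(h.sequence) <= 120
        assert 18 <= len(m.sequence) <= 24

    def test_deterministic_for_fixed_seed(self):
        a = make_reference(50, 20, seed=1)
        b = make_reference(50, 20, seed=1)
        assert a == b
        assert a != make_reference(50, 20, seed=2)

    def test_contains_sub10kb_pair_and_isolated_hairpin(self):
        ref = make_reference(10, 5, seed=3)
        ivs = [h.genomic for h in ref.hairpins]
        # exhaustive pairwise distance scan
        gaps = {}
        for i, a in enumerate(ivs):
            for j, b in enumerate(ivs):
                if i >= j or a.chrom != b.chrom:
                    continue
                lo, hi = (a, b) if a.start <= b.start else (b, a)
                gaps[(i, j)] = max(0, hi.start - lo.end - 1)
        assert any(g < 10_000 for g in gaps.values())
        # at least one hairpin with no neighbour within 10 kb
        close = {k for pair, g in gaps.items() if g < 10_000 for k in pair}
        assert len(close) < len(ivs)

    def test_planted_utr_sites_for_three_matures(self):
        ref = make_reference(10, 5, seed=3)
        rc = str.maketrans("ACGT", "TGCA")
        planted = sum(
            any(m.sequence.translate(rc)[::-1] in u.sequence for u in ref.utrs)
            for m in ref.matures
        )
        assert planted >= 3

    def test_adapter_prefix_excluded_from_references(self):
        ref = make_reference(8, 4, seed=5)
        for h in ref.hairpins:
            assert ADAPTER[:5] not in h.sequence
        for _, seq in ref.contaminants:
            assert ADAPTER[:5] not in seq

    @pytest.mark.parametrize("n_h,n_u", [(0, 1), (1, 0), (-2, 3)])
    def test_non_positive_counts_rejected(self, n_h, n_u):
        with pytest.raises(ValueError):
            make_reference(n_h, n_u, seed=1)


class TestSimulateLibraries:
    def test_zero_depth_gives_empty_files(self, small_ref, tmp_path):
        truth = default_truth(small_ref, seed=1, depth=0)
        manifest = simulate_libraries(small_ref, truth, tmp_path)
        assert len(manifest["samples"]) == 6
        for info in manifest["samples"].values():
            assert list(read_fastq(info["fastq"])) == []

    def test_byte_identical_under_fixed_seed(self, small_ref, tmp_path):
        truth = default_truth(small_ref, seed=4, depth=1500)
        m1 = simulate_libraries(small_ref, truth, tmp_path / "a")
        m2 = simulate_libraries(small_ref, truth, tmp_path / "b")
        for s in m1["samples"]:
            a = Path(m1["samples"][s]["fastq"]).read_bytes()
            b = Path(m2["samples"][s]["fastq"]).read_bytes()
            assert a == b

    def test_read_conservation(self, small_sim):
        truth, manifest = small_sim
        for info in manifest["samples"].values():
            assert sum(1 for _ in read_fastq(info["fastq"])) == truth.depth

    def test_mismatched_truth_rejected(self, small_ref, tmp_path):
        truth = EnrichmentTruth(
            baseline={"ghost": 1.0}, fold_change={"ghost": 1.0}, depth=10
        )
        with pytest.raises(ValueError):
            simulate_libraries(small_ref, truth, tmp_path)


@pytest.fixture(scope="module")
def flat_sim(small_ref, tmp_path_factory):
    """Fold 1 everywhere, dispersion 0: both conditions share expectations."""
    truth = default_truth(
        small_ref, seed=6, depth=100_000, n_replicates=1,
        dispersion=0.0, straggler_fraction=0.0,
    )
    truth.fold_change = {k: 1.0 for k in truth.fold_change}
    out = tmp_path_factory.mktemp("flat")
    return truth, simulate_libraries(small_ref, truth, out)


class TestFlatTruthProportions:

    def test_conditions_agree_within_three_binomial_se(self, flat_sim):
        truth, manifest = flat_sim
        n_genuine = manifest["n_genuine_per_library"]
        observed = {}
        for sample, info in manifest["samples"].items():
            counter = collections.Counter()
            for read in read_fastq(info["fastq"]):
                label = read.id.split("|", 1)[1]
                if label.startswith("mir="):
                    counter[label.split(";")[0][4:]] += 1
            observed[info["condition"]] = counter
        for name, p in truth.baseline.items():
            se = np.sqrt(n_genuine * p * (1 - p))
            a = observed["milk"][name]
            b = observed["exosome"][name]
            assert abs(a - n_genuine * p) <= 3 * se + 1
            assert abs(b - n_genuine * p) <= 3 * se + 1

    def test_genuine_read_length_mode_is_22(self, flat_sim):
        _, manifest = flat_sim
        lengths = collections.Counter()
        info = next(iter(manifest["samples"].values()))
        for read in read_fastq(info["fastq"]):
            if "mir=" in read.id:
                trimmed = trim_adapter(read, ADAPTER)
                lengths[len(trimmed.sequence)] += 1
        assert lengths.most_common(1)[0][0] == 22
        assert min(lengths) >= 18 and max(lengths) <= 34


class TestCrossModuleRoundTrip:
    def test_every_junk_class_fails_its_planted_filter(self, small_ref, small_sim):
        truth, manifest = small_sim
        index = ContaminantIndex(small_ref.contaminants)
        info = manifest["samples"]["E-1"]
        reads = list(read_fastq(info["fastq"]))
        planted = collections.Counter(
            r.id.split("junk=")[1] for r in reads if "junk=" in r.id
        )
        assert set(planted) == set(truth.junk_fractions)
        _, report = clean_reads(reads, truth.adapter, index)
        for cls, n in planted.items():
            assert report.removed[cls] == n, cls
        assert sum(planted.values()) == sum(report.removed.values())

    def test_cleaned_genuine_reads_map_inside_their_window(self, small_ref, small_sim):
        truth, manifest = small_sim
        index = ContaminantIndex(small_ref.contaminants)
        mature_by_name = {m.name: m for m in small_ref.matures}
        info = manifest["samples"]["R-1"]
        clean, _ = clean_reads(read_fastq(info["fastq"]), truth.adapter, index)
        genuine = [r for r in clean if "mir=" in r.id]
        assert genuine, "expected genuine reads to survive QC"
        aligns, unaligned = align_reads((r.sequence for r in genuine), small_ref.hairpins)
        assert unaligned == 0
        span_by_seq = {a.sequence: a for a in aligns}
        for read in genuine:
            name = read.id.split("mir=")[1].split(";")[0]
            m = mature_by_name[name]
            a = span_by_seq[read.sequence]
            assert a.hairpin == m.hairpin
            assert a.start >= m.x - 2 and a.end <= m.y + 5

    def test_straggler_reads_align_but_fall_outside_window(self, small_ref, small_sim):
        truth, manifest = small_sim
        index = ContaminantIndex(small_ref.contaminants)
        mature_by_name = {m.name: m for m in small_ref.matures}
        info = manifest["samples"]["R-1"]
        clean, _ = clean_reads(read_fastq(info["fastq"]), truth.adapter, index)
        stragglers = [r for r in clean if "straggler=" in r.id]
        assert stragglers, "straggler fraction > 0 should yield stragglers"
        aligns, unaligned = align_reads((r.sequence for r in stragglers), small_ref.hairpins)
        assert unaligned == 0
        span_by_seq = {a.sequence: a for a in aligns}
        for read in stragglers:
            name = read.id.split("straggler=")[1]
            m = mature_by_name[name]
            a = span_by_seq[read.sequence]
            assert a.start < m.x - 2 or a.end > m.y + 5

    def test_junk_inserts_carry_single_planted_flag(self, small_ref):
        # spot-check composition junk against the filter definitions
        from exomir.simulate import _junk_insert

        rng = np.random.default_rng(9)
        for cls in (
            "mono_composition", "ac_only", "gt_only",
            "dimer_repeat", "trimer_repeat", "ambiguous_base",
        ):
            for _ in range(20):
                seq = _junk_insert(
                    rng, cls, small_ref.contaminants, small_ref.hairpins, ADAPTER[:5]
                )
                assert composition_flags(seq) == {cls}
                assert cls in REASONS
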