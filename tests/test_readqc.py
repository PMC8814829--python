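"""Read-cleaning cascade: trimming, composition filters, accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomir.datasets import ENRICHED_MIRNAS
from exomir.io import ReadRecord
from exomir.readqc import (
    ContaminantIndex,
    clean_reads,
    composition_flags,
    contaminant_filter,
    length_filter,
    trim_adapter,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _read(seq, id="r"):
    return ReadRecord(id=id, sequence=seq, quality="I" * len(seq))


class TestTrimAdapter:
    def test_full_prefix_suffix_removed(self):
        r = trim_adapter(_read("ACGTACGT" + "TGGAATTC"), "TGGAATTCTCGG")
        assert r.sequence == "ACGTACGT"
        assert r.quality == "I" * 8

    def test_no_occurrence_is_noop(self):
        r = _read("ACGTACGTACGTACGTAC")
        assert trim_adapter(r, ADAPTER).sequence == r.sequence

    def test_adapter_shorter_than_overlap_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter(_read("ACGTACGT"), "ACGT", min_overlap=5)

    def test_matches_bruteforce_scan_on_random_reads(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))

        def oracle(seq, adapter, k_min=5):
            # leftmost i where the read suffix starts with an adapter
            # prefix of length >= k_min (or runs off the read end)
            for i in range(len(seq)):
                k = min(len(adapter), len(seq) - i)
                if k >= k_min and seq.startswith(adapter[:k], i):
                    return seq[:i]
            return seq

        for _ in range(1000):
            insert = "".join(rng.choice(bases, size=int(rng.integers(0, 30))))
            if rng.random() < 0.8:
                raw = (insert + ADAPTER)[: int(rng.integers(10, 40))]
            else:
                raw = "".join(rng.choice(bases, size=int(rng.integers(5, 40))))
            got = trim_adapter(_read(raw), ADAPTER).sequence
            assert got == oracle(raw, ADAPTER)


class TestCompositionFlags:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAAAAAAAAAAAAGGGC", {"mono_composition"}),  # 16/20 = 80 %
            ("AAAAAAAAAAAAAAAGGGGC", set()),  # 15/20 = 75 %
            ("ACACACACACACACACACAC", {"ac_only", "dimer_repeat"}),
            ("GTGTGTGTGTGTGTGTGT", {"gt_only", "dimer_repeat"}),
            ("AGTAGTAGTAGTAGTAGTAG", {"trimer_repeat"}),  # trailing partial unit
            ("ACGTACGTNACGTACGTA", {"ambiguous_base"}),
        ],
    )
    def test_flag_definitions(self, seq, expected):
        assert composition_flags(seq) == expected

    def test_quantified_mirna_sequences_pass(self):
        # sequences that were counted in the study must survive filtering
        for m in ENRICHED_MIRNAS:
            assert composition_flags(m.sequence) == set()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_flags("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_matches_naive_predicates(self, seq):
        flags = composition_flags(seq)
        n = len(seq)
        assert ("mono_composition" in flags) == any(
            seq.count(b) / n >= 0.8 for b in "ACGT"
        )
        assert ("ac_only" in flags) == (set(seq) <= {"A", "C"})
        assert ("gt_only" in flags) == (set(seq) <= {"G", "T"})
        for unit_len, flag in ((2, "dimer_repeat"), (3, "trimer_repeat")):
            tandem = n >= 2 * unit_len and all(
                seq[i] == seq[i % unit_len] for i in range(n)
            )
            assert (flag in flags) == tandem


class TestLengthFilter:
    @pytest.mark.parametrize(
        "n,verdict",
        [(17, "too_short"), (18, "keep"), (34, "keep"), (35, "too_long")],
    )
    def test_boundaries(self, n, verdict):
        assert length_filter("A" * n) == verdict


class TestContaminantFilter:
    def test_fragment_of_contaminant_is_flagged_both_strands(self):
        rng = np.random.default_rng(7)
        contaminant = "".join(rng.choice(list("ACGT"), size=200))
        index = ContaminantIndex([("rRNA", contaminant)])
        frag = contaminant[50:72]
        rc = frag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert contaminant_filter(frag, index) == "contaminant"
        assert contaminant_filter(rc, index) == "contaminant"

    def test_absent_read_passes_vs_naive_scan(self):
        rng = np.random.default_rng(8)
        contams = [
            (f"c{i}", "".join(rng.choice(list("ACGT"), size=300))) for i in range(3)
        ]
        index = ContaminantIndex(contams)
        rc_tab = str.maketrans("ACGT", "TGCA")
        for _ in range(200):
            read = "".join(rng.choice(list("ACGT"), size=22))
            naive = any(
                read in seq or read in seq.translate(rc_tab)[::-1]
                for _, seq in contams
            )
            assert (contaminant_filter(read, index) == "contaminant") == naive

    def test_empty_contaminant_set_is_vacuous(self):
        index = ContaminantIndex([])
        assert contaminant_filter("ACGTACGTACGTACGTACGTAC", index) == "pass"


def _random_library(rng, n):
    reads = []
    bases = np.array(list("ACGTN"))
    for i in range(n):
        length = int(rng.integers(1, 45))
        p = [0.24, 0.24, 0.24, 0.24, 0.04]
        seq = "".join(rng.choice(bases, size=length, p=p))
        if rng.random() < 0.3:
            seq = (seq + ADAPTER)[:36]
        reads.append(_read(seq, id=f"r{i}"))
    return reads


class TestCleanReads:
    def test_accounting_identity_on_random_libraries(self):
        rng = np.random.default_rng(12)
        contams = [("c", "".join(rng.choice(list("ACGT"), size=400)))]
        for trial in range(5):
            reads = _random_library(rng, 300)
            clean, report = clean_reads(reads, ADAPTER, ContaminantIndex(contams))
            assert report.input_reads == 300
            assert report.input_reads == report.surviving_reads + sum(
                report.removed.values()
            )
            assert len(clean) == report.surviving_reads

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(13)
        reads = _random_library(rng, 400)
        clean, _ = clean_reads(reads, ADAPTER)
        again, report = clean_reads(clean, ADAPTER)
        assert [r.sequence for r in again] == [r.sequence for r in clean]
        assert report.surviving_reads == report.input_reads

    def test_report_invariant_to_read_order(self):
        rng = np.random.default_rng(14)
        reads = _random_library(rng, 300)
        _, report_a = clean_reads(reads, ADAPTER)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        _, report_b = clean_reads(shuffled, ADAPTER)
        assert report_a.to_dict() == report_b.to_dict()

    def test_valid_isomir_library_fully_survives(self):
        rng = np.random.default_rng(15)
        reads = []
        while len(reads) < 100:
            seq = "".join(rng.choice(list("ACGT"), size=22))
            if not composition_flags(seq) and "TGGAA" not in seq:
                reads.append(_read(seq))
        _, report = clean_reads(reads, ADAPTER)
        assert report.surviving_reads == report.input_reads == 100

    def test_empty_library(self):
        clean, report = clean_reads([], ADAPTER)
        assert clean == [] and report.input_reads == 0
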