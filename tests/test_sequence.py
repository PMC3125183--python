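"""Sequence I/O, windowing and composition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpsorl import (
    GGF,
    TJ,
    CriteriaSet,
    GenomeSequence,
    Interval,
    NucleotideCounts,
    count_nucleotides,
    gc_content,
    mask_intervals,
    meets_criteria,
    oe_ratio,
    partition_windows,
    read_fasta,
)
from cpsorl.sequence import (
    CoordinateError,
    FormatError,
    SequenceProfile,
    UndefinedStatistic,
    normalize_residues,
)
from conftest import seq_of

dna = st.text(alphabet="ACGT", min_size=2, max_size=400)
dna_with_n = st.text(alphabet="ACGTN", min_size=2, max_size=400)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.name == "x" and rec.length == 4

    def test_case_fold_and_line_join(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nacgt\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "ACGTACGT"

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nACRT\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "ACNT"

    def test_multi_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n>b\nGGCC\n")
        recs = read_fasta(p)
        assert [r.name for r in recs] == ["a", "b"]

    @pytest.mark.parametrize("content", ["", "ACGT\n"])
    def test_malformed_input_names_line(self, tmp_path, content):
        p = tmp_path / "bad.fa"
        p.write_text(content)
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)


def test_normalize_residues():
    assert normalize_residues("acgtRyN-x") == "ACGTNNNNN"


class TestPartitionWindows:
    def test_step_arithmetic(self):
        seq = seq_of("A" * 25000)
        windows = partition_windows(seq, 10000, 2000)
        assert [w.start for w in windows] == [0, 8000, 16000]
        assert windows[-1] == Interval(16000, 25000)

    def test_short_sequence_single_window(self):
        assert partition_windows(seq_of("A" * 5000), 10000, 2000) == [Interval(0, 5000)]

    def test_zero_overlap_exact_tiling(self):
        windows = partition_windows(seq_of("A" * 2000), 1000, 0)
        assert windows == [Interval(0, 1000), Interval(1000, 2000)]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            partition_windows(seq_of("ACGT"), 2, 2)

    @given(L=st.integers(1, 5000), window=st.integers(2, 1000), overlap=st.integers(0, 999))
    @settings(max_examples=60, deadline=None)
    def test_every_base_covered(self, L, window, overlap):
        if overlap >= window:
            overlap = window - 1
        windows = partition_windows(seq_of("A" * L), window, overlap)
        covered = np.zeros(L, dtype=bool)
        for w in windows:
            assert 0 <= w.start < w.end <= L
            covered[w.start : w.end] = True
        assert covered.all()


class TestCounts:
    def test_cg_repeat(self):
        c = count_nucleotides(seq_of("CGCGCG"), Interval(0, 6))
        assert (c.nC, c.nG, c.nCpG, c.N) == (3, 3, 3, 6)

    def test_homopolymer(self):
        c = count_nucleotides(seq_of("AAAA"), Interval(0, 4))
        assert c.nA == 4 and c.nCpG == 0

    def test_n_breaks_dimer(self):
        c = count_nucleotides(seq_of("CNG"), Interval(0, 3))
        assert (c.nC, c.nG, c.nCpG, c.N) == (1, 1, 0, 2)

    def test_out_of_bounds(self):
        with pytest.raises(CoordinateError):
            count_nucleotides(seq_of("ACGT"), Interval(0, 5))

    @given(s=dna_with_n, cut=st.integers(1, 399))
    @settings(max_examples=80, deadline=None)
    def test_additive_over_partition(self, s, cut):
        if cut >= len(s):
            cut = len(s) - 1
        seq = seq_of(s)
        whole = count_nucleotides(seq, Interval(0, len(s)))
        left = count_nucleotides(seq, Interval(0, cut))
        right = count_nucleotides(seq, Interval(cut, len(s)))
        for base in "ATCG":
            attr = f"n{base}"
            assert getattr(whole, attr) == getattr(left, attr) + getattr(right, attr)
        # a CpG dimer split by the cut is counted by the whole only
        assert whole.nCpG >= left.nCpG + right.nCpG
        assert whole.nCpG - (left.nCpG + right.nCpG) <= 1


class TestCompositionStatistics:
    @pytest.mark.parametrize(
        "s,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)]
    )
    def test_gc_content(self, s, expected):
        assert gc_content(count_nucleotides(seq_of(s), Interval(0, len(s)))) == expected

    @pytest.mark.parametrize(
        "s,expected", [("CGCGCG", 2.0), ("CCGG", 1.0), ("AATT", 0.0)]
    )
    def test_oe_ratio_hand_counted(self, s, expected):
        assert oe_ratio(count_nucleotides(seq_of(s), Interval(0, len(s)))) == expected

    def test_all_n_interval_is_undefined(self):
        c = count_nucleotides(seq_of("NNNN"), Interval(0, 4))
        with pytest.raises(UndefinedStatistic):
            gc_content(c)
        with pytest.raises(UndefinedStatistic):
            oe_ratio(c)

    @given(s=dna)
    @settings(max_examples=80, deadline=None)
    def test_oe_invariant_under_reverse_complement(self, s):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp[b] for b in reversed(s))
        c1 = count_nucleotides(seq_of(s), Interval(0, len(s)))
        c2 = count_nucleotides(seq_of(rc), Interval(0, len(rc)))
        assert oe_ratio(c1) == pytest.approx(oe_ratio(c2))


class TestCriteria:
    def test_ggf_boundary_inclusive(self):
        # gc exactly 0.50, O/E exactly 0.60, length exactly 200+: all pass
        c = NucleotideCounts(nA=60, nT=60, nC=60, nG=60, nCpG=9)
        assert gc_content(c) == 0.5 and oe_ratio(c) == pytest.approx(0.6)
        assert meets_criteria(Interval(0, 240), c, GGF)
        # one CpG fewer drops O/E below threshold
        c2 = NucleotideCounts(nA=60, nT=60, nC=60, nG=60, nCpG=8)
        assert not meets_criteria(Interval(0, 240), c2, GGF)

    def test_length_below_minimum_fails(self):
        seq = seq_of("CGAT" * 50)  # rich in everything but only 199 bp used
        c = count_nucleotides(seq, Interval(0, 199))
        assert not meets_criteria(Interval(0, 199), c, GGF)
        c200 = count_nucleotides(seq, Interval(0, 200))
        assert meets_criteria(Interval(0, 200), c200, GGF)

    def test_tj_boundary_inclusive(self):
        # length 500 with gc 0.55 and O/E >= 0.65 passes TJ
        c = NucleotideCounts(nA=90, nT=90, nC=110, nG=110, nCpG=40)
        assert gc_content(c) == pytest.approx(0.55)
        assert oe_ratio(c) >= 0.65
        assert meets_criteria(Interval(0, 500), c, TJ)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            CriteriaSet(min_length=0, min_gc=0.5, min_oe=0.6)


class TestMasking:
    def test_basic_mask(self):
        assert mask_intervals(seq_of("CGCGAA"), [Interval(0, 4)]).residues == "NNNNAA"

    def test_empty_mask_is_identity(self):
        seq = seq_of("CGCGAA")
        assert mask_intervals(seq, []) is seq

    def test_overlapping_masks_equal_union(self):
        seq = seq_of("ACGTACGTAC")
        a = mask_intervals(seq, [Interval(1, 5), Interval(3, 8)])
        b = mask_intervals(seq, [Interval(1, 8)])
        assert a.residues == b.residues

    def test_out_of_bounds_mask(self):
        with pytest.raises(CoordinateError):
            mask_intervals(seq_of("ACGT"), [Interval(2, 9)])

    @given(s=dna, lo=st.integers(0, 300), hi=st.integers(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_mask_then_count_equals_deletion(self, s, lo, hi):
        lo, hi = sorted((lo % len(s), 1 + hi % len(s)))
        if lo == hi:
            hi = min(hi + 1, len(s))
        if lo >= hi:
            return
        seq = seq_of(s)
        masked = mask_intervals(seq, [Interval(lo, hi)])
        cm = count_nucleotides(masked, Interval(0, len(s)))
        # deletion oracle: count on the two retained flanks separately
        cl = count_nucleotides(seq, Interval(0, lo)) if lo else None
        cr = count_nucleotides(seq, Interval(hi, len(s))) if hi < len(s) else None
        for base in "ATCG":
            attr = f"n{base}"
            expect = (getattr(cl, attr) if cl else 0) + (getattr(cr, attr) if cr else 0)
            assert getattr(cm, attr) == expect


class TestSequenceProfile:
    @given(s=dna_with_n, a=st.integers(0, 399), b=st.integers(1, 400))
    @settings(max_examples=100, deadline=None)
    def test_profile_matches_direct_counts(self, s, a, b):
        a, b = sorted((a % len(s), 1 + b % len(s)))
        if a == b:
            return
        seq = seq_of(s)
        profile = SequenceProfile(seq)
        n_c, n_g, n_valid, n_cpg = profile.counts(Interval(a, b))
        direct = count_nucleotides(seq, Interval(a, b))
        assert (n_c, n_g, n_valid, n_cpg) == (
            direct.nC, direct.nG, direct.N, direct.nCpG,
        )
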