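"""Reverse-complement duplex finding: examples, oracle, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexsig import (
    AlignmentParameters,
    ReadCollection,
    SmallRNARead,
    brute_force_duplexes,
    find_duplexes,
    reverse_complement,
)
from tests.conftest import random_collection

seq_strategy = st.text(alphabet="ACGTN", min_size=1, max_size=40)


def coll(*reads, label=""):
    return ReadCollection(list(reads), source_label=label)


def as_multiset(duplexes):
    return sorted(
        (d.ref_id, d.query_id, d.align_start, d.align_len, d.ref_ext5, d.ref_ext3, d.q_ext5, d.q_ext3)
        for d in duplexes
    )


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("N", "N"), ("ATGCN", "NGCAT")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestFindDuplexes:
    def test_exact_full_length_duplex(self):
        ref = SmallRNARead("ref", "ACGTACGTACGTACGTACGTA")
        query = SmallRNARead("q", reverse_complement(ref.sequence))
        out = find_duplexes(coll(ref), coll(query))
        assert len(out) == 1
        d = out[0]
        assert d.align_len == 21
        assert (d.ref_ext5, d.ref_ext3, d.q_ext5, d.q_ext3) == (0, 0, 0, 0)

    def test_internal_placement_with_reference_overhangs(self):
        # 26-nt reference without internal repeats; the 19-nt passenger is
        # the reverse complement of bases 4..22, leaving a 4-nt 5' and
        # 3-nt 3' reference overhang.  Brute force confirms uniqueness.
        ref = SmallRNARead("ref", "ACGGTCATTGCAAGCTTCCGAGTGAC")
        query = SmallRNARead("q", reverse_complement(ref.sequence[4:23]))
        params = AlignmentParameters(min_overlap=19)
        out = find_duplexes(coll(ref), coll(query), params)
        assert as_multiset(out) == as_multiset(
            brute_force_duplexes(coll(ref), coll(query), params)
        )
        assert len(out) == 1
        d = out[0]
        assert (d.ref_ext5, d.align_len, d.ref_ext3) == (4, 19, 3)
        assert (d.q_ext5, d.q_ext3) == (0, 0)

    def test_homopolymer_multimapping_offsets(self):
        # A/T homopolymers admit ref_len - query_len + 1 = 5 placements.
        ref = SmallRNARead("ref", "A" * 12)
        query = SmallRNARead("q", "T" * 8)
        out = find_duplexes(coll(ref), coll(query), AlignmentParameters(min_overlap=8))
        assert len(out) == 5
        assert sorted(d.align_start for d in out) == [0, 1, 2, 3, 4]
        assert all(d.align_len == 8 for d in out)

    def test_empty_collections_raise(self):
        with pytest.raises(ValueError):
            find_duplexes(ReadCollection([]), ReadCollection([]))

    def test_min_overlap_beyond_all_queries_warns_empty(self):
        refs = coll(SmallRNARead("r", "A" * 20))
        queries = coll(SmallRNARead("q", "T" * 10))
        with pytest.warns(UserWarning, match="min_overlap"):
            out = find_duplexes(refs, queries, AlignmentParameters(min_overlap=15))
        assert out == []

    def test_n_containing_reads_excluded(self):
        ref = SmallRNARead("ref", "ACGTACGTACGTACGTACGTA")
        qn = SmallRNARead("qn", reverse_complement(ref.sequence)[:-1] + "N")
        with pytest.warns(UserWarning):
            out = find_duplexes(coll(ref), coll(qn), AlignmentParameters(min_overlap=10))
        assert out == []

    def test_palindromic_self_pair_kept(self):
        # a sequence equal to its own reverse complement duplexes with itself
        seq = "ACGTACGTACGTACGT"
        assert reverse_complement(seq) == seq
        c = coll(SmallRNARead("p", seq))
        out = find_duplexes(c, c, AlignmentParameters(min_overlap=16))
        assert [(d.ref_id, d.query_id, d.align_len) for d in out] == [("p", "p", 16)]

    def test_mirrored_pairs_both_reported_on_self_comparison(self):
        a = SmallRNARead("a", "ACGGTCATTGCAAGCTTCCGA")
        b = SmallRNARead("b", reverse_complement(a.sequence))
        c = coll(a, b)
        out = find_duplexes(c, c, AlignmentParameters(min_overlap=21))
        pairs = sorted((d.ref_id, d.query_id) for d in out)
        assert pairs == [("a", "b"), ("b", "a")]


class TestOracleAndInvariants:
    def test_oracle_equivalence_random(self):
        """Seeded random collections: seeded engine == exhaustive oracle."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            refs = random_collection(rng, int(rng.integers(5, 40)), label="A")
            queries = random_collection(rng, int(rng.integers(5, 40)), label="B")
            params = AlignmentParameters(min_overlap=int(rng.integers(8, 16)))
            assert as_multiset(find_duplexes(refs, queries, params)) == as_multiset(
                brute_force_duplexes(refs, queries, params)
            )

    def test_monotonicity_in_min_overlap(self, small_sim):
        lo = find_duplexes(
            small_sim.file_a, small_sim.file_b, AlignmentParameters(min_overlap=12)
        )
        hi = find_duplexes(
            small_sim.file_a, small_sim.file_b, AlignmentParameters(min_overlap=16)
        )
        assert set(as_multiset(hi)) <= set(as_multiset(lo))

    def test_zero_mismatch_spans_match_exactly(self, small_sim):
        seqs_a = {r.read_id: r.sequence for r in small_sim.file_a}
        seqs_b = {r.read_id: r.sequence for r in small_sim.file_b}
        for d in find_duplexes(small_sim.file_a, small_sim.file_b):
            ref = seqs_a[d.ref_id]
            rcq = reverse_complement(seqs_b[d.query_id])
            assert (
                ref[d.align_start : d.align_start + d.align_len]
                == rcq[d.q_ext5 : d.q_ext5 + d.align_len]
            )

    def test_symmetry_under_file_swap(self, small_sim):
        """Swapping files maps each duplex's extensions to their mirror."""
        params = AlignmentParameters(min_overlap=12)
        fwd = find_duplexes(small_sim.file_a, small_sim.file_b, params)
        rev = find_duplexes(small_sim.file_b, small_sim.file_a, params)
        fwd_set = sorted(
            (d.ref_id, d.query_id, d.ref_ext5, d.ref_ext3, d.q_ext5, d.q_ext3)
            for d in fwd
        )
        rev_mapped = sorted(
            (d.query_id, d.ref_id, d.q_ext3, d.q_ext5, d.ref_ext3, d.ref_ext5)
            for d in rev
        )
        assert fwd_set == rev_mapped

    def test_mismatch_allowance_adds_duplexes(self):
        ref = SmallRNARead("ref", "ACGGTCATTGCAAGCTTCCGA")
        rc = reverse_complement(ref.sequence)
        near = "G" + rc[1:] if rc[0] != "G" else "C" + rc[1:]
        queries = coll(SmallRNARead("q", near))
        strict = find_duplexes(coll(ref), queries, AlignmentParameters(min_overlap=21))
        relaxed = find_duplexes(
            coll(ref), queries, AlignmentParameters(min_overlap=21, max_mismatches=1)
        )
        assert strict == []
        assert len(relaxed) == 1
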