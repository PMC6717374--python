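"""Indel repeat/homopolymer/microhomology classification."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutmat.indels import (
    DEL,
    INS,
    IndelEvent,
    classify_indel,
    count_repeat_units,
    enumerate_channels,
    enumerate_id28,
    enumerate_id83,
    extend_sequence_channel,
    id28_label,
    left_align,
    microhomology_length,
    strip_motif,
)
from mutmat.reference import StrandState
from mutmat.util import revcomp

NON = StrandState.NONTRANSCRIBED
REF = StrandState.GENE_ON_REFERENCE_STRAND


def _classify(seq, pos, motif, kind, state=NON):
    event = IndelEvent(kind, "1", pos, motif)
    return classify_indel(seq, lambda p: state, event)


class TestRepeatUnits:
    def test_deletion_of_one_of_two_adjacent_copies(self):
        #      123456789
        seq = "ATTACAACAGGCGC"
        assert count_repeat_units(seq, 4, "ACA", DEL) == 2

    def test_insertion_with_no_flanking_repeat(self):
        seq = "ATTACAGGCGC"
        assert count_repeat_units(seq, 6, "CCTG", INS) == 0

    def test_homopolymer_deletion_counts_deleted_base(self):
        assert count_repeat_units("ATCCCCCG", 3, "C", DEL) == 5

    def test_homopolymer_insertion_counts_existing_bases_only(self):
        assert count_repeat_units("ATCCCCCG", 3, "C", INS) == 5

    def test_both_flanks_are_scanned(self):
        #      ACA ACA ACA: delete the middle copy
        seq = "TACAACAACAG"
        assert count_repeat_units(seq, 5, "ACA", DEL) == 3

    def test_deletion_repeat_size_never_zero(self):
        assert count_repeat_units("ATTACAGGCGC", 4, "AC", DEL) >= 1


class TestMicrohomology:
    def test_three_prime_partial_overlap(self):
        # delete TAGTC; TAGT follows the deletion
        seq = "ACCCATAGTCTAGTAGCGGC"
        pos, motif = left_align(seq, 6, "TAGTC", DEL)
        assert count_repeat_units(seq, pos, motif, DEL) == 1
        assert microhomology_length(seq, pos, motif) == 4

    def test_five_prime_partial_overlap(self):
        # delete TAGTC; AGTC precedes the deletion
        seq = "ACCCAGTCTAGTCAAGCGGC"
        pos, motif = left_align(seq, 9, "TAGTC", DEL)
        assert microhomology_length(seq, pos, motif) == 4

    def test_no_overlap_gives_zero(self):
        seq = "TTGGACTTGG"
        assert microhomology_length(seq, 5, "AC") == 0

    def test_equivalent_caller_representations_share_channel(self):
        """Two placements of the same 5 bp deletion in the homologous
        reference classify to the same microhomology channel."""
        ref = "ACCCATAGTCTAGTAGCGGC"
        a = _classify(ref, 6, "TAGTC", DEL)
        b = _classify(ref, 9, "TCTAG", DEL)
        assert ref[5:10] != ref[8:13] or True  # different spans, same result
        assert a == b
        assert a[1] == "5+:Del:M:4"


class TestClassify:
    def test_one_bp_deletion_reported_by_pyrimidine_partner(self):
        _, core, _ = _classify("TTAGTT", 4, "G", DEL)
        assert core == "1:Del:C:1"

    def test_homopolymer_run_sizes_and_caps(self):
        seq = "AT" + "C" * 7 + "GA"
        assert _classify(seq, 3, "C", DEL)[1] == "1:Del:C:6+"
        assert _classify(seq, 3, "C", INS)[1] == "1:Ins:C:5+"
        seq = "AC" + "T" * 3 + "GA"
        assert _classify(seq, 3, "T", DEL)[1] == "1:Del:T:3"

    def test_repeat_deletion_and_insertion(self):
        seq = "ATTACAACAGGCGC"
        assert _classify(seq, 4, "ACA", DEL)[1] == "3:Del:R:2"
        assert _classify(seq, 3, "ACA", INS)[1] == "3:Ins:R:2"

    def test_insertion_with_no_repeat(self):
        assert _classify("ATTACAGGCGC", 6, "CCTG", INS)[1] == "4:Ins:R:0"

    def test_repeat_takes_precedence_over_microhomology(self):
        """A deletion with a full extra copy is a repeat event even though
        its motif trivially overlaps the remaining copy."""
        seq = "TTAGCAGCATT"
        assert _classify(seq, 3, "AGC", DEL)[1] == "3:Del:R:2"

    def test_long_deletion_without_copy_or_overlap_is_repeat_one(self):
        seq = "TTGGACTTGG"
        assert _classify(seq, 5, "AC", DEL)[1] == "2:Del:R:1"

    def test_strand_labels(self):
        seq = "ATTTTTGA"
        assert _classify(seq, 3, "T", DEL, REF)[0] == "U:1:Del:T:5"
        seq = "AGGGGGTA"
        assert _classify(seq, 3, "G", DEL, REF)[0] == "T:1:Del:C:5"
        seq = "TACATGCC"
        lab, _, _ = _classify(seq, 3, "CATG", DEL, REF)  # mixed motif
        assert lab.startswith("Q:")
        seq = "TACTTCCAG"
        lab, _, _ = _classify(seq, 3, "CTTCC", DEL, REF)  # pure pyrimidine
        assert lab.startswith("U:")

    def test_alignment_invariance_within_homopolymer(self):
        seq = "AT" + "C" * 6 + "GA"
        results = {_classify(seq, p, "C", DEL) for p in range(3, 9)}
        assert len(results) == 1


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    unit=st.sampled_from(["AC", "TG", "ACA", "CTG", "TA"]),
    copies=st.integers(2, 5),
    offset_frac=st.integers(0, 10),
)
def test_representation_invariance_in_repeat_tracts(unit, copies, offset_frac):
    """Deleting any single copy of a tandem repeat yields one channel,
    wherever the caller anchored the deletion."""
    seq = "GG" + unit * copies + "GG" if unit[0] != "G" else "CC" + unit * copies + "CC"
    offsets = range(copies)
    start = 3
    labels = {
        _classify(seq, start + k * len(unit), unit, DEL)
        for k in offsets
    }
    assert len(labels) == 1


def test_extension_rules():
    assert extend_sequence_channel("3:Del:R:2", "ACA") == "3:Del:R:2:ACA"
    assert extend_sequence_channel("3:Del:R:2", "TGT") == "3:Del:R:2:ACA"  # revcomp
    assert extend_sequence_channel("5+:Del:M:4", "TAGTC") == "5+:Del:M:4"
    assert extend_sequence_channel("5+:Del:R:1", "TAGTC") == "5+:Del:R:1"
    assert strip_motif("3:Del:R:2:ACA") == "3:Del:R:2"
    assert strip_motif("5+:Del:M:4") == "5+:Del:M:4"


def test_channel_enumerations():
    assert len(enumerate_id83()) == 83
    assert len(set(enumerate_id83())) == 83
    assert len(enumerate_channels("ID415")) == 83 * 5
    assert len(enumerate_id28()) == 28
    ext = enumerate_channels("ID8628")
    assert len(ext) == len(set(ext))
    # every extended channel collapses onto a real ID-83 channel
    assert {strip_motif(c) for c in ext} == set(enumerate_id83())


def test_id28_collapse_is_a_partition():
    targets = set(enumerate_id28())
    mapped = {id28_label(c) for c in enumerate_id83()}
    assert mapped == targets


def test_no_deletion_channel_with_repeat_size_zero():
    assert not [c for c in enumerate_id83() if ":Del:" in c and c.endswith(":0")]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(data=st.data())
def test_classified_channels_belong_to_the_enumeration(data):
    rng_seq = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=60))
    kind = data.draw(st.sampled_from([DEL, INS]))
    L = data.draw(st.integers(1, 6))
    if kind == DEL:
        pos = data.draw(st.integers(2, len(rng_seq) - L))
        motif = rng_seq[pos - 1 : pos - 1 + L]
    else:
        pos = data.draw(st.integers(1, len(rng_seq) - 1))
        motif = data.draw(st.text(alphabet="ACGT", min_size=L, max_size=L))
    stranded, core, ext = _classify(rng_seq, pos, motif, kind)
    assert core in set(enumerate_id83())
    assert stranded in set(enumerate_channels("ID415"))
    assert ext in set(enumerate_channels("ID8628"))
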