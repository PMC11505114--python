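"""Protein records, FASTA I/O, percent identity and threshold grouping."""

import pytest
from hypothesis import given, settings, strategies as st

from zeinpep.motif_db import fixture_path
from zeinpep.sequences import (
    CANONICAL_AA, ProteinRecord, SequenceValidationError, group_by_identity,
    group_from_pairs, percent_identity, read_catalog, read_fasta,
    read_identity_pairs, write_fasta,
)

aa_text = st.text(alphabet=sorted(CANONICAL_AA), min_size=1, max_size=60)


class TestProteinRecord:
    def test_sequence_is_cleaned_and_validated(self):
        rec = ProteinRecord("X1", "ac de\nFG ")
        assert rec.sequence == "ACDEFG"
        assert len(rec) == 6

    def test_non_canonical_residue_raises_with_context(self):
        with pytest.raises(SequenceValidationError, match=r"X1.*1"):
            ProteinRecord("X1", "AC1E")

    def test_declared_length_discrepancy_is_flagged_not_fixed(self):
        rec = ProteinRecord("P04705", "ACDE" * 45, length_declared=186)
        assert len(rec) == 180
        assert rec.has_length_discrepancy


class TestFastaIO:
    def test_packaged_fixture_has_six_records_with_printed_lengths(self, printed_records):
        assert len(printed_records) == 6
        assert len(printed_records["P06674"]) == 230
        assert len(printed_records["P06676"]) == 240
        assert len(printed_records["Q94IM1"]) == 266

    def test_single_entry(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">X some protein\nACDE\n")
        (rec,) = read_fasta(p)
        assert (rec.accession, rec.name, len(rec)) == ("X", "some protein", 4)

    def test_wrapped_and_unwrapped_lines_agree(self, tmp_path):
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        a.write_text(">X\nACDEFGHIKLMNPQ\n")
        b.write_text(">X\nACDEFG\nHIKLMNPQ\n")
        assert read_fasta(a)[0].sequence == read_fasta(b)[0].sequence

    def test_invalid_alphabet_raises(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">X\nAC1E\n")
        with pytest.raises(SequenceValidationError):
            read_fasta(p)

    def test_round_trip(self, tmp_path, printed_records):
        out = tmp_path / "out.fasta"
        write_fasta(printed_records.values(), out)
        again = {r.accession: r for r in read_fasta(out)}
        assert {a: r.sequence for a, r in again.items()} == {
            a: r.sequence for a, r in printed_records.items()
        }


class TestPercentIdentity:
    def test_self_identity_is_exactly_100(self, printed_records):
        rec = printed_records["P06674"]
        assert percent_identity(rec, rec) == 100.0

    @pytest.mark.parametrize("a, b, expected", [
        ("AAAA", "AAAT", 75.0),
        ("ACDEFGHIK", "ACDEFGHIR", 100 * 8 / 9),   # one substitution, hand alignment
        ("ACDEF", "ACDEF", 100.0),
    ])
    def test_known_alignments(self, a, b, expected):
        assert percent_identity(a, b) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(aa_text, aa_text)
    def test_symmetry(self, a, b):
        assert percent_identity(a, b) == pytest.approx(percent_identity(b, a), abs=1e-9)


class TestGrouping:
    def test_identical_records_form_one_group(self):
        recs = [ProteinRecord("A", "ACDEF"), ProteinRecord("B", "ACDEF")]
        grouping = group_by_identity(recs, 90.0)
        assert grouping.groups == [frozenset({"A", "B"})]

    def test_single_linkage_chain_rule(self):
        pairs = {frozenset("AB"): 95.0, frozenset("BC"): 95.0, frozenset("AC"): 40.0}
        grouping = group_from_pairs(["A", "B", "C"], pairs, 90.0)
        assert grouping.groups == [frozenset("ABC")]

    def test_all_below_threshold_gives_singletons(self):
        pairs = {frozenset("AB"): 50.0, frozenset("BC"): 60.0, frozenset("AC"): 40.0}
        grouping = group_from_pairs(["A", "B", "C"], pairs, 90.0)
        assert len(grouping.groups) == 3

    def test_representative_is_longest_then_lexicographic(self):
        pairs = {frozenset("AB"): 95.0, frozenset(("A", "C")): 10.0,
                 frozenset(("B", "C")): 10.0}
        g = group_from_pairs(["A", "B", "C"], pairs, 90.0, lengths={"A": 5, "B": 9, "C": 2})
        assert g.representatives == ["B", "C"]
        tie = group_from_pairs(["A", "B"], {frozenset("AB"): 95.0}, 90.0,
                               lengths={"A": 5, "B": 5})
        assert tie.representatives == ["A"]

    @settings(max_examples=40, deadline=None)
    @given(st.dictionaries(
        st.frozensets(st.sampled_from("ABCDEF"), min_size=2, max_size=2),
        st.floats(0, 100), max_size=15,
    ), st.floats(0, 100), st.floats(0, 100))
    def test_raising_threshold_only_refines(self, pairs, t1, t2):
        lo, hi = sorted([t1, t2])
        accs = list("ABCDEF")
        coarse = group_from_pairs(accs, pairs, lo).groups
        fine = group_from_pairs(accs, pairs, hi).groups
        for g in fine:
            assert any(g <= c for c in coarse)

    def test_published_identity_matrix_reproduces_reported_merges(self):
        """At the 90% threshold the published matrix merges the reported pairs
        and leaves the two unique 19-kDa entries as singletons.  Note that
        single-linkage closure also chains the remaining 19-kDa entries into
        one group (e.g. P06674 ~ P06675 90.5% ~ B6SHV3 99.6% ~ Q548E7 97.0%
        ~ Q548E6 ~ P04702 ~ P04703 ~ P06676), even though P06674 and P06676
        are directly only 70.5% identical — a documented property of the
        chain rule, not an error."""
        pairs = read_identity_pairs(fixture_path("alpha_zein_identity.tsv"))
        catalog = read_catalog(fixture_path("alpha_zein_catalog.tsv"))
        accs = sorted(catalog)
        lengths = {a: n for a, (_, n) in catalog.items()}
        g = group_from_pairs(accs, pairs, 90.0, lengths)
        assert g.group_of("Q94IM1") == g.group_of("P04698")
        assert g.group_of("P06679") == g.group_of("P04700")
        assert g.group_of("P06678") == frozenset({"P06678"})
        assert g.group_of("P04705") == frozenset({"P04705"})
        assert pairs[frozenset(("P06674", "P06676"))] < 90.0
        assert g.group_of("P06674") == g.group_of("P06676")  # chained merge
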