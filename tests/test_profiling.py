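"""Occurrence search, the frequency statistic A, and report rendering."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_occurrences
from zeinpep.digestion import DigestResult, SUBTILISIN, digest
from zeinpep.motif_db import ActivityMotif, MotifDatabase
from zeinpep.profiling import (
    find_occurrences, per_motif_counts, profile_digest, profile_potential,
    read_report, render_report, round_frequency, write_report,
)
from zeinpep.sequences import CANONICAL_AA, ProteinRecord

aa_text = st.text(alphabet=sorted(CANONICAL_AA), min_size=1, max_size=120)
motif_text = st.text(alphabet=sorted(CANONICAL_AA), min_size=1, max_size=5)


class TestFindOccurrences:
    @pytest.mark.parametrize("seq, motif, expected", [
        ("AAA", "AA", [0, 1]),                  # overlaps all counted
        ("ACD", "F", []),
        ("ACD", "ACDE", []),                    # motif longer than sequence
        ("PFPFPF", "PF", [0, 2, 4]),
    ])
    def test_known_positions(self, seq, motif, expected):
        assert find_occurrences(seq, motif) == expected

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            find_occurrences("ACD", "")

    def test_ir_occurs_once_in_printed_p06674(self, printed_records):
        assert len(find_occurrences(printed_records["P06674"].sequence, "IR")) == 1

    @settings(max_examples=200, deadline=None)
    @given(aa_text, motif_text)
    def test_matches_brute_force_oracle(self, seq, motif):
        assert find_occurrences(seq, motif) == brute_force_occurrences(seq, motif)


class TestRounding:
    @pytest.mark.parametrize("a, n, expected", [
        (1, 230, 0.0043),
        (3, 230, 0.0130),
        (24, 230, 0.1043),
        (187, 230, 0.8130),
        (1, 16000, 0.0001),     # 0.0000625 rounds half-up to 0.0001
        (1, 20000, 0.0001),     # 0.00005 exactly: half-up, not banker's
    ])
    def test_half_up_to_four_decimals(self, a, n, expected):
        assert round_frequency(a, n) == expected


class TestProfilePotential:
    def test_empty_database_gives_no_profiles(self, printed_records):
        assert profile_potential(printed_records["P06674"], MotifDatabase()) == []

    def test_campde_row(self, printed_records, fixture_db):
        profs = {p.activity: p for p in
                 profile_potential(printed_records["P06674"], fixture_db)}
        row = profs["CaMPDE inhibitor"]
        assert row.fragments == ("IR",)
        assert (row.a, row.N, row.A) == (1, 230, 0.0043)

    def test_dpp3_row(self, printed_records, fixture_db):
        profs = {p.activity: p for p in
                 profile_potential(printed_records["P06674"], fixture_db)}
        row = profs["Dipeptidyl peptidase III inhibitor"]
        assert set(row.fragments) == {"YL", "YR", "HL", "LA", "FL", "PF"}
        assert row.A == 0.1043

    def test_adding_a_motif_never_decreases_a(self, printed_records):
        rec = printed_records["P06674"]
        small = MotifDatabase([ActivityMotif("PL", "Xaa-Pro inhibitor")])
        bigger = MotifDatabase([ActivityMotif("PL", "Xaa-Pro inhibitor"),
                                ActivityMotif("LL", "Xaa-Pro inhibitor")])
        a_small = profile_potential(rec, small)[0].a
        a_big = profile_potential(rec, bigger)[0].a
        assert a_big >= a_small


class TestProfileDigest:
    def test_released_instances_counted_with_multiplicity(self):
        """Four distinct ACE dipeptides, one released twice: a = 5, and with a
        230-residue parent A = 5/230 = 0.0217."""
        seq = "PLGLCFPFPL" + "Q" * 220
        rec = ProteinRecord("SYN230", seq)
        result = digest(rec, [SUBTILISIN])
        assert result.peptides[:5] == ("PL", "GL", "CF", "PF", "PL")
        db = MotifDatabase([ActivityMotif(m, "ACE inhibitor")
                            for m in ("PL", "GL", "CF", "PF")])
        (row,) = profile_digest(result, db)
        assert set(row.fragments) == {"PL", "GL", "CF", "PF"}
        assert (row.a, row.N, row.A) == (5, 230, 0.0217)

    def test_substring_containment_does_not_count(self):
        rec = ProteinRecord("SYN", "QPLQQ")   # PL encrypted, never released
        db = MotifDatabase([ActivityMotif("PL", "Xaa-Pro inhibitor")])
        result = digest(rec, [SUBTILISIN])
        assert "QPL" in result.peptides        # PL stays inside a longer peptide
        assert profile_digest(result, db) == []

    def test_no_matches_gives_empty_list(self, fixture_db):
        result = digest(ProteinRecord("SYN", "QQQQQQ"), [SUBTILISIN])
        assert profile_digest(result, fixture_db) == []

    @settings(max_examples=100, deadline=None)
    @given(seq=aa_text)
    def test_a_bounded_by_released_peptide_count(self, fixture_db, seq):
        result = digest(ProteinRecord("SYN", seq), [SUBTILISIN])
        for row in profile_digest(result, fixture_db):
            assert row.a <= len(result.peptides)


class TestPerMotifCounts:
    def test_dpp3_decomposition_matches_oracle(self, printed_records):
        rec = printed_records["P06674"]
        counts = per_motif_counts(rec, ["YL", "YR", "HL", "LA", "FL", "PF"])
        oracle = {m: len(brute_force_occurrences(rec.sequence, m)) for m in counts}
        assert counts == oracle
        assert counts == {"YL": 4, "YR": 1, "HL": 1, "LA": 7, "FL": 5, "PF": 6}
        assert sum(counts.values()) == 24


class TestReport:
    def test_empty_profiles_render_header_only(self):
        assert render_report([]) == "accession\tmode\tactivity\tfragments\ta\tN\tA\n"

    def test_hypouricemic_row_prints_four_decimals(self, printed_records, fixture_db):
        text = render_report(profile_potential(printed_records["P06674"], fixture_db))
        assert "Hypouricemic\tLT, PT\t3\t230\t0.0130" in text

    def test_report_round_trip(self, tmp_path, printed_records, fixture_db):
        profiles = profile_potential(printed_records["P06676"], fixture_db)
        p = tmp_path / "report.tsv"
        write_report(profiles, p)
        again = read_report(p)
        assert [(r.activity, r.fragments, r.a, r.A) for r in again] == \
               [(r.activity, r.fragments, r.a, r.A) for r in sorted(
                   profiles, key=lambda x: (x.accession, x.mode, x.activity))]

    def test_rendering_is_deterministic(self, printed_records, fixture_db):
        profiles = profile_potential(printed_records["Q94IM1"], fixture_db)
        assert render_report(profiles) == render_report(list(reversed(profiles)))
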