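import pytest
from hypothesis import given, settings, strategies as st

from parapep import (
    PeptideObservation,
    ProteinRecord,
    ValidationError,
    build_attribution,
    count_missed_cleavages,
    enumerate_tryptic_peptides,
    filter_peptide_table,
    map_peptide,
)
from conftest import brute_force_tryptic

# alphabet rich in cleavage sites and prolines so boundary rules are exercised
_PROT = st.text(alphabet="ACDEGKLPRST", min_size=1, max_size=60)


class TestMissedCleavages:
    @pytest.mark.parametrize(
        "peptide,expected",
        [
            ("ATSQGGDLMSDLFNK", 0),  # terminal K never counts
            ("K", 0),
            ("AKRAK", 2),
            ("AKPAK", 0),  # the only internal K precedes P and is suppressed
            ("R", 0),
        ],
    )
    def test_examples(self, peptide, expected):
        assert count_missed_cleavages(peptide) == expected

    def test_proline_rule_can_be_disabled(self):
        assert count_missed_cleavages("AKPAK", proline_rule=False) == 1

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValidationError):
            count_missed_cleavages("")


class TestEnumerate:
    def test_no_missed_cleavages(self):
        got = enumerate_tryptic_peptides("MKAARGK", max_missed=0, min_len=1, max_len=50)
        assert got == {("MK", 1), ("AAR", 3), ("GK", 6)}

    def test_one_missed_cleavage_adds_joined_fragments(self):
        got = enumerate_tryptic_peptides("MKAARGK", max_missed=1, min_len=1, max_len=50)
        assert got == {("MK", 1), ("AAR", 3), ("GK", 6), ("MKAAR", 1), ("AARGK", 3)}

    def test_protein_without_cleavage_sites_is_its_own_peptide(self):
        assert enumerate_tryptic_peptides("MAAA", max_missed=0, min_len=1, max_len=50) == {
            ("MAAA", 1)
        }

    def test_fragments_containing_x_are_dropped(self):
        got = enumerate_tryptic_peptides("MXKAAR", max_missed=0, min_len=1, max_len=50)
        assert got == {("AAR", 4)}

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(seq=_PROT, max_missed=st.integers(0, 2), proline=st.booleans())
    def test_agrees_with_all_substrings_oracle(self, seq, max_missed, proline):
        got = enumerate_tryptic_peptides(
            seq, max_missed=max_missed, min_len=1, max_len=60, proline_rule=proline
        )
        assert got == brute_force_tryptic(seq, max_missed, 1, 60, proline)


class TestMapPeptide:
    PROT = ProteinRecord(id="P", sequence="MKLLRGG")

    def test_internal_fully_tryptic_match(self):
        (m,) = map_peptide("LLR", [self.PROT])
        assert (m.start, m.end, m.missed_cleavages) == (3, 5, 0)
        assert m.nterm_tryptic and m.cterm_tryptic

    def test_semi_tryptic_c_boundary_rejected(self):
        assert map_peptide("LLRG", [self.PROT]) == []

    def test_protein_nterm_is_a_valid_boundary(self):
        (m,) = map_peptide("MKLLR", [self.PROT])
        assert (m.start, m.end, m.missed_cleavages) == (1, 5, 1)

    def test_proline_suppression_blocks_boundary(self):
        prot = ProteinRecord(id="P", sequence="MKPLLR")
        assert map_peptide("PLLR", [prot]) == []
        assert map_peptide("PLLR", [prot], proline_rule=False) != []

    def test_il_equivalence_mode(self):
        prot = ProteinRecord(id="P", sequence="MKILR")
        assert map_peptide("LIR", [prot]) == []
        (m,) = map_peptide("LIR", [prot], il_equivalent=True)
        assert (m.start, m.end) == (3, 5)

    def test_peptide_with_x_never_matches(self):
        prot = ProteinRecord(id="P", sequence="MKAXR")
        assert map_peptide("AXR", [prot]) == []

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(seq=_PROT, data=st.data())
    def test_every_enumerated_peptide_maps_back(self, seq, data):
        peps = sorted(enumerate_tryptic_peptides(seq, max_missed=2, min_len=1, max_len=60))
        if not peps:
            return
        pep, start = data.draw(st.sampled_from(peps))
        prot = ProteinRecord(id="P", sequence=seq)
        matches = map_peptide(pep, [prot])
        assert any(m.start == start for m in matches)
        for m in matches:
            assert m.missed_cleavages <= 2
            assert m.nterm_tryptic and m.cterm_tryptic


class TestFilter:
    def test_singletons_removed(self):
        obs = [
            PeptideObservation("AAALFNK", 1),
            PeptideObservation("GGGLFNK", 2),
            PeptideObservation("TTTLFNK", 5),
        ]
        assert [o.peptide for o in filter_peptide_table(obs)] == ["GGGLFNK", "TTTLFNK"]

    def test_excess_missed_cleavages_removed(self):
        obs = [PeptideObservation("AKAKAKAK", 10)]
        assert filter_peptide_table(obs) == []

    def test_empty_input(self):
        assert filter_peptide_table([]) == []


class TestAttribution:
    def test_two_paralogues_differing_at_one_residue(self):
        p1 = ProteinRecord(id="P1", sequence="MKAAADKR")
        p2 = ProteinRecord(id="P2", sequence="MKAAAEKR")
        peps = [PeptideObservation("AAADK", 10), PeptideObservation("AAAEK", 4)]
        report = build_attribution(peps, [p1, p2])
        assert report.entry("P1").unique == ("AAADK",)
        assert report.entry("P2").unique == ("AAAEK",)
        assert report.entry("P1").explained_fraction == pytest.approx(10 / 14)
        assert report.ranking == ("P1", "P2")
        assert report.unmapped == ()

    def test_no_peptides_gives_zeroed_report(self):
        report = build_attribution([], [ProteinRecord(id="P", sequence="MKAAR")])
        assert report.top.explained_fraction == 0.0
        assert report.total_obs == 0

    def test_identical_twins_have_no_unique_peptides(self):
        twins = [
            ProteinRecord(id="A", sequence="MKAAADKR"),
            ProteinRecord(id="B", sequence="MKAAADKR"),
        ]
        report = build_attribution([PeptideObservation("AAADK", 5)], twins)
        a, b = report.entry("A"), report.entry("B")
        assert a.unique == b.unique == ()
        assert a.captured == b.captured == ("AAADK",)
        # tie broken lexicographically
        assert report.ranking == ("A", "B")

    def test_empty_protein_collection_rejected(self):
        with pytest.raises(ValidationError):
            build_attribution([], [])

    def test_invariant_to_input_order(self):
        p1 = ProteinRecord(id="P1", sequence="MKAAADKRGGLK")
        p2 = ProteinRecord(id="P2", sequence="MKAAAEKRGGLK")
        peps = [
            PeptideObservation("AAADK", 10),
            PeptideObservation("AAAEK", 4),
            PeptideObservation("GGLK", 7),
        ]
        a = build_attribution(peps, [p1, p2])
        b = build_attribution(peps[::-1], [p2, p1])
        assert a == b

    def test_unique_peptides_absent_from_all_other_capture_sets(self, default_family):
        _, family, observations = default_family
        from parapep import filter_peptide_table

        report = build_attribution(filter_peptide_table(observations), family.proteins)
        for e in report.paralogues:
            for other in report.paralogues:
                if other.protein_id != e.protein_id:
                    assert not set(e.unique) & set(other.captured)

    def test_observation_conservation(self, default_family):
        _, family, observations = default_family
        filtered = filter_peptide_table(observations)
        report = build_attribution(filtered, family.proteins)
        mapped = set()
        for e in report.paralogues:
            mapped |= set(e.captured)
        assert mapped | {p for p, _ in report.unmapped} == {o.peptide for o in filtered}
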