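import pytest

from parapep import (
    CladeMap,
    ProteinRecord,
    ValidationError,
    classify_substitution,
    conserved_columns,
    mutate_reference_paralogue,
    profile_paralogue_variants,
    qc_orthologues,
    shared_derived_variants,
    simulate_orthologue_msa,
)
from parapep.io import CLADE_LEVELS


def toy_msa():
    # 2 primates, 2 mammals, 1 tetrapod, 1 vertebrate (fish); 4 columns:
    #   col 1 invariant everywhere
    #   col 2 'A' within mammals, 'G' outside
    #   col 3 variable even among primates
    #   col 4 gap in one mammal
    msa = {
        "human": "MAKA",
        "chimp": "MAGA",
        "mouse": "MALA",
        "cow":   "MATA",
        "frog":  "MGCA",
        "fish":  "MGW-",
    }
    clades = CladeMap(
        levels={
            "human": "primates",
            "chimp": "primates",
            "mouse": "mammals",
            "cow": "mammals",
            "frog": "tetrapods",
            "fish": "vertebrates",
        }
    )
    return msa, clades


class TestConservedColumns:
    def test_invariant_column_conserved_to_vertebrate_depth(self):
        msa, clades = toy_msa()
        cset = conserved_columns(msa, clades)
        assert cset.depth[0] == "vertebrates"
        assert cset.consensus_at(0) == "M"

    def test_column_conserved_only_within_mammals(self):
        msa, clades = toy_msa()
        cset = conserved_columns(msa, clades)
        assert cset.depth[1] == "mammals"
        assert cset.consensus[1] == {"primates": "A", "mammals": "A"}

    def test_variable_column_unconserved(self):
        msa, clades = toy_msa()
        assert conserved_columns(msa, clades).depth[2] is None

    def test_gap_breaks_conservation_under_zero_tolerance(self):
        msa, clades = toy_msa()
        cset = conserved_columns(msa, clades)
        assert cset.depth[3] == "tetrapods"  # fish gap stops the chain

    def test_empty_alignment_rejected(self):
        _, clades = toy_msa()
        with pytest.raises(ValidationError):
            conserved_columns({}, clades)

    def test_monotone_depth_on_simulated_panels(self):
        for seed in range(3):
            msa, clades, _ = simulate_orthologue_msa(seed=seed)
            cset = conserved_columns(msa, clades)
            for c, d in enumerate(cset.depth):
                if d is None:
                    continue
                for level in CLADE_LEVELS[: CLADE_LEVELS.index(d) + 1]:
                    assert cset.is_conserved_at(c, level)


class TestQcOrthologues:
    REF = "human"

    def test_eight_column_insertion_excluded(self):
        msa = {"human": "MKAA--------LLR", "far": "MKAAGGGGGGGGLLR"}
        assert qc_orthologues(msa, "human") == ["human"]

    def test_seven_column_deletion_retained(self):
        msa = {"human": "MKAAGGGGGGGLLR", "near": "MKAA-------LLR"}
        assert qc_orthologues(msa, "human") == ["human", "near"]

    def test_identical_candidate_retained(self):
        msa = {"human": "MKAALLR", "twin": "MKAALLR"}
        assert qc_orthologues(msa, "human") == ["human", "twin"]

    def test_missing_terminal_residue_excluded(self):
        msa = {"human": "MKAALLR", "headless": "-KAALLR"}
        assert qc_orthologues(msa, "human") == ["human"]

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValidationError):
            qc_orthologues({"human": "MKAA", "x": "MKAAA"}, "human")


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("Y", "D", "non_conservative"),  # radical aromatic-to-acidic swap
            ("D", "E", "conservative"),
            ("L", "I", "conservative"),
            ("R", "K", "conservative"),
            ("G", "W", "non_conservative"),
        ],
    )
    def test_fixed_grouping(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_symmetric(self):
        for ref, alt in [("A", "C"), ("K", "H"), ("F", "Y")]:
            assert classify_substitution(ref, alt) == classify_substitution(alt, ref)

    def test_identical_residues_rejected(self):
        with pytest.raises(ValidationError):
            classify_substitution("A", "A")


class TestProfile:
    def test_identical_paralogue_has_empty_profile(self):
        msa, clades, truth = simulate_orthologue_msa(seed=5)
        cset = conserved_columns(msa, clades)
        ref = ProteinRecord(id="self", sequence=msa["primate_1"])
        profile = profile_paralogue_variants(ref, msa, "primate_1", cset)
        assert profile.saavs == ()
        assert profile.deletions == ()

    def test_single_substitution_at_conserved_column(self):
        msa, clades, truth = simulate_orthologue_msa(seed=5)
        cset = conserved_columns(msa, clades)
        paralogue, planted = mutate_reference_paralogue(
            msa, "primate_1", truth, n_saavs=1, seed=5
        )
        profile = profile_paralogue_variants(paralogue, msa, "primate_1", cset)
        assert [(s.column, s.ref_residue, s.alt_residue) for s in profile.saavs] == list(
            planted
        )
        # a SAAV at a conserved column counts at every level up to its depth
        s = profile.saavs[0]
        for level in CLADE_LEVELS[: CLADE_LEVELS.index(s.clade_depth) + 1]:
            assert profile.saav_total_at(level) >= 1

    def test_three_residue_deletion_reported(self):
        msa, clades, _ = simulate_orthologue_msa(seed=5)
        cset = conserved_columns(msa, clades)
        ref_seq = msa["primate_1"]
        mutant = ProteinRecord(id="del3", sequence=ref_seq[:50] + ref_seq[53:])
        profile = profile_paralogue_variants(mutant, msa, "primate_1", cset)
        assert len(profile.deletions) == 1
        assert profile.deletions[0][2] == 3

    def test_saav_totals_monotone_over_clade_depth(self):
        msa, clades, truth = simulate_orthologue_msa(seed=6)
        cset = conserved_columns(msa, clades)
        paralogue, _ = mutate_reference_paralogue(msa, "primate_1", truth, n_saavs=6, seed=6)
        profile = profile_paralogue_variants(paralogue, msa, "primate_1", cset)
        totals = [profile.saav_total_at(level) for level in CLADE_LEVELS]
        assert totals == sorted(totals, reverse=True)


class TestSharedVariants:
    def _profiles(self):
        msa, clades, truth = simulate_orthologue_msa(seed=8)
        cset = conserved_columns(msa, clades)
        a, planted_a = mutate_reference_paralogue(msa, "primate_1", truth, 3, seed=1)
        return msa, cset, a, planted_a

    def test_variant_in_both_profiles_reported_with_both_ids(self):
        msa, cset, _, _ = self._profiles()
        p1, planted = mutate_reference_paralogue(msa, "primate_1", cset, 2, seed=3)
        prof1 = profile_paralogue_variants(p1, msa, "primate_1", cset)
        p2 = ProteinRecord(id="copyB", sequence=p1.sequence)
        prof2 = profile_paralogue_variants(p2, msa, "primate_1", cset)
        shared = shared_derived_variants([prof1, prof2], min_share=2)
        assert {(v.column, v.alt_residues) for v in shared} == {
            (c, (alt,)) for c, _, alt in planted
        }
        for v in shared:
            assert set(v.paralogue_ids) == {p1.id, "copyB"}

    def test_disjoint_profiles_share_nothing(self):
        msa, cset, a, _ = self._profiles()
        prof_a = profile_paralogue_variants(a, msa, "primate_1", cset)
        b, _ = mutate_reference_paralogue(msa, "primate_1", cset, 3, seed=99)
        prof_b = profile_paralogue_variants(b, msa, "primate_1", cset)
        shared = shared_derived_variants([prof_a, prof_b], min_share=2)
        planted_cols_a = {s.column for s in prof_a.saavs}
        planted_cols_b = {s.column for s in prof_b.saavs}
        assert all(
            v.column in (planted_cols_a & planted_cols_b) for v in shared
        )

    def test_min_share_threshold_excludes(self):
        msa, cset, a, _ = self._profiles()
        prof_a = profile_paralogue_variants(a, msa, "primate_1", cset)
        b = ProteinRecord(id="b", sequence=a.sequence)
        prof_b = profile_paralogue_variants(b, msa, "primate_1", cset)
        c = ProteinRecord(id="c", sequence=msa["primate_1"])
        prof_c = profile_paralogue_variants(c, msa, "primate_1", cset)
        assert shared_derived_variants([prof_a, prof_b, prof_c], min_share=3) == []

    def test_pooled_alternates_merge_columns(self):
        msa, cset, a, _ = self._profiles()
        prof_a = profile_paralogue_variants(a, msa, "primate_1", cset)
        s = prof_a.saavs[0]
        other_alt = "W" if s.alt_residue != "W" else "F"
        seq = list(msa["primate_1"])
        seq[s.paralogue_position - 1] = other_alt
        b = ProteinRecord(id="b", sequence="".join(seq))
        prof_b = profile_paralogue_variants(b, msa, "primate_1", cset)
        pooled = shared_derived_variants([prof_a, prof_b], min_share=2, pool_alternates=True)
        assert any(
            v.column == s.column and set(v.alt_residues) == {s.alt_residue, other_alt}
            for v in pooled
        )

    def test_fewer_than_two_profiles_rejected(self):
        msa, cset, a, _ = self._profiles()
        prof_a = profile_paralogue_variants(a, msa, "primate_1", cset)
        with pytest.raises(ValidationError):
            shared_derived_variants([prof_a], min_share=1)
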