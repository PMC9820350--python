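"""Alignment, anchor extraction and family/activity classification."""

import pytest
from hypothesis import given, settings, strategies as st

from pspkit import (
    AlignmentParams,
    Peptide,
    classify,
    extract_anchor_residues,
    gen_reference_profile,
    global_align,
    load_anchor_table,
)
from pspkit.annotate import Anchor, AnchorProfile, profiles_from_table

PARAMS = AlignmentParams()

FAMILIES = ["S9A", "S9B", "S28", "M24B", "M17", "M20"]


@pytest.fixture(scope="module")
def s9b():
    profile, positions = gen_reference_profile("S9B", length=80, seed=7)
    return profile, positions


@pytest.fixture(scope="module")
def all_profiles():
    return [gen_reference_profile(f, length=80, seed=11)[0] for f in FAMILIES]


class TestGlobalAlign:
    def test_self_alignment_has_no_gaps(self):
        p = Peptide("p", "FLQPQQPFPQ")
        aln = global_align(p, p, PARAMS)
        assert aln.aligned_a == aln.aligned_b == p.seq

    def test_one_mismatch_keeps_nine_matches(self):
        a = Peptide("a", "FLQPQQPFPQ")
        b = Peptide("b", "FLQPWQPFPQ")
        aln = global_align(a, b, PARAMS)
        assert "-" not in aln.aligned_a + aln.aligned_b
        matches = sum(x == y for x, y in zip(aln.aligned_a, aln.aligned_b))
        assert matches == 9

    def test_length_one_vs_two_forces_one_gap(self):
        aln = global_align(Peptide("a", "A"), Peptide("b", "AA"), PARAMS)
        assert (aln.aligned_a + aln.aligned_b).count("-") == 1


class TestAnchorExtraction:
    def test_self_extraction_observes_expected(self, s9b):
        profile, positions = s9b
        obs = extract_anchor_residues(profile.reference_seq, profile, PARAMS)
        for anchor in profile.anchors:
            assert obs[anchor.position] in anchor.expected

    def test_catalytic_ser_to_gly_is_observed(self, s9b):
        profile, positions = s9b
        seq = list(profile.reference_seq.seq)
        seq[positions[0] - 1] = "G"
        obs = extract_anchor_residues(Peptide("mut", "".join(seq)), profile, PARAMS)
        assert obs[positions[0]] == "G"

    def test_deletion_over_anchor_reports_gap(self, s9b):
        profile, positions = s9b
        ref = profile.reference_seq.seq
        his = positions[2]
        cand = Peptide("del", ref[:his - 4] + ref[his + 3:])
        obs = extract_anchor_residues(cand, profile, PARAMS)
        assert obs[his] == "-"

    def test_invariant_to_terminal_extensions(self, s9b):
        profile, _ = s9b
        padded = Peptide("pad", "MKLV" + profile.reference_seq.seq + "AAHHY")
        base = extract_anchor_residues(profile.reference_seq, profile, PARAMS)
        ext = extract_anchor_residues(padded, profile, PARAMS)
        assert ext == base


class TestClassify:
    def test_self_classification_active(self, all_profiles):
        for profile in all_profiles:
            rep = classify(
                Peptide("cand", profile.reference_seq.seq), all_profiles, PARAMS)
            assert rep.best_family == profile.family
            assert rep.activity_call == "active"

    def test_gly_substituted_s9b_is_inactive_homolog(self, s9b):
        profile, positions = s9b
        seq = list(profile.reference_seq.seq)
        seq[positions[0] - 1] = "G"
        rep = classify(Peptide("dpp10_like", "".join(seq)), [profile], PARAMS)
        assert rep.activity_call == "inactive_homolog"
        assert any("DPP10-like" in n for n in rep.notes)

    def test_metal_anchor_mutation_is_incomplete(self):
        profile, positions = gen_reference_profile("M24B", length=80, seed=13)
        seq = list(profile.reference_seq.seq)
        seq[positions[0] - 1] = "A"  # metal-site Asp -> Ala
        rep = classify(Peptide("m24b_mut", "".join(seq)), [profile], PARAMS)
        assert rep.activity_call == "incomplete"

    def test_s9b_exo_determinant_note(self, s9b):
        profile, _ = s9b
        rep = classify(Peptide("c", profile.reference_seq.seq), [profile], PARAMS)
        assert any(n.startswith("exo-only") for n in rep.notes)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_non_anchor_mutations_keep_activity_call(self, data, s9b):
        profile, positions = s9b
        protected = set(positions) | {profile.determinant_position}
        free_pos = [i for i in range(1, len(profile.reference_seq) + 1)
                    if i not in protected]
        pos = data.draw(st.sampled_from(free_pos))
        new = data.draw(st.sampled_from(sorted(
            set("ACDEFGHIKLMNQRSTVWY") - {profile.reference_seq.seq[pos - 1]})))
        seq = list(profile.reference_seq.seq)
        seq[pos - 1] = new
        rep = classify(Peptide("mut", "".join(seq)), [profile], PARAMS)
        assert rep.activity_call == "active"


class TestPackagedAnchorTable:
    def test_table_structure(self):
        table = load_anchor_table()
        assert set(table.columns) == {
            "family", "reference_id", "role", "position", "expected"}
        assert set(table.family) == set(FAMILIES)
        # serine families carry exactly three catalytic anchors, S/D/H order
        for fam in ("S9A", "S9B", "S28"):
            cat = table[(table.family == fam) & (table.role == "catalytic")]
            cat = cat.sort_values("position")
            assert list(cat.expected) == ["S", "D", "H"]

    def test_profiles_from_table_with_synthetic_reference(self):
        table = load_anchor_table()
        m20 = table[table.family == "M20"]
        # synthetic stand-in reference long enough for the real positions
        import numpy as np
        rng = np.random.default_rng(1)
        seq = list(rng.choice(sorted(set("ACDEFGHIKLMNPQRSTVWY")), size=500))
        for _, row in m20.iterrows():
            seq[int(row.position) - 1] = row.expected[0]
        refs = {"Q96KP4": Peptide("Q96KP4", "".join(seq))}
        profiles = profiles_from_table(table, refs)
        assert len(profiles) == 1
        rep = classify(refs["Q96KP4"], profiles, PARAMS)
        assert rep.best_family == "M20" and rep.activity_call == "active"

    def test_anchor_outside_reference_is_config_error(self):
        with pytest.raises(ValueError, match="outside reference"):
            AnchorProfile("S9B", "r", Peptide("r", "ACDEF"),
                          (Anchor("catalytic", 10, frozenset("S")),))
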