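import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dimerscreen import (
    BundleSpec,
    DimerPoseSpec,
    EnergyTable,
    build_ideal_bundle,
    fit_membrane_frame,
    format_interface_string,
    helix_contributions,
    interface_profile,
    interface_residues,
    parse_interface_string,
    place_dimer,
    segment_qualifier,
    significant_residues,
)
from dimerscreen.model import ComplexModel

from oracles import brute_force_interface


class TestInterfaceResidues:
    def test_distant_protomers_have_empty_interface(self, bundle7, bundle7_b):
        far = place_dimer(bundle7, bundle7_b, DimerPoseSpec((4, 5), (4, 5), axis_separation=40.0))
        subj, part = interface_residues(far)
        assert subj == set() and part == set()

    def test_designed_interface_confined_to_facing_helices(self, homodimer):
        subj, part = interface_residues(homodimer)
        assert subj and part
        helices = {homodimer.subject.segment_of(r).index for r in subj}
        assert helices == {4, 5}

    def test_matches_brute_force_scan(self, homodimer, blocker_complex):
        for model in (homodimer, blocker_complex):
            assert interface_residues(model, 5.0) == brute_force_interface(model, 5.0)

    def test_monotone_in_cutoff(self, homodimer):
        s5, p5 = interface_residues(homodimer, 5.0)
        s6, p6 = interface_residues(homodimer, 6.0)
        assert s5 <= s6 and p5 <= p6

    def test_symmetric_under_role_swap(self, homodimer):
        swapped = ComplexModel(
            homodimer.partner.with_chain_id("A"),
            homodimer.subject.with_chain_id("B"),
            homodimer.designation,
        )
        # residue numbering is shared, so the sets swap exactly
        s, p = interface_residues(homodimer)
        s2, p2 = interface_residues(swapped)
        assert (s, p) == (p2, s2)

    def test_nonpositive_cutoff_rejected(self, homodimer):
        with pytest.raises(ValueError, match="cutoff"):
            interface_residues(homodimer, 0.0)


class TestSignificantResidues:
    def test_strict_threshold(self):
        table = EnergyTable({("A", 1): -1.5, ("A", 2): -0.5, ("A", 3): -1.0})
        sig = significant_residues(table, -1.0)
        assert sig == {("A", 1)}  # -1.0 exactly is excluded, -0.5 is above

    @given(t1=st.floats(-3, 0), t2=st.floats(-3, 0))
    def test_nested_in_threshold(self, t1, t2):
        table = EnergyTable({("A", i): -i / 4 for i in range(12)})
        if t1 < t2:
            t1, t2 = t2, t1
        assert significant_residues(table, t1) >= significant_residues(table, t2)


class TestHelixContributions:
    def test_energy_weighted_ordering(self, homodimer):
        subj, _ = interface_residues(homodimer)
        tm4 = [r for r in subj if homodimer.subject.segment_of(r).index == 4]
        tm5 = [r for r in subj if homodimer.subject.segment_of(r).index == 5]
        table = EnergyTable(
            {("A", r): -30.0 / len(tm4) for r in tm4}
            | {("A", r): -5.0 / len(tm5) for r in tm5}
        )
        ranked = helix_contributions(homodimer, subj, table)
        assert [h.index for h in ranked] == [4, 5]
        assert ranked[0].score == pytest.approx(30.0)

    def test_tie_breaks_to_lower_index(self, homodimer):
        subj, _ = interface_residues(homodimer)
        table = EnergyTable({("A", r): -1.0 for r in subj})
        # force equal scores by assigning equal per-helix totals
        tm4 = [r for r in subj if homodimer.subject.segment_of(r).index == 4]
        tm5 = [r for r in subj if homodimer.subject.segment_of(r).index == 5]
        table = EnergyTable(
            {("A", r): -6.0 / len(tm4) for r in tm4}
            | {("A", r): -6.0 / len(tm5) for r in tm5}
        )
        ranked = helix_contributions(homodimer, subj, table)
        assert [h.index for h in ranked] == [4, 5]

    def test_contact_count_fallback_ranks_designed_helices_first(self, bundle7, bundle7_b):
        dimer = place_dimer(bundle7, bundle7_b, DimerPoseSpec((2, 3), (2, 3)))
        ranked = helix_contributions(dimer)
        assert {h.index for h in ranked[:2]} == {2, 3}

    def test_scale_invariance_of_energy_ranking(self, homodimer):
        subj, _ = interface_residues(homodimer)
        base = {("A", r): -float(i + 1) for i, r in enumerate(sorted(subj))}
        r1 = helix_contributions(homodimer, subj, EnergyTable(base))
        r2 = helix_contributions(
            homodimer, subj, EnergyTable({k: 7.5 * v for k, v in base.items()})
        )
        assert [h.index for h in r1] == [h.index for h in r2]

    def test_empty_interface_gives_empty_ranking(self, bundle7, bundle7_b):
        far = place_dimer(bundle7, bundle7_b, DimerPoseSpec((4, 5), (4, 5), axis_separation=40.0))
        assert helix_contributions(far) == []


class TestSegmentQualifier:
    def _helix_by_height(self, protomer, index):
        seg = next(s for s in protomer.tm_segments if s.index == index)
        frame = fit_membrane_frame(protomer)
        res = sorted(
            protomer.segment_residues(seg), key=lambda r: frame.height(r.ca)
        )
        return frame, res  # ascending: intracellular -> extracellular

    def test_extracellular_patch_is_E(self, bundle7):
        frame, res = self._helix_by_height(bundle7, 4)
        top = {r.resseq for r in res[-5:]}
        assert segment_qualifier(bundle7, 4, top, frame) == "E"

    def test_spread_patch_has_no_qualifier(self, bundle7):
        frame, res = self._helix_by_height(bundle7, 4)
        spread = {res[1].resseq, res[len(res) // 2].resseq, res[-2].resseq}
        assert segment_qualifier(bundle7, 4, spread, frame) is None

    def test_two_of_three_intracellular_is_I(self, bundle7):
        frame, res = self._helix_by_height(bundle7, 4)
        patch = {res[0].resseq, res[1].resseq, res[-1].resseq}  # 2/3 >= 0.6
        assert segment_qualifier(bundle7, 4, patch, frame) == "I"


class TestInterfaceStrings:
    @pytest.mark.parametrize(
        "ranked,expected",
        [
            ([(2, None), (1, None), (3, "E"), (4, "I")], "TM2, TM1, TM3 (E), TM4 (I)"),
            ([(4, None), (5, None)], "TM4, TM5"),
            ([], ""),
        ],
    )
    def test_format(self, ranked, expected):
        assert format_interface_string(ranked) == expected

    def test_parse_tolerates_tight_qualifiers(self):
        assert parse_interface_string("TM2, TM1, TM3 (E), TM4(I)") == [
            (2, None), (1, None), (3, "E"), (4, "I"),
        ]

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_interface_string("TM2, helix9")

    def test_profile_string_on_designed_dimer(self, homodimer):
        prof = interface_profile(homodimer)
        assert {h.index for h in prof.helix_ranking} == {4, 5}
        assert prof.interface_string.startswith("TM")
        # round trip through the parser
        parsed = parse_interface_string(prof.interface_string)
        assert [i for i, _ in parsed] == [h.index for h in prof.helix_ranking]
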