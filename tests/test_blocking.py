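import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dimerscreen import (
    BindingEnergy,
    BundleSpec,
    DimerPoseSpec,
    Thresholds,
    blocking_call,
    blocking_verdict,
    build_ideal_bundle,
    competition_groups,
    interface_overlap,
    place_dimer,
    superpose_on_subject,
)
from dimerscreen.blocking import OverlapResult
from dimerscreen.geometry import kabsch, rotation_about_axis

from oracles import quaternion_superpose


class TestSuperposition:
    def test_self_superposition_is_identity(self, homodimer):
        sup = superpose_on_subject(homodimer, homodimer)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rigid_motion(self, homodimer):
        R = rotation_about_axis([2, -1, 4], 71.0)
        t = np.array([3.0, -8.0, 12.0])
        moved = homodimer.transformed(R, t)
        sup = superpose_on_subject(moved, homodimer)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(sup.rotation, R, atol=1e-6)
        assert np.allclose(sup.translation, t, atol=1e-6)

    def test_matches_quaternion_oracle_on_noisy_copy(self, homodimer, blocker_complex):
        rng = np.random.default_rng(7)
        resseqs = homodimer.subject.tm_resseqs()
        fixed = homodimer.subject.ca_coords(resseqs)
        moving = blocker_complex.subject.ca_coords(resseqs) + rng.normal(0, 0.5, (len(resseqs), 3))
        _, _, rmsd_k = kabsch(moving, fixed)
        _, _, rmsd_q = quaternion_superpose(moving, fixed)
        assert rmsd_k == pytest.approx(rmsd_q, abs=1e-6)

    def test_different_subjects_rejected(self, homodimer, bundle7, iso2):
        other = place_dimer(
            iso2.with_chain_id("A"), bundle7.with_chain_id("B"),
            DimerPoseSpec((1, 2), (4, 5)),
        )
        with pytest.raises(ValueError, match="share a subject"):
            superpose_on_subject(homodimer, other)


class TestInterfaceOverlap:
    def test_identical_sets(self):
        r = interface_overlap({1, 2, 3}, {1, 2, 3})
        assert (r.shared, r.jaccard, r.frac_of_dimer) == (3, 1.0, 1.0)

    def test_disjoint_sets(self):
        r = interface_overlap({1, 2}, {3, 4})
        assert (r.shared, r.jaccard, r.frac_of_dimer) == (0, 0.0, 0.0)

    def test_partial_overlap_arithmetic(self):
        r = interface_overlap(set(range(1, 11)), set(range(6, 16)))
        assert r.shared == 5
        assert r.jaccard == pytest.approx(5 / 15)
        assert r.frac_of_dimer == pytest.approx(0.5)

    def test_empty_dimer_interface_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            interface_overlap(set(), {1})

    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=20),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=20),
    )
    def test_jaccard_symmetric_and_bounded(self, a, b):
        ab = interface_overlap(a, b)
        ba = interface_overlap(b, a)
        assert ab.jaccard == pytest.approx(ba.jaccard)
        assert 0 <= ab.jaccard <= ab.frac_of_dimer <= 1
        if a <= b:
            assert ab.frac_of_dimer == 1.0


class TestBlockingCall:
    def _call(self, frac, dimer_mean, blocker_mean, **kw):
        overlap = OverlapResult(shared=int(frac * 100), jaccard=frac, frac_of_dimer=frac)
        params = Thresholds().updated(**kw)
        return blocking_call(
            overlap, BindingEnergy(dimer_mean, 0.1), BindingEnergy(blocker_mean, 0.1), params
        )

    def test_overlap_and_energy_both_required(self):
        assert self._call(0.9, -70.0, -100.0).blocks
        assert not self._call(0.0, -70.0, -100.0).blocks  # no overlap
        # full overlap but 20 kcal/mol weaker at delta 5 -> no block
        assert not self._call(1.0, -100.0, -80.0, delta_close=5.0).blocks

    @given(
        frac=st.floats(0, 1), frac2=st.floats(0, 1),
        blocker=st.floats(-150, -10), blocker2=st.floats(-150, -10),
    )
    def test_monotone_in_overlap_and_energy(self, frac, frac2, blocker, blocker2):
        """More overlap or stronger blocker binding never un-blocks."""
        base = self._call(frac, -70.0, blocker)
        better = self._call(max(frac, frac2), -70.0, min(blocker, blocker2))
        if base.blocks:
            assert better.blocks

    def test_verdict_from_structures(self, homodimer, blocker_complex):
        homodimer.bfe = BindingEnergy(-70.5, 0.1)
        blocker_complex.bfe = BindingEnergy(-104.7, 0.3)
        v = blocking_verdict(homodimer, blocker_complex)
        assert v.overlap_pass and v.energy_pass and v.blocks

    def test_opposite_face_blocker_does_not_block(self, bundle7, bundle7_b, iso2):
        dimer = place_dimer(bundle7, bundle7_b, DimerPoseSpec((1, 2), (1, 2)))
        dimer.bfe = BindingEnergy(-69.8, 0.3)
        blocker = place_dimer(bundle7, iso2, DimerPoseSpec((4, 5), (1, 2)))
        blocker.bfe = BindingEnergy(-104.7, 0.3)
        v = blocking_verdict(dimer, blocker)
        assert not v.overlap_pass and not v.blocks

    def test_missing_bfe_rejected(self, homodimer, blocker_complex):
        import dataclasses

        dimer = dataclasses.replace(homodimer, bfe=None)
        with pytest.raises(ValueError, match="binding free energy"):
            blocking_verdict(dimer, blocker_complex)


class TestCompetitionGroups:
    def test_same_face_dimers_group_together(self, bundle7, bundle7_b):
        same_face = [
            place_dimer(bundle7, bundle7_b, DimerPoseSpec((4, 5), (4, 5))),
            place_dimer(bundle7, bundle7_b, DimerPoseSpec((4, 5), (1, 2))),
            place_dimer(bundle7, bundle7_b, DimerPoseSpec((4, 5), (6, 7))),
        ]
        assert competition_groups(same_face) == [[0, 1, 2]]

    def test_opposite_faces_do_not_group(self, bundle7, bundle7_b):
        dimers = [
            place_dimer(bundle7, bundle7_b, DimerPoseSpec((4, 5), (4, 5))),
            place_dimer(bundle7, bundle7_b, DimerPoseSpec((1, 2), (1, 2))),
        ]
        assert competition_groups(dimers) == []

    def test_single_complex_has_no_group(self, homodimer):
        assert competition_groups([homodimer]) == []
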