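import numpy as np
import pytest

from dimerscreen import (
    BundleSpec,
    DimerPoseSpec,
    build_ideal_bundle,
    fit_membrane_frame,
    layers_consistent,
    make_decoy,
    orientation_consistent,
    place_dimer,
    topology_filter,
)
from dimerscreen.geometry import rotation_about_axis
from dimerscreen.membrane import MembraneFrame
from dimerscreen.model import Protomer, Residue

from oracles import svd_plane_normal


def _angle_deg(u, v):
    c = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    return np.degrees(np.arccos(c))


class TestFitMembraneFrame:
    def test_ideal_bundle_normal_is_z(self, bundle7):
        frame = fit_membrane_frame(bundle7)
        assert _angle_deg(frame.normal, [0, 0, 1]) < 1e-4
        assert frame.fit_residual < 0.5

    def test_equivariance_under_rigid_motion(self, bundle7):
        R = rotation_about_axis([1, 2, 3], 53.0)
        t = np.array([10.0, -4.0, 7.0])
        f0 = fit_membrane_frame(bundle7)
        f1 = fit_membrane_frame(bundle7.transformed(R, t))
        assert np.allclose(f1.normal, R @ f0.normal, atol=1e-9)
        assert np.allclose(f1.midplane_point, R @ f0.midplane_point + t, atol=1e-9)

    def test_agrees_with_svd_plane_fit_on_tilted_helices(self, bundle7):
        # tilt each helix by an alternating +/-10 deg about x around its centre
        residues = []
        for seg in bundle7.tm_segments:
            seg_res = bundle7.segment_residues(seg)
            center = np.mean([r.ca for r in seg_res], axis=0)
            R = rotation_about_axis([1, 0, 0], 10.0 if seg.index % 2 else -10.0)
            for r in seg_res:
                residues.append(
                    Residue(r.chain_id, r.resseq, r.name,
                            [(n, R @ (x - center) + center) for n, x in r.atoms])
                )
        tilted = Protomer("A", residues, bundle7.tm_segments, "subject")
        frame = fit_membrane_frame(tilted)
        # oracle: least-squares plane through the per-helix CA midpoints
        # (a plane fit of all TM CAs is degenerate - the slab is thicker
        # than it is wide)
        midpoints = np.array([
            tilted.ca_coords([r.resseq for r in tilted.segment_residues(s)]).mean(axis=0)
            for s in tilted.tm_segments
        ])
        oracle = svd_plane_normal(midpoints)
        if oracle @ frame.normal < 0:
            oracle = -oracle
        assert _angle_deg(frame.normal, oracle) < 2.0

    def test_needs_two_tm_segments(self, bundle7):
        seg = bundle7.tm_segments[0]
        residues = [r for r in bundle7.residues if r.resseq in seg]
        single = Protomer("A", residues, [seg], "subject")
        with pytest.raises(ValueError, match="cannot infer membrane"):
            fit_membrane_frame(single)


class TestPairwiseRules:
    def test_identical_frames(self, bundle7):
        f = fit_membrane_frame(bundle7)
        ok, angle = orientation_consistent(f, f)
        assert ok and angle == pytest.approx(0.0, abs=1e-9)
        ok, offset = layers_consistent(f, f)
        assert ok and offset == pytest.approx(0.0, abs=1e-9)

    def test_flipped_normal_fails_orientation(self):
        f = MembraneFrame([0, 0, 1], [0, 0, 0])
        g = MembraneFrame([0, 0, -1], [0, 0, 0])
        ok, angle = orientation_consistent(f, g)
        assert not ok
        assert angle == pytest.approx(180.0)

    def test_constructed_20_degree_tilt_passes_at_30(self):
        R = rotation_about_axis([0, 1, 0], 20.0)
        f = MembraneFrame([0, 0, 1], [0, 0, 0])
        g = MembraneFrame(R @ np.array([0, 0, 1.0]), [0, 0, 0])
        ok, angle = orientation_consistent(f, g, 30.0)
        assert ok
        assert angle == pytest.approx(20.0, abs=1e-9)

    def test_orientation_symmetric(self):
        f = MembraneFrame([0, 0, 1], [0, 0, 0])
        g = MembraneFrame([0, 1, 1], [0, 0, 0])
        assert orientation_consistent(f, g)[1] == pytest.approx(
            orientation_consistent(g, f)[1]
        )

    @pytest.mark.parametrize("dz,tol,expect", [(15.0, 8.0, False), (5.0, 8.0, True)])
    def test_layer_offsets(self, dz, tol, expect):
        f = MembraneFrame([0, 0, 1], [0, 0, 0])
        g = MembraneFrame([0, 0, 1], [3.0, -2.0, dz])  # in-plane shift ignored
        ok, offset = layers_consistent(f, g, tol)
        assert ok is expect
        assert offset == pytest.approx(dz)


class TestTopologyFilter:
    def test_symmetric_homodimer_is_compliant(self, homodimer):
        report = topology_filter(homodimer)
        assert report.compliant
        assert report.rule_orientation.passed
        assert report.rule_layers.passed
        assert report.rule_symmetry.passed and report.rule_symmetry.applicable

    def test_flip_decoy_fails_only_orientation(self, homodimer):
        report = topology_filter(make_decoy(homodimer, "flip"))
        assert not report.compliant
        assert not report.rule_orientation.passed
        assert report.rule_layers.passed
        assert report.rule_symmetry.passed

    def test_heterodimer_symmetry_not_applicable(self, blocker_complex):
        report = topology_filter(blocker_complex)
        assert report.compliant
        assert not report.rule_symmetry.applicable

    def test_accepts_in_plane_rotated_placements(self, bundle7, bundle7_b):
        # protomers related by a rotation about the membrane normal plus an
        # in-plane translation are always topology-compliant
        for facing in [(1, 2), (3, 4), (6, 7)]:
            dimer = place_dimer(bundle7, bundle7_b, DimerPoseSpec(facing, facing))
            assert topology_filter(dimer).compliant
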