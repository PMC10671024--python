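"""Membrane-frame fitting and topology-compliance filtering.

A docked GPCR dimer pose is only physically meaningful if both protomers
could sit in the same lipid bilayer.  With no explicit membrane present,
the bilayer is inferred per protomer from its TM annotation: each TM
helix contributes an axis vector and the shared normal is the principal
direction of those axes (sign-corrected for the up/down alternation of a
serpentine bundle, odd TMs running extracellular to intracellular).

Three rules then triage a two-chain pose:

(i)   orientation - the two protomers' membrane normals agree to within
      ``orientation_tol_deg``;
(ii)  layers - the two inferred membrane midplanes coincide to within
      ``layer_tol_A`` measured along the mean normal;
(iii) symmetry - for a homodimer, both protomers contribute the same set
      of TM helices to the interface (not applicable to heterodimers).

The tolerances quantify rules that are stated only qualitatively in the
modelling literature; they are configurable and always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Thresholds
from .geometry import unit
from .model import ComplexModel, Protomer

__all__ = [
    "MembraneFrame",
    "RuleResult",
    "ComplianceReport",
    "fit_membrane_frame",
    "orientation_consistent",
    "layers_consistent",
    "topology_filter",
]


@dataclass(frozen=True)
class MembraneFrame:
    """A planar membrane model: unit normal (pointing extracellular),
    midplane point, slab half-thickness and the RMS residual of the
    per-helix midpoints about the midplane (all in Angstroms)."""

    normal: np.ndarray
    midplane_point: np.ndarray
    half_thickness: float = 15.0
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "normal", unit(self.normal))
        object.__setattr__(self, "midplane_point", np.asarray(self.midplane_point, float))
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")

    def height(self, point: np.ndarray) -> float:
        """Signed distance of a point from the midplane (positive = extracellular)."""
        return float((np.asarray(point, float) - self.midplane_point) @ self.normal)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MembraneFrame":
        R = np.asarray(rotation, float)
        return MembraneFrame(
            R @ self.normal,
            R @ self.midplane_point + np.asarray(translation, float),
            self.half_thickness,
            self.fit_residual,
        )


def fit_membrane_frame(
    protomer: Protomer,
    half_thickness: float = 15.0,
    end_window: int = 5,
) -> MembraneFrame:
    """Fit a membrane frame to a protomer from its TM segments.

    Each TM helix yields an axis from its intracellular-end to its
    extracellular-end C-alpha centroid (ends assigned by the serpentine
    convention: odd TMs have their N-terminal end extracellular).  The
    normal is the principal direction of the axis bundle, sign-fixed so
    the protomer's N-terminal residue sits on the positive (extracellular)
    side.  The midplane passes through the centroid of the per-helix
    C-alpha midpoints.
    """
    tms = [s for s in protomer.tm_segments if not s.is_h8]
    if len(tms) < 2:
        raise ValueError(
            f"chain {protomer.chain_id}: cannot infer membrane from "
            f"{len(tms)} TM segment(s); need at least 2"
        )
    axes = []
    midpoints = []
    for seg in tms:
        ca = protomer.ca_coords([r.resseq for r in protomer.segment_residues(seg)])
        if len(ca) < 2:
            raise ValueError(f"chain {protomer.chain_id}: {seg.label} has <2 CA atoms")
        if len(ca) > 18:
            # five ideal alpha-helical turns span 18 residues, so the mean
            # 18-residue offset cancels the CA spiral and tracks the axis
            raw = (ca[18:] - ca[:-18]).mean(axis=0)
        else:
            k = max(1, min(end_window, len(ca) // 3))
            raw = ca[-k:].mean(axis=0) - ca[:k].mean(axis=0)
        # raw points N->C; odd TMs run extracellular -> intracellular
        axis = -raw if seg.index % 2 == 1 else raw
        axes.append(unit(axis))
        midpoints.append(ca.mean(axis=0))
    axes = np.array(axes)
    midpoints = np.array(midpoints)

    # principal direction of the (sign-aligned) axis bundle
    _, _, vt = np.linalg.svd(axes, full_matrices=False)
    normal = vt[0]
    if normal @ axes.mean(axis=0) < 0:
        normal = -normal
    midplane = midpoints.mean(axis=0)

    # safeguard: the chain's N-terminus must be on the extracellular side
    n_term_ca = protomer.residues[0].ca
    if n_term_ca is not None and (n_term_ca - midplane) @ normal < 0:
        normal = -normal

    residual = float(np.sqrt(np.mean(((midpoints - midplane) @ normal) ** 2)))
    return MembraneFrame(normal, midplane, half_thickness, residual)


def orientation_consistent(
    frame_a: MembraneFrame, frame_b: MembraneFrame, tol_angle_deg: float = 30.0
) -> tuple[bool, float]:
    """Angle between two membrane normals; pass iff <= tolerance."""
    cosang = float(np.clip(frame_a.normal @ frame_b.normal, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return angle <= tol_angle_deg, angle


def layers_consistent(
    frame_a: MembraneFrame, frame_b: MembraneFrame, tol_offset_A: float = 8.0
) -> tuple[bool, float]:
    """Midplane offset along the mean normal; pass iff <= tolerance."""
    mean_normal = frame_a.normal + frame_b.normal
    if np.linalg.norm(mean_normal) < 1e-9:  # antiparallel normals
        mean_normal = frame_a.normal
    n = unit(mean_normal)
    offset = abs(float((frame_a.midplane_point - frame_b.midplane_point) @ n))
    return offset <= tol_offset_A, offset


@dataclass(frozen=True)
class RuleResult:
    passed: bool
    value: float | None = None
    applicable: bool = True
    detail: str = ""


@dataclass(frozen=True)
class ComplianceReport:
    rule_orientation: RuleResult
    rule_layers: RuleResult
    rule_symmetry: RuleResult
    subject_frame: MembraneFrame
    partner_frame: MembraneFrame

    @property
    def compliant(self) -> bool:
        return all(
            r.passed
            for r in (self.rule_orientation, self.rule_layers, self.rule_symmetry)
            if r.applicable
        )

    def summary(self) -> str:
        def fmt(name: str, r: RuleResult) -> str:
            if not r.applicable:
                return f"{name}: n/a"
            state = "pass" if r.passed else "FAIL"
            return f"{name}: {state} ({r.detail})" if r.detail else f"{name}: {state}"

        return "; ".join(
            [
                fmt("orientation", self.rule_orientation),
                fmt("layers", self.rule_layers),
                fmt("symmetry", self.rule_symmetry),
            ]
        )


def topology_filter(
    complex_model: ComplexModel, params: Thresholds | None = None
) -> ComplianceReport:
    """Apply the three topology-compliance rules to a two-chain pose."""
    from .interface import interface_residues  # local import to avoid a cycle

    params = params or Thresholds()
    frame_s = fit_membrane_frame(complex_model.subject)
    frame_p = fit_membrane_frame(complex_model.partner)

    ok_o, angle = orientation_consistent(frame_s, frame_p, params.orientation_tol_deg)
    rule_o = RuleResult(ok_o, angle, True, f"angle {angle:.1f} deg, tol {params.orientation_tol_deg:g}")

    ok_l, offset = layers_consistent(frame_s, frame_p, params.layer_tol_A)
    rule_l = RuleResult(ok_l, offset, True, f"offset {offset:.1f} A, tol {params.layer_tol_A:g}")

    if complex_model.is_homodimer:
        subj_iface, part_iface = interface_residues(complex_model, params.cutoff_A)
        helices = []
        for prot, iface in (
            (complex_model.subject, subj_iface),
            (complex_model.partner, part_iface),
        ):
            hs = set()
            for resseq in iface:
                seg = prot.segment_of(resseq)
                if seg is not None and not seg.is_h8:
                    hs.add(seg.index)
            helices.append(hs)
        same = helices[0] == helices[1]
        rule_sym = RuleResult(
            same, None, True,
            f"subject helices {sorted(helices[0])}, partner helices {sorted(helices[1])}",
        )
    else:
        rule_sym = RuleResult(True, None, False, "heterodimer")

    return ComplianceReport(rule_o, rule_l, rule_sym, frame_s, frame_p)
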