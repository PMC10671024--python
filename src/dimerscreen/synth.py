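"""Synthetic 7TM structures, dimer poses, decoys and energy tables.

This generator produces every input the triage pipeline consumes, in
place of AlphaFold/ClusPro/MD outputs: idealized transmembrane helix
bundles (full 7TM receptors and 2-5TM truncated isoforms), dimer poses
with a designed facing-helix interface, decoys that each violate exactly
one topology rule, and per-residue energy tables whose mass concentrates
on the designed interface.

The bundles are deliberately idealized: straight alpha-helices (backbone
N/CA/C/O plus a CB marker) on a circle, alternating up/down like a
serpentine membrane protein, with notional loops (numbering gaps, no
coordinates).  Each helix is built from a distinct marker residue type so
interface membership can be verified by sequence inspection.  This is
sufficient for every distance- and orientation-based criterion in the
pipeline; it does not emulate side-chain packing, loop geometry or
docking physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import rotation_about_axis, unit
from .model import (
    ComplexModel,
    EnergyTable,
    ModelDesignation,
    Protomer,
    Residue,
    TMSegment,
)
from .interface import interface_residues, residue_contact_counts

__all__ = [
    "BundleSpec",
    "DimerPoseSpec",
    "build_ideal_bundle",
    "place_dimer",
    "make_decoy",
    "synth_energy_table",
    "HELIX_MARKERS",
]

# one distinctive residue type per TM helix (plus H8) for easy inspection
HELIX_MARKERS = {1: "LEU", 2: "ILE", 3: "VAL", 4: "PHE", 5: "TRP", 6: "MET", 7: "TYR", 8: "ARG"}

# ideal alpha-helix cylindrical placement per backbone atom:
# (radius A, phase offset deg, z offset A) relative to the residue's CA
_ATOM_GEOMETRY = {
    "N": (1.56, -26.0, -0.93),
    "CA": (2.27, 0.0, 0.0),
    "C": (1.61, 27.0, 1.05),
    "O": (2.00, 29.0, 2.28),
    "CB": (3.32, -5.0, -0.40),
}


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of an idealized TM bundle.

    ``n_tm`` between 2 and 7 selects a full receptor (7) or a truncated
    Iso_XTM isoform.  The defaults give a 26-residue TM span (39 A, a
    typical bilayer crossing) with 6-residue notional loops.
    """

    n_tm: int = 7
    residues_per_tm: int = 26
    loop_len: int = 6
    bundle_radius: float = 12.0
    rise_per_res: float = 1.5
    twist_deg: float = 100.0
    ca_radius: float = 2.27
    h8_len: int = 0
    chain_id: str = "A"
    role: str = "subject"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_tm <= 7:
            raise ValueError(f"n_tm must be in [2, 7], got {self.n_tm}")
        for name in ("residues_per_tm", "loop_len", "bundle_radius", "rise_per_res"):
            if getattr(self, name) <= 0 and name != "loop_len":
                raise ValueError(f"{name} must be positive")
        if self.residues_per_tm < 6:
            raise ValueError("residues_per_tm must be at least 6")


@dataclass(frozen=True)
class DimerPoseSpec:
    """A designed dimer pose: which helices of each bundle face the
    interface, the separation between the facing helix axes, and an
    optional extra in-plane rotation of the partner."""

    facing_helices_subject: tuple[int, ...] = (4, 5)
    facing_helices_partner: tuple[int, ...] = (4, 5)
    axis_separation: float = 10.0
    in_plane_angle: float = 0.0
    seed: int = 0


def _helix_coords(
    n_res: int,
    axis_base: np.ndarray,
    direction_up: bool,
    rise: float,
    twist_deg: float,
    radius_scale: float,
    phase0_deg: float,
) -> list[dict[str, np.ndarray]]:
    """Atom coordinates of one straight helix centred vertically on z=0.

    The helix is built along +z then flipped about its own centre for
    down-running helices, and finally shifted to ``axis_base`` (x, y of
    the helix axis; the bundle midplane stays at z=0).
    """
    span = (n_res - 1) * rise
    out = []
    for j in range(n_res):
        atoms = {}
        for name, (r0, dphase, dz) in _ATOM_GEOMETRY.items():
            phase = np.deg2rad(phase0_deg + j * twist_deg + dphase)
            r = r0 * radius_scale
            x = np.array([r * np.cos(phase), r * np.sin(phase), j * rise + dz - span / 2.0])
            atoms[name] = x
        out.append(atoms)
    if not direction_up:
        flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about local x axis
        out = [{n: flip @ x for n, x in atoms.items()} for atoms in out]
    base = np.asarray(axis_base, float)
    return [{n: x + base for n, x in atoms.items()} for atoms in out]


def build_ideal_bundle(spec: BundleSpec) -> Protomer:
    """Build an idealized serpentine TM bundle as a Protomer.

    TM helices sit on a circle of ``bundle_radius`` at 2*pi/7 spacing
    (truncated bundles occupy the first ``n_tm`` positions), alternate
    up/down, and are joined by notional loops: loop residues advance the
    numbering but carry no coordinates, as in a PDB file with unresolved
    loops.  Odd TMs run extracellular (+z) to intracellular; the first
    residue of TM1 is the most extracellular, so the bundle's membrane
    normal is +z by construction.  Deterministic for a given spec.
    """
    residues: list[Residue] = []
    segments: list[TMSegment] = []
    resseq = 1
    angle_step = 2 * np.pi / 7
    for h in range(1, spec.n_tm + 1):
        theta = (h - 1) * angle_step
        base = np.array(
            [spec.bundle_radius * np.cos(theta), spec.bundle_radius * np.sin(theta), 0.0]
        )
        up = h % 2 == 0  # odd TMs run extracellular -> intracellular (downward)
        # seed a per-helix azimuth so equivalent helices are not in phase
        phase0 = 40.0 * h
        coords = _helix_coords(
            spec.residues_per_tm, base, up, spec.rise_per_res, spec.twist_deg,
            spec.ca_radius / _ATOM_GEOMETRY["CA"][0], phase0,
        )
        # residues are listed N->C; the flip inside _helix_coords already puts
        # a down helix's first (N-terminal) residue at the extracellular top
        start = resseq
        for atoms in coords:
            residues.append(
                Residue(
                    spec.chain_id, resseq, HELIX_MARKERS[h],
                    [(n, x) for n, x in atoms.items()],
                )
            )
            resseq += 1
        segments.append(TMSegment(h, start, resseq - 1))
        resseq += spec.loop_len  # notional loop: numbering gap only
    if spec.h8_len > 0:
        # short amphipathic helix lying in-plane at the intracellular rim
        theta = (spec.n_tm - 1) * angle_step
        span_z = (spec.residues_per_tm - 1) * spec.rise_per_res / 2.0
        base = np.array(
            [
                (spec.bundle_radius + 3.0) * np.cos(theta),
                (spec.bundle_radius + 3.0) * np.sin(theta),
                -(span_z + 4.0),
            ]
        )
        coords = _helix_coords(
            spec.h8_len, np.zeros(3), True, spec.rise_per_res, spec.twist_deg,
            spec.ca_radius / _ATOM_GEOMETRY["CA"][0], 0.0,
        )
        # lay the helix axis in the membrane plane, tangential to the bundle
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        xhat = np.cross(zhat, tangent)
        frame = np.column_stack([xhat, zhat, tangent])  # maps local z -> tangent
        start = resseq
        for atoms in coords:
            residues.append(
                Residue(
                    spec.chain_id, resseq, HELIX_MARKERS[8],
                    [(n, frame @ x + base) for n, x in atoms.items()],
                )
            )
            resseq += 1
        segments.append(TMSegment(8, start, resseq - 1, is_h8=True))
    return Protomer(spec.chain_id, residues, segments, spec.role)


def _bundle_center(protomer: Protomer) -> np.ndarray:
    ca = protomer.ca_coords(protomer.tm_resseqs())
    return ca.mean(axis=0)


def _facing_direction(protomer: Protomer, helices: tuple[int, ...]) -> tuple[np.ndarray, float]:
    """In-plane unit vector from the bundle centre toward the facing
    helices' axis centroid, and its in-plane distance."""
    center = _bundle_center(protomer)
    points = []
    for h in helices:
        seg = next(
            (s for s in protomer.tm_segments if s.index == h and not s.is_h8), None
        )
        if seg is None:
            raise ValueError(f"bundle has no TM{h} to face the interface")
        ca = protomer.ca_coords([r.resseq for r in protomer.segment_residues(seg)])
        points.append(ca.mean(axis=0))
    centroid = np.mean(points, axis=0)
    v = centroid - center
    v[2] = 0.0
    return unit(v), float(np.linalg.norm(v))


def place_dimer(
    bundle_a: Protomer,
    bundle_b: Protomer,
    pose: DimerPoseSpec | None = None,
    designation: ModelDesignation | None = None,
    complex_name: str = "",
    max_interpenetration: int = 25,
) -> ComplexModel:
    """Pose two bundles as a membrane-plane dimer with a designed interface.

    ``bundle_b`` is rotated about its own vertical axis so its facing
    helices point at ``bundle_a``'s facing helices, then translated in
    the membrane plane until the facing helix axes are
    ``pose.axis_separation`` apart.  Both bundles keep their membrane
    frame (normal +z), so a compliant pose results by construction.
    """
    pose = pose or DimerPoseSpec()
    u_a, r_a = _facing_direction(bundle_a, pose.facing_helices_subject)
    u_b, r_b = _facing_direction(bundle_b, pose.facing_helices_partner)

    # rotate B about its own axis so its facing direction is -u_a
    target = np.arctan2(-u_a[1], -u_a[0])
    current = np.arctan2(u_b[1], u_b[0])
    gamma = np.degrees(target - current) + pose.in_plane_angle
    Rz = rotation_about_axis([0, 0, 1], gamma)
    center_b = _bundle_center(bundle_b)
    center_a = _bundle_center(bundle_a)
    distance = r_a + r_b + pose.axis_separation
    new_center = center_a + distance * u_a
    translation = new_center - Rz @ center_b
    partner = bundle_b.transformed(Rz, translation)
    if partner.chain_id == bundle_a.chain_id:
        partner = partner.with_chain_id("B" if bundle_a.chain_id != "B" else "C")
    if partner.role == "subject":
        partner = Protomer(partner.chain_id, partner.residues, partner.tm_segments, "partner")

    subject = bundle_a
    if subject.role != "subject":
        subject = Protomer(subject.chain_id, subject.residues, subject.tm_segments, "subject")

    model = ComplexModel(
        subject, partner,
        designation or ModelDesignation("cluspro", "balanced", 1),
        complex_name=complex_name or "synthetic-dimer",
    )
    # interpenetration guard
    from .interface import _contact_pairs

    n_clashes = sum(1 for _, _, d in _contact_pairs(model, 1.8))
    if n_clashes > max_interpenetration:
        raise ValueError(
            f"axis separation {pose.axis_separation} A interpenetrates the bundles "
            f"({n_clashes} heavy-atom pairs below 1.8 A)"
        )
    return model


def make_decoy(
    complex_model: ComplexModel,
    mode: str,
    magnitude: float | None = None,
    seed: int = 0,
) -> ComplexModel:
    """Derive a topology decoy from a compliant pose.

    - ``flip``: partner turned upside down (180 deg about an in-plane
      axis through its centre) - violates the orientation rule.
    - ``offset``: partner translated ``magnitude`` A (default 15) along
      the membrane normal - violates the layer rule.
    - ``tilt``: partner tilted ``magnitude`` deg (default 10) about an
      in-plane axis - compliant at default tolerances.
    - ``asymmetric``: partner spun about its own vertical axis by
      ``magnitude`` deg (default two helix positions, ~102.9) so a
      different helix set faces the subject - violates homodimer
      interface symmetry.
    """
    partner = complex_model.partner
    center = _bundle_center(partner)
    if mode == "flip":
        R = rotation_about_axis([1, 0, 0], 180.0)
        t = center - R @ center
    elif mode == "offset":
        magnitude = 15.0 if magnitude is None else magnitude
        R = np.eye(3)
        t = np.array([0.0, 0.0, magnitude])
    elif mode == "tilt":
        magnitude = 10.0 if magnitude is None else magnitude
        R = rotation_about_axis([1, 0, 0], magnitude)
        t = center - R @ center
    elif mode == "asymmetric":
        magnitude = 2 * 360.0 / 7 if magnitude is None else magnitude
        R = rotation_about_axis([0, 0, 1], magnitude)
        t = center - R @ center
    else:
        raise ValueError(f"unknown decoy mode {mode!r}")
    return ComplexModel(
        complex_model.subject,
        partner.transformed(R, t),
        complex_model.designation,
        complex_model.bfe,
        complex_model.energy_table,
        (complex_model.complex_name or "synthetic-dimer") + f"-{mode}-decoy",
    )


def synth_energy_table(
    complex_model: ComplexModel,
    total_bfe_mean: float,
    interface_frac: float = 0.9,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> EnergyTable:
    """Seeded per-residue energy table concentrated on the interface.

    ``interface_frac`` of the total is spread over interface residues of
    both protomers proportionally to their heavy-atom contact counts; the
    remainder is spread uniformly over all other residues.  Gaussian
    noise of scale ``noise_sd`` (kcal/mol) is added per residue.
    """
    if total_bfe_mean >= 0:
        raise ValueError("total_bfe_mean must be negative (favorable binding)")
    subj_counts, part_counts = residue_contact_counts(complex_model, 5.0)
    if not subj_counts and not part_counts:
        raise ValueError("complex has an empty interface; no table to synthesise")
    rng = np.random.default_rng(seed)
    weights: dict[tuple[str, int], float] = {}
    for prot, counts in (
        (complex_model.subject, subj_counts),
        (complex_model.partner, part_counts),
    ):
        for resseq, c in counts.items():
            weights[(prot.chain_id, resseq)] = float(c)
    wsum = sum(weights.values())
    table: dict[tuple[str, int], float] = {}
    others = []
    for prot in complex_model.protomers:
        for r in prot.residues:
            key = (prot.chain_id, r.resseq)
            if key not in weights:
                others.append(key)
    for key, w in weights.items():
        table[key] = total_bfe_mean * interface_frac * w / wsum
    rest = total_bfe_mean * (1.0 - interface_frac)
    for key in others:
        table[key] = rest / len(others) if others else 0.0
    noise = rng.normal(0.0, noise_sd, size=len(table))
    for i, key in enumerate(sorted(table)):
        table[key] += noise[i]
    return EnergyTable(table)
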