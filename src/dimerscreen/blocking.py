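"""Competitive dimerization and isoform-blocking analysis.

A truncated isoform "blocks" a dimerization interface when (i) the
interface it occupies on the shared subject receptor significantly
overlaps the dimer's interface on that subject, and (ii) it binds the
subject with a free energy lower than, or close to, the dimer's.  Both
criteria are evaluated on the subject protomer: residue-set overlap for
rule (i) and MMPBSA mean binding free energies for rule (ii).  "Close"
is an additive allowance (``delta_close``) on the means; SEMs are carried
through for reporting but do not enter the decision.

Rigid superposition of two complexes on their shared subject (Kabsch over
common TM C-alpha atoms) is provided for steric inspection and for
anchoring oligomer extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import networkx as nx
import numpy as np

from .config import Thresholds
from .geometry import kabsch
from .interface import interface_residues
from .model import BindingEnergy, ComplexModel

__all__ = [
    "Superposition",
    "superpose_on_subject",
    "OverlapResult",
    "interface_overlap",
    "BlockingVerdict",
    "blocking_call",
    "blocking_verdict",
    "competition_groups",
]


@dataclass(frozen=True)
class Superposition:
    """Rigid map ``x -> R x + t`` with the RMSD over the fitted atoms."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose_on_subject(
    complex_a: ComplexModel, complex_b: ComplexModel
) -> Superposition:
    """Superpose ``complex_b`` onto ``complex_a`` via their shared subject.

    The fit uses C-alpha atoms of subject TM residues present in both
    models (the subjects must be the same receptor).
    """
    if complex_a.subject.sequence != complex_b.subject.sequence:
        raise ValueError(
            "complexes do not share a subject: "
            f"{complex_a.complex_name!r} vs {complex_b.complex_name!r}"
        )
    resseqs_a = set(complex_a.subject.tm_resseqs(include_h8=True))
    resseqs_b = set(complex_b.subject.tm_resseqs(include_h8=True))
    common = sorted(resseqs_a & resseqs_b)
    fixed = complex_a.subject.ca_coords(
        [r for r in common if complex_a.subject.residue(r).ca is not None]
    )
    moving = complex_b.subject.ca_coords(
        [r for r in common if complex_b.subject.residue(r).ca is not None]
    )
    if len(fixed) < 3 or len(fixed) != len(moving):
        raise ValueError(
            f"need >=3 common subject TM CA atoms, got {min(len(fixed), len(moving))}"
        )
    R, t, rmsd = kabsch(moving, fixed)
    return Superposition(R, t, rmsd, len(fixed))


@dataclass(frozen=True)
class OverlapResult:
    """Set overlap between two interfaces on the same subject numbering."""

    shared: int
    jaccard: float
    frac_of_dimer: float


def interface_overlap(
    dimer_iface: set[Hashable], blocker_iface: set[Hashable]
) -> OverlapResult:
    """Overlap of a blocker's subject interface with a dimer's.

    ``frac_of_dimer`` is the fraction of the dimer interface covered by
    the blocker; both sets must use the same subject numbering.
    """
    dimer = set(dimer_iface)
    blocker = set(blocker_iface)
    if not dimer:
        raise ValueError("dimer interface is empty")
    inter = dimer & blocker
    union = dimer | blocker
    return OverlapResult(
        shared=len(inter),
        jaccard=len(inter) / len(union),
        frac_of_dimer=len(inter) / len(dimer),
    )


@dataclass(frozen=True)
class BlockingVerdict:
    blocks: bool
    overlap: OverlapResult
    overlap_pass: bool
    energy_pass: bool
    bfe_dimer: BindingEnergy
    bfe_blocker: BindingEnergy
    delta_used: float
    overlap_min_used: float


def blocking_call(
    overlap: OverlapResult,
    bfe_dimer: BindingEnergy,
    bfe_blocker: BindingEnergy,
    params: Thresholds | None = None,
) -> BlockingVerdict:
    """Issue a blocking verdict from precomputed overlap and energies."""
    params = params or Thresholds()
    overlap_pass = overlap.frac_of_dimer >= params.overlap_min
    energy_pass = bfe_blocker.mean <= bfe_dimer.mean + params.delta_close
    return BlockingVerdict(
        blocks=overlap_pass and energy_pass,
        overlap=overlap,
        overlap_pass=overlap_pass,
        energy_pass=energy_pass,
        bfe_dimer=bfe_dimer,
        bfe_blocker=bfe_blocker,
        delta_used=params.delta_close,
        overlap_min_used=params.overlap_min,
    )


def blocking_verdict(
    dimer: ComplexModel,
    blocker: ComplexModel,
    params: Thresholds | None = None,
) -> BlockingVerdict:
    """Can ``blocker`` (a subject-isoform complex) block ``dimer``?

    Both complexes must share the subject receptor and carry binding free
    energies; interfaces are computed on the subject protomer.
    """
    params = params or Thresholds()
    if dimer.subject.sequence != blocker.subject.sequence:
        raise ValueError("dimer and blocker must share the same subject receptor")
    if dimer.bfe is None or blocker.bfe is None:
        raise ValueError("both complexes need a binding free energy for a verdict")
    dimer_iface, _ = interface_residues(dimer, params.cutoff_A)
    blocker_iface, _ = interface_residues(blocker, params.cutoff_A)
    overlap = interface_overlap(dimer_iface, blocker_iface)
    return blocking_call(overlap, dimer.bfe, blocker.bfe, params)


def competition_groups(
    complexes: Sequence[ComplexModel],
    params: Thresholds | None = None,
) -> list[list[int]]:
    """Groups of models competing for the same surface on a shared subject.

    Two models are connected when each covers at least ``overlap_min`` of
    the other's subject interface; groups are connected components with
    at least two members.  Returns lists of indices into ``complexes``.
    """
    params = params or Thresholds()
    ifaces = []
    for c in complexes:
        subj, _ = interface_residues(c, params.cutoff_A)
        ifaces.append(subj)
    g = nx.Graph()
    g.add_nodes_from(range(len(complexes)))
    for i in range(len(complexes)):
        for j in range(i + 1, len(complexes)):
            if complexes[i].subject.sequence != complexes[j].subject.sequence:
                continue
            if not ifaces[i] or not ifaces[j]:
                continue
            ab = interface_overlap(ifaces[i], ifaces[j]).frac_of_dimer
            ba = interface_overlap(ifaces[j], ifaces[i]).frac_of_dimer
            if ab >= params.overlap_min and ba >= params.overlap_min:
                g.add_edge(i, j)
    return sorted(
        [sorted(comp) for comp in nx.connected_components(g) if len(comp) >= 2]
    )
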