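"""Higher-order oligomer assembly with steric clash checking.

Oligomers are grown by chaining dimer models on shared protomers: the
subject of a dimer model is superposed onto an already-placed protomer
(the anchor) and the partner is added with the induced rigid transform.
Anchors never move, so a chain with alternating interfaces can be
extended indefinitely as long as each new protomer lands clash-free.

A clash is any heavy-atom pair closer than ``clash_cutoff_A`` (default
2.0 A) between two placements - except pairs of residues that form the
designed interface between a parent and its child, which are expected to
be in contact.  The builder only detects clashes; it never repairs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .config import Thresholds
from .geometry import kabsch
from .interface import interface_residues
from .model import ComplexModel, ModelDesignation, Protomer

__all__ = ["Placement", "ClashPair", "OligomerAssembly", "extend_oligomer", "clash_check"]

_CHAIN_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class Placement:
    label: str
    protomer: Protomer
    source_designation: str
    rotation: np.ndarray
    translation: np.ndarray
    parent_label: str | None = None
    # resseqs of the designed parent/child interface (exempt from clash checks)
    interface_on_parent: frozenset[int] = frozenset()
    interface_on_self: frozenset[int] = frozenset()


@dataclass(frozen=True)
class ClashPair:
    label_a: str
    resseq_a: int
    label_b: str
    resseq_b: int
    min_distance: float


class OligomerAssembly:
    """An ordered set of placed protomers grown from a seed."""

    def __init__(self, placements: list[Placement]):
        if not placements:
            raise ValueError("assembly needs at least the seed placement")
        self.placements = list(placements)
        labels = [p.label for p in self.placements]
        if len(set(labels)) != len(labels):
            raise ValueError("placement labels must be unique")

    @classmethod
    def seed(cls, protomer: Protomer, label: str = "A") -> "OligomerAssembly":
        return cls(
            [
                Placement(
                    label, protomer, "seed",
                    np.eye(3), np.zeros(3), None,
                )
            ]
        )

    def placement(self, label: str) -> Placement:
        for p in self.placements:
            if p.label == label:
                return p
        raise KeyError(f"no placement labelled {label!r} in assembly")

    def __len__(self) -> int:
        return len(self.placements)

    def extend(
        self,
        dimer_model: ComplexModel,
        anchor_label: str,
        new_label: str | None = None,
        cutoff_A: float = 5.0,
    ) -> "OligomerAssembly":
        """Return a new assembly with the dimer's partner added at the anchor.

        The dimer's subject must be the same receptor as the anchor
        protomer; the anchor's coordinates are untouched.
        """
        anchor = self.placement(anchor_label)
        if dimer_model.subject.sequence != anchor.protomer.sequence:
            raise ValueError(
                f"dimer subject sequence does not match anchor {anchor_label!r}"
            )
        if new_label is None:
            used = {p.label for p in self.placements}
            new_label = next(c for c in _CHAIN_NAMES if c not in used)

        common = sorted(
            set(dimer_model.subject.tm_resseqs(include_h8=True))
            & set(anchor.protomer.tm_resseqs(include_h8=True))
        )
        moving = dimer_model.subject.ca_coords(common)
        fixed = anchor.protomer.ca_coords(common)
        if len(moving) < 3:
            raise ValueError("need >=3 common TM CA atoms to anchor the extension")
        R, t, _ = kabsch(moving, fixed)

        subj_iface, part_iface = interface_residues(dimer_model, cutoff_A)
        placed = dimer_model.partner.transformed(R, t).with_chain_id(new_label)
        placement = Placement(
            new_label, placed, dimer_model.designation.label, R, t,
            parent_label=anchor_label,
            interface_on_parent=frozenset(subj_iface),
            interface_on_self=frozenset(part_iface),
        )
        return OligomerAssembly(self.placements + [placement])

    # -- clash detection --------------------------------------------------

    def clash_check(self, clash_cutoff_A: float = 2.0) -> list[ClashPair]:
        """All clashing residue pairs between placements.

        For adjacent (parent/child) placements, residue pairs belonging to
        their designed interface are exempt; everything else closer than
        the cutoff is reported with its minimum distance.
        """
        if len(self.placements) < 2:
            raise ValueError("clash check needs at least 2 placements")
        clashes: dict[tuple[str, int, str, int], float] = {}
        for ia in range(len(self.placements)):
            for ib in range(ia + 1, len(self.placements)):
                a, b = self.placements[ia], self.placements[ib]
                adjacent = (a.parent_label == b.label) or (b.parent_label == a.label)
                xa, ra = a.protomer.atom_array()
                xb, rb = b.protomer.atom_array()
                pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), clash_cutoff_A)
                for i, js in enumerate(pairs):
                    for j in js:
                        d = float(np.linalg.norm(xa[i] - xb[j]))
                        if d >= clash_cutoff_A:
                            continue
                        if adjacent:
                            child, child_res, parent_res = (
                                (b, rb[j], ra[i]) if b.parent_label == a.label
                                else (a, ra[i], rb[j])
                            )
                            if (
                                child_res in child.interface_on_self
                                and parent_res in child.interface_on_parent
                            ):
                                continue
                        key = (a.label, int(ra[i]), b.label, int(rb[j]))
                        if key not in clashes or d < clashes[key]:
                            clashes[key] = d
        return [
            ClashPair(la, res_a, lb, res_b, d)
            for (la, res_a, lb, res_b), d in sorted(clashes.items())
        ]

    def is_clash_free(self, clash_cutoff_A: float = 2.0) -> bool:
        return not self.clash_check(clash_cutoff_A)

    # -- output -----------------------------------------------------------

    def write_pdb(self, path: str | Path) -> Path:
        """Write the assembly as a multi-chain PDB (chains renamed A, B, C...)."""
        import gemmi

        st = gemmi.Structure()
        st.name = "oligomer"
        gm = gemmi.Model("1")
        for placement, chain_name in zip(self.placements, _CHAIN_NAMES):
            ch = gemmi.Chain(chain_name)
            for r in placement.protomer.residues:
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.resseq, " ")
                for atom_name, xyz in r.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom_name
                    ga.element = gemmi.Element(atom_name[:1])
                    ga.pos = gemmi.Position(*map(float, xyz))
                    ga.occ = 1.0
                    gr.add_atom(ga)
                ch.add_residue(gr)
            gm.add_chain(ch)
        st.add_model(gm)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        st.write_pdb(str(path))
        return path


def extend_oligomer(
    assembly: OligomerAssembly,
    dimer_model: ComplexModel,
    anchor_label: str,
    new_label: str | None = None,
) -> OligomerAssembly:
    """Functional wrapper around :meth:`OligomerAssembly.extend`."""
    return assembly.extend(dimer_model, anchor_label, new_label)


def clash_check(
    assembly: OligomerAssembly, clash_cutoff_A: float = 2.0
) -> list[ClashPair]:
    """Functional wrapper around :meth:`OligomerAssembly.clash_check`."""
    return assembly.clash_check(clash_cutoff_A)
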