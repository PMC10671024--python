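"""Interface detection, helix ranking and interface-string formatting.

An interface residue is any residue with a heavy atom strictly closer
than the cutoff (default 5 A) to a heavy atom of the opposite protomer.
Helix-level contributions are ranked either by summed per-residue binding
energy (when an MMPBSA-style decomposition table is available) or by the
number of interface residues in the helix (contact-count fallback), and
formatted in the conventional table dialect, e.g.::

    TM2, TM1, TM3 (E), TM4 (I)

where the parenthesised qualifier marks interfaces confined to the
extracellular (E), middle (M) or intracellular (I) third of the helix.
Loops and Helix 8 take part in contact computation but are left out of
the ranking and the formatted string (only TM helices are shown).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Thresholds
from .membrane import MembraneFrame, fit_membrane_frame
from .model import ComplexModel, EnergyTable, Protomer

__all__ = [
    "interface_residues",
    "residue_contact_counts",
    "significant_residues",
    "HelixContribution",
    "helix_contributions",
    "segment_qualifier",
    "format_interface_string",
    "parse_interface_string",
    "InterfaceProfile",
    "interface_profile",
]


def _contact_pairs(
    complex_model: ComplexModel, cutoff: float
) -> list[tuple[int, int, float]]:
    """All cross-protomer heavy-atom contacts (subject resseq, partner
    resseq, distance) with distance strictly below the cutoff."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    xs, rs = complex_model.subject.atom_array()
    xp, rp = complex_model.partner.atom_array()
    tree_s = cKDTree(xs)
    tree_p = cKDTree(xp)
    out = []
    for i, js in enumerate(tree_s.query_ball_tree(tree_p, cutoff)):
        for j in js:
            d = float(np.linalg.norm(xs[i] - xp[j]))
            if d < cutoff:
                out.append((int(rs[i]), int(rp[j]), d))
    return out


def interface_residues(
    complex_model: ComplexModel, cutoff_A: float = 5.0
) -> tuple[set[int], set[int]]:
    """Residues of each protomer within ``cutoff_A`` of the other.

    Returns ``(subject_resseqs, partner_resseqs)``.
    """
    pairs = _contact_pairs(complex_model, cutoff_A)
    return {s for s, _, _ in pairs}, {p for _, p, _ in pairs}


def residue_contact_counts(
    complex_model: ComplexModel, cutoff_A: float = 5.0
) -> tuple[dict[int, int], dict[int, int]]:
    """Number of cross-protomer heavy-atom contacts per residue."""
    subject: dict[int, int] = {}
    partner: dict[int, int] = {}
    for s, p, _ in _contact_pairs(complex_model, cutoff_A):
        subject[s] = subject.get(s, 0) + 1
        partner[p] = partner.get(p, 0) + 1
    return subject, partner


def significant_residues(
    energy_table: EnergyTable, threshold: float = -1.0
) -> set[tuple[str, int]]:
    """Residues whose per-residue contribution is strictly below ``threshold``
    (default -1 kcal/mol), i.e. those that positively contribute to binding."""
    return {key for key, value in energy_table.items() if value < threshold}


@dataclass(frozen=True)
class HelixContribution:
    index: int
    score: float
    n_residues: int
    qualifier: str | None = None  # 'E' | 'M' | 'I' | None


def helix_contributions(
    complex_model: ComplexModel,
    interface: set[int] | None = None,
    energy_table: EnergyTable | None = None,
    cutoff_A: float = 5.0,
    protomer: str = "subject",
) -> list[HelixContribution]:
    """Ranked TM-helix contributions to the interface on one protomer.

    The score is the summed negated per-residue energy over the helix's
    interface residues when a decomposition table is given, otherwise the
    count of interface residues in the helix.  Helices are sorted by
    descending score; ties break toward the lower helix index.  Loops and
    Helix 8 are excluded.
    """
    prot: Protomer = getattr(complex_model, protomer)
    if interface is None:
        subj, part = interface_residues(complex_model, cutoff_A)
        interface = subj if protomer == "subject" else part
    per_helix: dict[int, list[int]] = {}
    for resseq in interface:
        seg = prot.segment_of(resseq)
        if seg is None or seg.is_h8:
            continue
        per_helix.setdefault(seg.index, []).append(resseq)
    out = []
    for index, resseqs in per_helix.items():
        if energy_table is not None:
            score = float(
                sum(-energy_table.get((prot.chain_id, r), 0.0) for r in resseqs)
            )
        else:
            score = float(len(resseqs))
        out.append(HelixContribution(index, score, len(resseqs)))
    out.sort(key=lambda h: (-h.score, h.index))
    return out


def segment_qualifier(
    protomer: Protomer,
    helix_index: int,
    helix_interface_resseqs: set[int],
    frame: MembraneFrame,
    qualifier_frac: float = 0.6,
) -> str | None:
    """E/M/I qualifier for one helix's interface patch.

    The helix span along the membrane normal is split into three equal
    thirds (extracellular, middle, intracellular).  If at least
    ``qualifier_frac`` of the helix's interface residues fall in a single
    third, that third's letter is returned; otherwise None, meaning the
    majority of the helix is involved.
    """
    seg = next(
        (s for s in protomer.tm_segments if s.index == helix_index and not s.is_h8),
        None,
    )
    if seg is None:
        raise ValueError(f"chain {protomer.chain_id} has no TM{helix_index}")
    if not helix_interface_resseqs:
        return None
    heights = {
        r.resseq: frame.height(r.ca)
        for r in protomer.segment_residues(seg)
        if r.ca is not None
    }
    lo = min(heights.values())
    hi = max(heights.values())
    if hi - lo < 1e-9:
        return None
    third = (hi - lo) / 3.0
    counts = {"E": 0, "M": 0, "I": 0}
    n = 0
    for resseq in helix_interface_resseqs:
        if resseq not in heights:
            continue
        h = heights[resseq]
        if h >= hi - third:
            counts["E"] += 1
        elif h <= lo + third:
            counts["I"] += 1
        else:
            counts["M"] += 1
        n += 1
    if n == 0:
        return None
    best = max(counts, key=lambda k: (counts[k], k))
    if counts[best] / n >= qualifier_frac:
        return best
    return None


def format_interface_string(ranked: list) -> str:
    """Format a ranked helix list as e.g. 'TM2, TM1, TM3 (E), TM4 (I)'.

    Accepts :class:`HelixContribution` items or ``(index, qualifier)``
    pairs.
    """
    parts = []
    for item in ranked:
        if isinstance(item, HelixContribution):
            index, qualifier = item.index, item.qualifier
        else:
            index, qualifier = item
        text = f"TM{index}"
        if qualifier:
            text += f" ({qualifier})"
        parts.append(text)
    return ", ".join(parts)


_TOKEN_RE = re.compile(r"^TM(\d+)\s*(?:\(\s*([EMI])\s*\))?$")


def parse_interface_string(text: str) -> list[tuple[int, str | None]]:
    """Parse an interface string back into (helix index, qualifier) pairs.

    Tolerates missing whitespace before the qualifier ('TM4(I)').
    """
    text = text.strip()
    if not text:
        return []
    out = []
    for token in text.split(","):
        m = _TOKEN_RE.match(token.strip())
        if not m:
            raise ValueError(f"cannot parse interface token {token.strip()!r}")
        out.append((int(m.group(1)), m.group(2)))
    return out


@dataclass(frozen=True)
class InterfaceProfile:
    """Full characterisation of the interface on the subject protomer."""

    subject_residues: frozenset[int]
    partner_residues: frozenset[int]
    helix_ranking: tuple[HelixContribution, ...]
    interface_string: str
    cutoff_A: float


def interface_profile(
    complex_model: ComplexModel,
    params: Thresholds | None = None,
    frame: MembraneFrame | None = None,
) -> InterfaceProfile:
    """Compute the subject-side interface profile of a complex model."""
    params = params or Thresholds()
    subj_iface, part_iface = interface_residues(complex_model, params.cutoff_A)
    ranking = helix_contributions(
        complex_model,
        interface=subj_iface,
        energy_table=complex_model.energy_table,
        cutoff_A=params.cutoff_A,
    )
    if ranking:
        if frame is None:
            frame = fit_membrane_frame(complex_model.subject)
        qualified = []
        for h in ranking:
            seg = next(
                s for s in complex_model.subject.tm_segments
                if s.index == h.index and not s.is_h8
            )
            in_helix = {r for r in subj_iface if r in seg}
            q = segment_qualifier(
                complex_model.subject, h.index, in_helix, frame, params.qualifier_frac
            )
            qualified.append(HelixContribution(h.index, h.score, h.n_residues, q))
        ranking = qualified
    return InterfaceProfile(
        frozenset(subj_iface),
        frozenset(part_iface),
        tuple(ranking),
        format_interface_string(ranking),
        params.cutoff_A,
    )
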