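"""Domain types for dimer-model triage.

The objects here mirror how structural work on GPCR dimers is organised:
a :class:`Protomer` is one receptor chain (full-length or a truncated
``Iso_XTM`` splice isoform) with its transmembrane (TM) annotation, and a
:class:`ComplexModel` is a two-chain docked or predicted complex together
with its provenance label and, when available, an MMPBSA binding free
energy and a per-residue energy decomposition.

Coordinates are stored in Angstroms, heavy atoms only.  Residue numbering
is taken verbatim from the input file; TM ranges are 1-based inclusive in
that numbering (the UniProt convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Residue",
    "TMSegment",
    "Protomer",
    "ModelDesignation",
    "BindingEnergy",
    "EnergyTable",
    "ComplexModel",
    "three_to_one",
]

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def three_to_one(name: str) -> str:
    """Map a 3-letter residue name to a 1-letter code ('X' if unknown)."""
    return _AA_3TO1.get(name.upper(), "X")


@dataclass
class Residue:
    """One amino-acid residue with its heavy atoms.

    ``atoms`` is a list of ``(atom_name, xyz)`` pairs; ``xyz`` is a
    float array of shape (3,) in Angstroms.
    """

    chain_id: str
    resseq: int
    name: str
    atoms: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.name}{self.resseq} of chain {self.chain_id} has no atoms"
            )
        self.atoms = [(n, np.asarray(x, dtype=float)) for n, x in self.atoms]

    @property
    def ca(self) -> np.ndarray | None:
        for n, x in self.atoms:
            if n == "CA":
                return x
        return None

    def coords(self) -> np.ndarray:
        return np.array([x for _, x in self.atoms], dtype=float)


@dataclass(frozen=True)
class TMSegment:
    """A transmembrane helix annotation (1-based inclusive residue range).

    ``index`` is the TM number (1..7).  The short intracellular amphipathic
    Helix 8 is carried with ``index=8, is_h8=True``; it never counts toward
    ``n_tm`` and is left out of interface strings, but its residues do take
    part in contact computations.
    """

    index: int
    start: int
    end: int
    is_h8: bool = False

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"TM index must be >= 1, got {self.index}")
        if self.start > self.end:
            raise ValueError(
                f"TM{self.index}: start {self.start} > end {self.end}"
            )

    def __contains__(self, resseq: int) -> bool:
        return self.start <= resseq <= self.end

    @property
    def label(self) -> str:
        return "H8" if self.is_h8 else f"TM{self.index}"


class Protomer:
    """One chain of a complex: residues, sequence, TM annotation and role.

    ``role`` is one of ``subject`` (the receptor whose interface is being
    characterised), ``partner`` (the other full-length receptor) or
    ``isoform`` (a truncated splice variant acting as candidate blocker).
    """

    ROLES = ("subject", "partner", "isoform")

    def __init__(
        self,
        chain_id: str,
        residues: Sequence[Residue],
        tm_segments: Sequence[TMSegment],
        role: str = "subject",
    ) -> None:
        if role not in self.ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {self.ROLES}")
        if not residues:
            raise ValueError(f"chain {chain_id}: no residues")
        self.chain_id = chain_id
        self.residues = sorted(residues, key=lambda r: r.resseq)
        seen: set[int] = set()
        for r in self.residues:
            if r.resseq in seen:
                raise ValueError(f"chain {chain_id}: duplicate resseq {r.resseq}")
            seen.add(r.resseq)
        self._by_resseq = {r.resseq: r for r in self.residues}
        self.tm_segments = self._check_segments(tm_segments)
        self.role = role
        self._atom_cache: tuple[np.ndarray, np.ndarray] | None = None

    def _check_segments(self, segments: Sequence[TMSegment]) -> list[TMSegment]:
        segs = sorted(segments, key=lambda s: s.index)
        for a, b in zip(segs, segs[1:]):
            if a.index == b.index:
                raise ValueError(f"chain {self.chain_id}: duplicate TM index {a.index}")
            if a.end >= b.start:
                raise ValueError(
                    f"chain {self.chain_id}: {a.label} ({a.start}-{a.end}) overlaps "
                    f"{b.label} ({b.start}-{b.end})"
                )
        for s in segs:
            if not any(s.start <= r <= s.end for r in self._by_resseq):
                raise ValueError(
                    f"chain {self.chain_id}: {s.label} range {s.start}-{s.end} maps to "
                    f"no residues (numbering {self.residues[0].resseq}-"
                    f"{self.residues[-1].resseq})"
                )
        return segs

    # -- basic properties -------------------------------------------------

    @property
    def n_tm(self) -> int:
        return sum(1 for s in self.tm_segments if not s.is_h8 and s.index <= 7)

    @property
    def sequence(self) -> str:
        return "".join(three_to_one(r.name) for r in self.residues)

    @property
    def isoform_name(self) -> str:
        """'Iso_{n}TM' naming used for truncated isoforms."""
        return f"Iso_{self.n_tm}TM"

    def residue(self, resseq: int) -> Residue:
        return self._by_resseq[resseq]

    def has_residue(self, resseq: int) -> bool:
        return resseq in self._by_resseq

    def segment_of(self, resseq: int) -> TMSegment | None:
        for s in self.tm_segments:
            if resseq in s:
                return s
        return None

    def segment_residues(self, segment: TMSegment) -> list[Residue]:
        return [r for r in self.residues if r.resseq in segment]

    # -- coordinate access ------------------------------------------------

    def atom_array(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and the resseq of each atom.

        Returns ``(coords, resseqs)`` with shapes (n_atoms, 3) and (n_atoms,).
        """
        if self._atom_cache is None:
            coords = []
            owners = []
            for r in self.residues:
                for _, x in r.atoms:
                    coords.append(x)
                    owners.append(r.resseq)
            self._atom_cache = (np.array(coords, float), np.array(owners, int))
        return self._atom_cache

    def ca_coords(self, resseqs: Iterable[int] | None = None) -> np.ndarray:
        """C-alpha coordinates for the given residues (all residues if None)."""
        if resseqs is None:
            resseqs = [r.resseq for r in self.residues]
        pts = []
        for i in resseqs:
            ca = self._by_resseq[i].ca
            if ca is not None:
                pts.append(ca)
        return np.array(pts, float)

    def tm_resseqs(self, include_h8: bool = False) -> list[int]:
        out = []
        for s in self.tm_segments:
            if s.is_h8 and not include_h8:
                continue
            out.extend(r.resseq for r in self.segment_residues(s))
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Protomer":
        """A copy with coordinates mapped through ``x -> R x + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        residues = [
            Residue(r.chain_id, r.resseq, r.name, [(n, R @ x + t) for n, x in r.atoms])
            for r in self.residues
        ]
        return Protomer(self.chain_id, residues, self.tm_segments, self.role)

    def with_chain_id(self, chain_id: str) -> "Protomer":
        residues = [
            Residue(chain_id, r.resseq, r.name, [(n, x.copy()) for n, x in r.atoms])
            for r in self.residues
        ]
        return Protomer(chain_id, residues, self.tm_segments, self.role)

    def __repr__(self) -> str:
        return (
            f"Protomer(chain={self.chain_id!r}, n_res={len(self.residues)}, "
            f"n_tm={self.n_tm}, role={self.role!r})"
        )


_DESIGNATION_RE = re.compile(r"^(AF|CP|CP-H)-?(\d+)$")


@dataclass(frozen=True)
class ModelDesignation:
    """Provenance label of a complex model.

    ``AF-k`` is the rank-k AlphaFold-Multimer model; ``CP-n`` is ClusPro
    model n from the default Balanced mode and ``CP-Hn`` from the
    Hydrophobic-favored mode.
    """

    source: str  # "alphafold" | "cluspro"
    mode: str  # "balanced" | "hydrophobic" | "none"
    rank_or_number: int

    def __post_init__(self) -> None:
        if self.source not in ("alphafold", "cluspro"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.mode not in ("balanced", "hydrophobic", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.source == "alphafold" and self.mode != "none":
            raise ValueError("AlphaFold designations carry no docking mode")
        if self.source == "cluspro" and self.mode == "none":
            raise ValueError("ClusPro designations need a docking mode")
        if self.rank_or_number < 1:
            raise ValueError(f"rank/number must be >= 1, got {self.rank_or_number}")

    @property
    def label(self) -> str:
        if self.source == "alphafold":
            return f"AF-{self.rank_or_number}"
        prefix = "CP-H" if self.mode == "hydrophobic" else "CP-"
        return f"{prefix}{self.rank_or_number}"

    @classmethod
    def parse(cls, label: str) -> "ModelDesignation":
        label = label.strip()
        m = re.match(r"^AF-(\d+)$", label)
        if m:
            return cls("alphafold", "none", int(m.group(1)))
        m = re.match(r"^CP-H(\d+)$", label)
        if m:
            return cls("cluspro", "hydrophobic", int(m.group(1)))
        m = re.match(r"^CP-(\d+)$", label)
        if m:
            return cls("cluspro", "balanced", int(m.group(1)))
        raise ValueError(f"unrecognised model designation {label!r}")

    def __str__(self) -> str:
        return self.label


def parse_model_designation(label: str) -> ModelDesignation:
    """Parse a canonical model label ('AF-1', 'CP-12', 'CP-H18')."""
    return ModelDesignation.parse(label)


@dataclass(frozen=True)
class BindingEnergy:
    """MMPBSA binding free energy, mean +/- SEM in kcal/mol (negative = favorable)."""

    mean: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError(f"SEM must be >= 0, got {self.sem}")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sem:.2f}"


class EnergyTable:
    """Per-residue energy decomposition: (chain_id, resseq) -> kcal/mol."""

    def __init__(self, contributions: Mapping[tuple[str, int], float]):
        self._data: dict[tuple[str, int], float] = {}
        for key, v in contributions.items():
            v = float(v)
            if not np.isfinite(v):
                raise ValueError(f"non-finite contribution for residue {key}")
            chain, resseq = key
            self._data[(str(chain), int(resseq))] = v

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self._data[key]

    def get(self, key: tuple[str, int], default: float = 0.0) -> float:
        return self._data.get(key, default)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._data

    def __len__(self) -> int:
        return len(self._data)

    def items(self):
        return self._data.items()

    def total(self) -> float:
        return float(sum(self._data.values()))


@dataclass
class ComplexModel:
    """A two-chain complex model: subject + partner protomers and metadata."""

    subject: Protomer
    partner: Protomer
    designation: ModelDesignation
    bfe: BindingEnergy | None = None
    energy_table: EnergyTable | None = None
    complex_name: str = ""

    def __post_init__(self) -> None:
        if self.subject.chain_id == self.partner.chain_id:
            raise ValueError(
                f"subject and partner share chain id {self.subject.chain_id!r}"
            )

    @property
    def is_homodimer(self) -> bool:
        return self.subject.sequence == self.partner.sequence

    @property
    def protomers(self) -> tuple[Protomer, Protomer]:
        return (self.subject, self.partner)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexModel":
        return ComplexModel(
            self.subject.transformed(rotation, translation),
            self.partner.transformed(rotation, translation),
            self.designation,
            self.bfe,
            self.energy_table,
            self.complex_name,
        )

    def __repr__(self) -> str:
        return (
            f"ComplexModel({self.complex_name or 'unnamed'}, {self.designation.label}, "
            f"chains {self.subject.chain_id}/{self.partner.chain_id})"
        )
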