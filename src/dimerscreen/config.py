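"""Tunable thresholds of the triage pipeline.

Every numeric criterion that the workflow applies is collected here so
that reports can state exactly which values were used.  Defaults:

- ``cutoff_A`` (5.0): heavy-atom distance below which two residues of
  opposite protomers are interface residues.
- ``orientation_tol_deg`` (30): maximum angle between the two protomers'
  membrane normals for a pose to count as properly oriented.
- ``layer_tol_A`` (8.0): maximum membrane-midplane offset along the shared
  normal for the two inferred membrane slabs to count as consistent.
- ``overlap_min`` (0.25): minimum fraction of a dimer's subject interface
  that a blocker's subject interface must cover to count as significantly
  overlapping.
- ``delta_close`` (15.0 kcal/mol): how much weaker (higher) a blocker's
  mean binding free energy may be than the dimer's and still count as
  "close"; chosen to cover the weakest reported blocking margin
  (about 13 kcal/mol) with headroom.
- ``delta_keep`` (15.0 kcal/mol): band above the best model's mean within
  which additional models with distinct interfaces are retained.
- ``distinct_jaccard`` (0.5): subject helix-set Jaccard below which two
  interfaces are considered distinct.
- ``max_keep`` (3): most models retained per complex group.
- ``qualifier_frac`` (0.6): fraction of a helix's interface residues that
  must fall in one membrane third to earn an E/M/I qualifier.
- ``sig_energy`` (-1.0 kcal/mol): per-residue contribution below which a
  residue significantly contributes to binding.
- ``clash_cutoff_A`` (2.0): heavy-atom distance defining a steric clash in
  oligomer assemblies.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, replace

import yaml

__all__ = ["Thresholds"]


@dataclass(frozen=True)
class Thresholds:
    cutoff_A: float = 5.0
    orientation_tol_deg: float = 30.0
    layer_tol_A: float = 8.0
    overlap_min: float = 0.25
    delta_close: float = 15.0
    delta_keep: float = 15.0
    distinct_jaccard: float = 0.5
    max_keep: int = 3
    qualifier_frac: float = 0.6
    sig_energy: float = -1.0
    clash_cutoff_A: float = 2.0
    identity_matrix: str = "BLOSUM62"
    identity_open_gap: float = -10.0
    identity_extend_gap: float = -0.5

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be positive")
        if self.clash_cutoff_A <= 0:
            raise ValueError("clash_cutoff_A must be positive")
        if not 0 < self.overlap_min <= 1:
            raise ValueError("overlap_min must be in (0, 1]")
        if not 0 < self.qualifier_frac <= 1:
            raise ValueError("qualifier_frac must be in (0, 1]")

    def updated(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown threshold names: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
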