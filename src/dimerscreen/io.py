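"""Reading and writing complex models.

PDB I/O is done with :mod:`gemmi`.  A complex on disk is a PDB file with
one chain per protomer plus a YAML sidecar (``<file>.meta.yaml``) that
carries what the PDB format cannot: chain roles, TM-segment annotations,
the model designation and, optionally, the binding free energy.

Energy decompositions and binding-free-energy tables travel as CSV/TSV
and are read with pandas.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .model import (
    BindingEnergy,
    ComplexModel,
    EnergyTable,
    ModelDesignation,
    Protomer,
    Residue,
    TMSegment,
)

__all__ = [
    "read_complex_pdb",
    "write_complex_pdb",
    "sidecar_path",
    "read_energy_table",
    "write_energy_table",
    "read_bfe_table",
    "write_bfe_table",
]


def sidecar_path(pdb_path: str | os.PathLike) -> Path:
    return Path(str(pdb_path) + ".meta.yaml")


def _load_chain(chain: gemmi.Chain, tm_segments: Sequence[TMSegment], role: str) -> Protomer:
    residues = []
    for res in chain:
        if res.is_water():
            continue
        atoms = []
        for atom in res:
            if atom.is_hydrogen():
                continue
            p = atom.pos
            atoms.append((atom.name, np.array([p.x, p.y, p.z])))
        if atoms:
            residues.append(Residue(chain.name, res.seqid.num, res.name, atoms))
    if not residues:
        raise ValueError(f"chain {chain.name} contains no heavy atoms")
    return Protomer(chain.name, residues, tm_segments, role)


def _segments_from_spec(spec: Sequence) -> list[TMSegment]:
    """Accept TMSegment objects or mapping/list forms from YAML."""
    segs = []
    for s in spec:
        if isinstance(s, TMSegment):
            segs.append(s)
        elif isinstance(s, Mapping):
            segs.append(
                TMSegment(
                    int(s["index"]), int(s["start"]), int(s["end"]),
                    bool(s.get("is_h8", False)),
                )
            )
        else:
            idx, start, end = s[:3]
            h8 = bool(s[3]) if len(s) > 3 else False
            segs.append(TMSegment(int(idx), int(start), int(end), h8))
    return segs


def read_complex_pdb(
    path: str | os.PathLike,
    chain_roles: Mapping[str, str] | None = None,
    tm_annotations: Mapping[str, Sequence] | None = None,
) -> ComplexModel:
    """Read a two-chain complex from a PDB file.

    ``chain_roles`` maps chain id -> role (subject/partner/isoform) and
    ``tm_annotations`` maps chain id -> TM segments.  When omitted, both
    are taken from the YAML sidecar written by :func:`write_complex_pdb`.
    Hydrogens are dropped on read.
    """
    path = Path(path)
    meta: dict = {}
    side = sidecar_path(path)
    if (chain_roles is None or tm_annotations is None) and side.exists():
        with open(side) as fh:
            meta = yaml.safe_load(fh) or {}
    if chain_roles is None:
        chain_roles = meta.get("chain_roles")
    if tm_annotations is None:
        tm_annotations = meta.get("tm_segments")
    if chain_roles is None or tm_annotations is None:
        raise ValueError(
            f"{path}: chain roles / TM annotations not given and no sidecar at {side}"
        )

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    model = st[0]
    chains = {c.name: c for c in model}
    protomers: dict[str, Protomer] = {}
    for chain_id, role in chain_roles.items():
        if chain_id not in chains:
            raise ValueError(f"{path}: chain {chain_id} absent")
        segs = _segments_from_spec(tm_annotations.get(chain_id, []))
        protomers[chain_id] = _load_chain(chains[chain_id], segs, role)

    subject = next((p for p in protomers.values() if p.role == "subject"), None)
    others = [p for p in protomers.values() if p is not subject]
    if subject is None or not others:
        raise ValueError(
            f"{path}: chain_roles must name one 'subject' and at least one other chain"
        )
    partner = others[0]

    designation = ModelDesignation.parse(meta["designation"]) if "designation" in meta \
        else ModelDesignation("cluspro", "balanced", 1)
    bfe = None
    if "bfe" in meta and meta["bfe"] is not None:
        bfe = BindingEnergy(float(meta["bfe"]["mean"]), float(meta["bfe"].get("sem", 0.0)))
    return ComplexModel(
        subject, partner, designation, bfe=bfe,
        complex_name=meta.get("complex_name", path.stem),
    )


def write_complex_pdb(model: ComplexModel, path: str | os.PathLike) -> Path:
    """Write a complex to PDB plus a YAML sidecar with the metadata.

    Round-trips coordinates at PDB field precision (1e-3 A).
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.complex_name or "complex"
    gm = gemmi.Model("1")
    for prot in model.protomers:
        ch = gemmi.Chain(prot.chain_id)
        for r in prot.residues:
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
    st.setup_entities()
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))

    meta = {
        "complex_name": model.complex_name,
        "designation": model.designation.label,
        "chain_roles": {p.chain_id: p.role for p in model.protomers},
        "tm_segments": {
            p.chain_id: [
                {"index": s.index, "start": s.start, "end": s.end, "is_h8": s.is_h8}
                for s in p.tm_segments
            ]
            for p in model.protomers
        },
    }
    if model.bfe is not None:
        meta["bfe"] = {"mean": model.bfe.mean, "sem": model.bfe.sem}
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


# -- tabular inputs -------------------------------------------------------

def read_energy_table(path: str | os.PathLike) -> EnergyTable:
    """Read a per-residue energy decomposition CSV.

    Expected columns: chain, resseq, resname, contribution_kcal_mol
    (resname is informational only).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"chain", "resseq", "contribution_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return EnergyTable(
        {
            (str(row.chain), int(row.resseq)): float(row.contribution_kcal_mol)
            for row in df.itertuples()
        }
    )


def write_energy_table(
    table: EnergyTable, path: str | os.PathLike,
    resnames: Mapping[tuple[str, int], str] | None = None,
) -> Path:
    rows = [
        {
            "chain": chain,
            "resseq": resseq,
            "resname": (resnames or {}).get((chain, resseq), "UNK"),
            "contribution_kcal_mol": value,
        }
        for (chain, resseq), value in sorted(table.items())
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_bfe_table(path: str | os.PathLike) -> dict[str, BindingEnergy]:
    """Read a binding-free-energy CSV: designation, mean, sem."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"designation", "mean", "sem"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for row in df.itertuples():
        ModelDesignation.parse(str(row.designation))  # validate early
        out[str(row.designation)] = BindingEnergy(float(row.mean), float(row.sem))
    return out


def write_bfe_table(table: Mapping[str, BindingEnergy], path: str | os.PathLike) -> Path:
    rows = [
        {"designation": label, "mean": bfe.mean, "sem": bfe.sem}
        for label, bfe in table.items()
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
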