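"""Curated published reference data for chemokine receptor dimer models.

``reference_models.tsv`` summarises the most stable complex models
reported for CXCR2, CXCR7, CCR2 and CCR7 homo-/heterodimers and their
complexes with truncated Iso_XTM isoforms: the model designation, the
interface composition on the subject (and partner), and the MMPBSA
binding free energy (mean +/- SEM over a 50 ns production trajectory).
These energies are consumed as inputs; the package never recomputes
MMPBSA.

``blocking_cases.tsv`` lists each reported dimer/blocker pairing together
with the helices stated to be shared between the dimer's subject
interface and the blocker's subject interface ('none' when the report
found no interface overlap), and the reported blocking outcome.  Feeding
these stated overlap relationships plus the published binding free
energies through :func:`dimerscreen.blocking.blocking_call` reproduces
the published verdicts (a worked truth table used by the test suite).

The bundled receptor FASTA files are best-effort transcriptions of the
UniProt entries (P41597 CCR2, P51681 CCR5, P61073 CXCR4) labelled
``.synthetic.fasta``: they were written down without access to the
database and are stand-ins, not authoritative downloads.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .blocking import BlockingVerdict, OverlapResult, blocking_call, interface_overlap
from .config import Thresholds
from .interface import parse_interface_string
from .model import BindingEnergy

__all__ = [
    "load_reference_models",
    "load_blocking_cases",
    "reference_binding_energies",
    "helix_set",
    "evaluate_blocking_cases",
    "load_receptor_sequence",
]

_SEQUENCE_FILES = {
    "CCR2": "ccr2_P41597.synthetic.fasta",
    "CCR5": "ccr5_P51681.synthetic.fasta",
    "CXCR4": "cxcr4_P61073.synthetic.fasta",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dimerscreen").joinpath("data", name)))


def load_reference_models() -> pd.DataFrame:
    """The curated table of most-stable complex models (one row per model)."""
    return pd.read_csv(_data_path("reference_models.tsv"), sep="\t")


def load_blocking_cases() -> pd.DataFrame:
    """Reported dimer/blocker pairings with stated interface overlap."""
    df = pd.read_csv(_data_path("blocking_cases.tsv"), sep="\t")
    df["reported_blocks"] = df["reported_blocks"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    return df


def reference_binding_energies() -> dict[tuple[str, str], BindingEnergy]:
    """Map (complex name, designation) -> published binding free energy."""
    df = load_reference_models()
    return {
        (row.complex, row.designation): BindingEnergy(row.bfe_mean, row.bfe_sem)
        for row in df.itertuples()
    }


def helix_set(interface_string: str) -> frozenset[int]:
    """The set of TM helix indices named in an interface string."""
    return frozenset(index for index, _ in parse_interface_string(interface_string))


def evaluate_blocking_cases(params: Thresholds | None = None) -> pd.DataFrame:
    """Recompute every reported blocking verdict from the curated data.

    For each case, the dimer's subject interface helix set (from the
    model table) and the stated shared helices are turned into an
    interface overlap, and the published binding free energies are fed
    through the standard blocking rules.  Returns one row per case with
    the computed verdict next to the reported one.
    """
    params = params or Thresholds()
    bfes = reference_binding_energies()
    models = load_reference_models().set_index(["complex", "designation"])
    rows = []
    for case in load_blocking_cases().itertuples():
        dimer_key = (case.dimer_complex, case.dimer_model)
        blocker_key = (case.blocker_complex, case.blocker_model)
        dimer_helices = helix_set(models.loc[dimer_key, "subject_interface"])
        if case.shared_helices == "none":
            shared: frozenset[int] = frozenset()
        else:
            shared = frozenset(int(h) for h in str(case.shared_helices).split(","))
        overlap = interface_overlap(dimer_helices, shared)
        verdict = blocking_call(overlap, bfes[dimer_key], bfes[blocker_key], params)
        rows.append(
            {
                "dimer": f"{case.dimer_complex} {case.dimer_model}",
                "blocker": f"{case.blocker_complex} {case.blocker_model}",
                "frac_of_dimer": overlap.frac_of_dimer,
                "bfe_dimer": bfes[dimer_key].mean,
                "bfe_blocker": bfes[blocker_key].mean,
                "computed_blocks": verdict.blocks,
                "reported_blocks": bool(case.reported_blocks),
                "agrees": verdict.blocks == bool(case.reported_blocks),
            }
        )
    return pd.DataFrame(rows)


def load_receptor_sequence(name: str) -> str:
    """Bundled receptor sequence by name ('CCR2', 'CCR5', 'CXCR4').

    These are synthetic stand-ins for the UniProt entries (see module
    docstring); treat identity percentages computed from them as
    approximate.
    """
    try:
        fname = _SEQUENCE_FILES[name.upper()]
    except KeyError:
        raise KeyError(
            f"no bundled sequence for {name!r}; available: {sorted(_SEQUENCE_FILES)}"
        ) from None
    text = _data_path(fname).read_text()
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith(">")]
    return "".join(lines)
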