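"""Config-driven orchestration of the full triage workflow.

The screen mirrors the published workflow: read candidate complex models
for each complex group, discard poses that are not membrane-topology
compliant, characterise the interface of the survivors, select the most
stable model(s) by binding free energy (keeping up to three comparably
stable models with distinct interfaces), then issue blocking verdicts
for isoform complexes against dimers of the same subject and report
competition groups among the selected dimers.

Configuration is YAML::

    output_dir: screen_out
    seed: 1
    thresholds: {layer_tol_A: 8.0}     # optional overrides
    groups:
      - name: RecA-RecA
        bfe_table: bfe.csv             # designation,mean,sem
        models:
          - pdb: model1.pdb            # sidecar carries roles/TMs/designation
            energy_table: decomp1.csv  # optional

Every threshold used is echoed into the report; reruns on identical
inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
import sys
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .blocking import blocking_verdict, competition_groups
from .config import Thresholds
from .interface import interface_profile
from .io import read_bfe_table, read_complex_pdb, read_energy_table
from .membrane import topology_filter
from .model import ComplexModel

__all__ = ["ScreenConfig", "ScreenReport", "select_most_stable", "run_screen"]


def _helix_jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union) if union else 1.0


def select_most_stable(
    models: list[ComplexModel],
    params: Thresholds | None = None,
    helix_sets: dict[str, frozenset[int]] | None = None,
) -> list[ComplexModel]:
    """Select the most stable model(s) of a complex group.

    The minimum-mean-BFE model is always kept.  Further models are kept
    (up to ``max_keep`` total) when their mean is within ``delta_keep``
    kcal/mol of the best AND their subject interface helix set has a
    Jaccard similarity below ``distinct_jaccard`` with every model kept
    so far - i.e. they are comparably stable with a distinct interface.
    ``helix_sets`` maps designation label -> subject helix set; computed
    from the structures when not given.
    """
    if not models:
        raise ValueError("no models to select from")
    for m in models:
        if m.bfe is None:
            raise ValueError(f"model {m.designation.label} lacks a binding free energy")
    params = params or Thresholds()
    if helix_sets is None:
        helix_sets = {}
        for m in models:
            prof = interface_profile(m, params)
            helix_sets[m.designation.label] = frozenset(
                h.index for h in prof.helix_ranking
            )
    ordered = sorted(models, key=lambda m: (m.bfe.mean, m.designation.label))
    kept = [ordered[0]]
    best_mean = ordered[0].bfe.mean
    for m in ordered[1:]:
        if len(kept) >= params.max_keep:
            break
        if m.bfe.mean > best_mean + params.delta_keep:
            break
        hs = helix_sets[m.designation.label]
        if all(
            _helix_jaccard(hs, helix_sets[k.designation.label]) < params.distinct_jaccard
            for k in kept
        ):
            kept.append(m)
    return kept


@dataclass
class ScreenConfig:
    groups: list[dict]
    output_dir: Path = Path("screen_out")
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" not in raw or not raw["groups"]:
            raise ValueError(f"{path}: config must define at least one group")
        base = path.parent

        def resolve(p):  # paths in the config are relative to the config file
            p = Path(p)
            return p if p.is_absolute() else base / p

        groups = []
        for g in raw["groups"]:
            g = dict(g)
            g["models"] = [dict(m) for m in g.get("models", [])]
            for m in g["models"]:
                m["pdb"] = resolve(m["pdb"])
                if "energy_table" in m and m["energy_table"]:
                    m["energy_table"] = resolve(m["energy_table"])
            if g.get("bfe_table"):
                g["bfe_table"] = resolve(g["bfe_table"])
            groups.append(g)
        thresholds = Thresholds.from_dict(raw.get("thresholds", {}) or {})
        out = raw.get("output_dir", "screen_out")
        out = Path(out)
        if not out.is_absolute():
            out = base / out
        return cls(groups, out, thresholds, int(raw.get("seed", 0)))


@dataclass
class ScreenReport:
    model_rows: list[dict]
    verdict_rows: list[dict]
    competition: list[list[str]]
    thresholds: dict
    errors: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.model_rows)

    def write(self, output_dir: str | Path) -> dict[str, Path]:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "models": output_dir / "models.tsv",
            "verdicts": output_dir / "verdicts.tsv",
            "report": output_dir / "report.json",
        }
        pd.DataFrame(self.model_rows).to_csv(paths["models"], sep="\t", index=False)
        pd.DataFrame(self.verdict_rows).to_csv(paths["verdicts"], sep="\t", index=False)
        with open(paths["report"], "w") as fh:
            json.dump(
                {
                    "thresholds": self.thresholds,
                    "models": self.model_rows,
                    "verdicts": self.verdict_rows,
                    "competition_groups": self.competition,
                    "errors": self.errors,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return paths


def _load_group_models(group: dict, params: Thresholds) -> list[ComplexModel]:
    bfes = read_bfe_table(group["bfe_table"]) if group.get("bfe_table") else {}
    models = []
    for spec in group["models"]:
        model = read_complex_pdb(spec["pdb"])
        if spec.get("designation"):
            from .model import ModelDesignation

            model.designation = ModelDesignation.parse(spec["designation"])
        label = model.designation.label
        if label in bfes:
            model.bfe = bfes[label]
        if spec.get("energy_table"):
            model.energy_table = read_energy_table(spec["energy_table"])
        if group.get("name"):
            model.complex_name = group["name"]
        models.append(model)
    return models


def run_screen(config: ScreenConfig, log=sys.stderr) -> ScreenReport:
    """Run the full screen and return (and write) the report.

    A failure in one group is recorded and does not stop the others.
    """
    params = config.thresholds
    model_rows: list[dict] = []
    errors: dict[str, str] = {}
    selected_dimers: list[ComplexModel] = []
    selected_blockers: list[ComplexModel] = []

    for group in config.groups:
        name = group.get("name", "unnamed")
        try:
            models = _load_group_models(group, params)
            compliant_with_bfe = []
            helix_sets: dict[str, frozenset[int]] = {}
            rows_here = []
            for model in models:
                report = topology_filter(model, params)
                profile = interface_profile(model, params)
                helix_sets[model.designation.label] = frozenset(
                    h.index for h in profile.helix_ranking
                )
                rows_here.append(
                    {
                        "group": name,
                        "designation": model.designation.label,
                        "compliant": report.compliant,
                        "rules": report.summary(),
                        "interface": profile.interface_string,
                        "bfe_mean": model.bfe.mean if model.bfe else None,
                        "bfe_sem": model.bfe.sem if model.bfe else None,
                        "selected": False,
                    }
                )
                if report.compliant and model.bfe is not None:
                    compliant_with_bfe.append(model)
            if compliant_with_bfe:
                kept = select_most_stable(compliant_with_bfe, params, helix_sets)
                kept_labels = {m.designation.label for m in kept}
                for row in rows_here:
                    row["selected"] = row["designation"] in kept_labels
                is_blocker = any(m.partner.role == "isoform" for m in kept)
                (selected_blockers if is_blocker else selected_dimers).extend(kept)
            model_rows.extend(rows_here)
        except Exception as exc:  # keep the screen going for other groups
            errors[name] = f"{type(exc).__name__}: {exc}"
            print(f"[dimerscreen] group {name} failed: {exc}", file=log)

    verdict_rows = []
    for dimer in selected_dimers:
        for blocker in selected_blockers:
            if dimer.subject.sequence != blocker.subject.sequence:
                continue
            v = blocking_verdict(dimer, blocker, params)
            verdict_rows.append(
                {
                    "dimer": f"{dimer.complex_name} {dimer.designation.label}",
                    "blocker": f"{blocker.complex_name} {blocker.designation.label}",
                    "shared_residues": v.overlap.shared,
                    "jaccard": round(v.overlap.jaccard, 4),
                    "frac_of_dimer": round(v.overlap.frac_of_dimer, 4),
                    "bfe_dimer": v.bfe_dimer.mean,
                    "bfe_blocker": v.bfe_blocker.mean,
                    "overlap_pass": v.overlap_pass,
                    "energy_pass": v.energy_pass,
                    "blocks": v.blocks,
                    "overlap_min": v.overlap_min_used,
                    "delta_close": v.delta_used,
                }
            )

    comp_groups = []
    if len(selected_dimers) >= 2:
        for idx_group in competition_groups(selected_dimers, params):
            comp_groups.append(
                [
                    f"{selected_dimers[i].complex_name} "
                    f"{selected_dimers[i].designation.label}"
                    for i in idx_group
                ]
            )

    report = ScreenReport(
        model_rows, verdict_rows, comp_groups, params.to_dict(), errors
    )
    report.write(config.output_dir)
    return report
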