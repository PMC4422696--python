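"""Drug-project catalog handling: stage normalisation, target join, stage filter.

The catalog is a TTD-style table of target–drug development projects.
Free-text development stages ("Approved", "Phase III withdraw",
"Suspended in Phase II", ...) are normalised onto a closed five-class
vocabulary by an ordered regex table shipped as a versioned data file, so
new stage dialects are added without code changes.  Research- and
preclinical-stage projects are then filtered out: they carry no human
toxicity information, which is the whole point of repositioning.
Withdrawn or suspended *clinical* projects are retained — drugs that
reached humans remain informative candidates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ClassificationError, ConfigurationError, ValidationError
from .evidence import RiskProteinSet, normalize_identifier

STAGE_CLASSES = (
    "approved",
    "clinical",
    "preclinical",
    "research",
    "withdrawn_or_suspended_clinical",
)

#: Stage classes that survive the development-stage filter.
INCLUDABLE_STAGES = frozenset(
    {"approved", "clinical", "withdrawn_or_suspended_clinical"}
)

ACTION_MODES = ("inhibitor", "antagonist", "agonist", "activator", "modulator_unknown")


@dataclass(frozen=True)
class DrugProject:
    """One target–drug development record."""

    target_accession: str
    target_name: str
    drug_name: str
    indication: str
    stage_raw: str
    stage_class: str
    action_mode: str

    def __post_init__(self):
        if self.stage_class not in STAGE_CLASSES:
            raise ValidationError(f"unknown stage class {self.stage_class!r}")
        if self.action_mode not in ACTION_MODES:
            raise ValidationError(f"unknown action mode {self.action_mode!r}")


@lru_cache(maxsize=1)
def _stage_rules() -> tuple[tuple[re.Pattern, str], ...]:
    with resources.files("drugrepo.data").joinpath("stage_rules.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return tuple(
        (re.compile(row.pattern, re.IGNORECASE), row.stage_class)
        for row in table.itertuples(index=False)
    )


def parse_stage(stage_raw: str) -> str:
    """Normalise a free-text development stage onto the closed vocabulary.

    First matching rule in the ordered table wins; withdrawal/suspension
    wording is checked before plain phase wording so that e.g.
    "Phase III withdraw" classifies as withdrawn clinical, never as
    active clinical and never as preclinical.
    """
    if not stage_raw or not str(stage_raw).strip():
        raise ClassificationError("empty development-stage text")
    text = str(stage_raw).strip()
    for pattern, stage_class in _stage_rules():
        if pattern.search(text):
            return stage_class
    raise ClassificationError(f"unrecognised development stage {text!r}")


def parse_action_mode(text: str) -> str:
    mode = str(text).strip().casefold()
    if mode in ACTION_MODES:
        return mode
    if mode in ("modulator", "unknown", "binder", ""):
        return "modulator_unknown"
    raise ClassificationError(f"unrecognised action mode {text!r}")


def load_catalog(path) -> list[DrugProject]:
    """Read a drug-project catalog TSV.

    Mandatory columns: target_name, drug_name, indication, stage, action_mode;
    target_accession is honoured when present (else the normalised target
    name doubles as the join key).
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"target_name", "drug_name", "indication", "stage", "action_mode"}
    missing = needed - set(table.columns)
    if missing:
        raise ValidationError(
            f"{Path(path).name}: catalog missing columns {sorted(missing)}"
        )
    projects = []
    for row in table.itertuples(index=False):
        accession = getattr(row, "target_accession", "") or row.target_name
        projects.append(
            DrugProject(
                target_accession=normalize_identifier(accession),
                target_name=str(row.target_name).strip(),
                drug_name=str(row.drug_name).strip(),
                indication=str(row.indication).strip(),
                stage_raw=str(row.stage).strip(),
                stage_class=parse_stage(row.stage),
                action_mode=parse_action_mode(row.action_mode),
            )
        )
    return projects


def join_targets(
    risk_proteins: RiskProteinSet,
    catalog: Sequence[DrugProject],
    *,
    join_on: str = "accession",
) -> tuple[list[DrugProject], dict]:
    """Select catalog rows whose target is a risk protein.

    ``join_on`` is 'accession' (default) or 'name' (exact normalised
    target name, for catalogs without stable accessions).  Returns the
    candidate projects plus a target-level summary.
    """
    if not catalog:
        raise ConfigurationError("drug-project catalog is empty")
    if join_on not in ("accession", "name"):
        raise ConfigurationError(f"join_on must be 'accession' or 'name', got {join_on!r}")
    key = (
        (lambda p: p.target_accession)
        if join_on == "accession"
        else (lambda p: normalize_identifier(p.target_name))
    )
    candidates = [p for p in catalog if key(p) in risk_proteins.members]
    summary = {
        "n_risk_proteins": len(risk_proteins),
        "n_catalog_projects": len(catalog),
        "n_candidate_projects": len(candidates),
        "targets_with_projects": sorted({key(p) for p in candidates}),
    }
    return candidates, summary


def filter_stage(
    candidates: Sequence[DrugProject],
) -> tuple[list[DrugProject], pd.DataFrame]:
    """Drop research/preclinical projects; keep approved, clinical and
    withdrawn/suspended-clinical ones.

    Returns the retained projects and an exclusion log (one row per
    removed project with its reason).
    """
    retained, excluded = [], []
    for i, project in enumerate(candidates):
        if project.stage_class in INCLUDABLE_STAGES:
            retained.append(project)
        else:
            excluded.append(
                {
                    "row": i,
                    "drug_name": project.drug_name,
                    "target_accession": project.target_accession,
                    "stage_raw": project.stage_raw,
                    "reason": f"stage_class={project.stage_class}",
                }
            )
    log = pd.DataFrame(
        excluded, columns=["row", "drug_name", "target_accession", "stage_raw", "reason"]
    )
    return retained, log


def projects_to_frame(projects: Sequence[DrugProject]) -> pd.DataFrame:
    cols = [
        "target_accession", "target_name", "drug_name", "indication",
        "stage_raw", "stage_class", "action_mode",
    ]
    return pd.DataFrame([vars(p) for p in projects], columns=cols)
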