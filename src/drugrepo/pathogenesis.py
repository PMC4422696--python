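"""Gain/loss-of-function compatibility rules for candidate drugs.

Omics evidence only associates a protein with diabetes risk; it does not
say whether pushing the protein up or down helps.  This module codifies
the mechanistic decision: a drug induces a loss of function (inhibitor,
antagonist) or a gain of function (agonist, activator) in its target, and
curated pathogenesis annotations state whether a gain (GOF) or loss (LOF)
of that target's function is harmful or beneficial for diabetes.  A
LOF-inducing drug is therapeutic when GOF is harmful or LOF is
beneficial; mirrored combinations aggravate the disease.  Any aggravating
evidence for the drug's own direction vetoes repositioning (conservative
veto), and targets whose annotations have no direct diabetes link, or
only a complication link, are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .catalog import DrugProject, projects_to_frame
from .errors import ValidationError
from .evidence import normalize_identifier

DIRECTIONS = ("gof", "lof")
VALENCES = ("beneficial", "harmful")
LINK_SCOPES = ("direct_diabetes", "complication_only", "none")
EFFECTS = ("lof_like", "gof_like", "unknown")
VERDICTS = (
    "therapeutic",
    "aggravating",
    "excluded_no_link",
    "excluded_complication",
    "indeterminate",
)

_ACTION_TO_EFFECT = {
    "inhibitor": "lof_like",
    "antagonist": "lof_like",
    "agonist": "gof_like",
    "activator": "gof_like",
    "modulator_unknown": "unknown",
}


@dataclass(frozen=True)
class PathogenesisAnnotation:
    """Structured GOF/LOF knowledge for one target.

    ``link_scope`` distinguishes direct diabetes pathogenesis from
    complication-only links; scope ``none`` forbids direction/valence
    content.  The verbatim curated phrase travels in ``free_text`` for
    auditability but is never parsed.
    """

    target_accession: str
    direction: Optional[str] = None
    valence: Optional[str] = None
    link_scope: str = "direct_diabetes"
    evidence_source: str = ""
    free_text: str = ""

    def __post_init__(self):
        if self.link_scope not in LINK_SCOPES:
            raise ValidationError(f"unknown link scope {self.link_scope!r}")
        if self.link_scope == "none":
            if self.direction is not None or self.valence is not None:
                raise ValidationError(
                    "link_scope 'none' forbids direction/valence content"
                )
        else:
            if self.direction not in DIRECTIONS:
                raise ValidationError(f"unknown direction {self.direction!r}")
            if self.valence not in VALENCES:
                raise ValidationError(f"unknown valence {self.valence!r}")


@dataclass
class CompatibilityVerdict:
    """Outcome of the rule engine for one (target, drug) project row."""

    pair: tuple[str, str]
    verdict: str
    supporting_annotations: list[PathogenesisAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")


def drug_effect_direction(action_mode: str) -> str:
    """Map a drug action mode to the functional change it induces."""
    try:
        return _ACTION_TO_EFFECT[action_mode]
    except KeyError:
        raise ValidationError(f"unknown action mode {action_mode!r}") from None


def compatibility(
    effect: str,
    annotations: Sequence[PathogenesisAnnotation],
    pair: tuple[str, str] = ("", ""),
) -> CompatibilityVerdict:
    """Pure decision function: drug effect direction x annotations -> verdict.

    Decision order:

    1. no annotations, or all with scope ``none`` -> ``excluded_no_link``;
    2. no direct-scope annotations but some complication-only ones ->
       ``excluded_complication``;
    3. unknown drug effect direction -> ``indeterminate``;
    4. among direct annotations, a LOF-like drug is therapeutic on any
       (gof, harmful) or (lof, beneficial) annotation and aggravating on
       any (gof, beneficial) or (lof, harmful); GOF-like mirrored;
    5. aggravating evidence vetoes therapeutic evidence when both exist.
    """
    if effect not in EFFECTS:
        raise ValidationError(f"unknown effect direction {effect!r}")
    targets = {a.target_accession for a in annotations}
    if len(targets) > 1:
        raise ValidationError(
            f"annotations span several targets: {sorted(targets)}"
        )

    informative = [a for a in annotations if a.link_scope != "none"]
    if not informative:
        return CompatibilityVerdict(pair, "excluded_no_link")
    direct = [a for a in informative if a.link_scope == "direct_diabetes"]
    if not direct:
        return CompatibilityVerdict(pair, "excluded_complication", informative)
    if effect == "unknown":
        return CompatibilityVerdict(pair, "indeterminate", direct)

    if effect == "lof_like":
        good = {("gof", "harmful"), ("lof", "beneficial")}
    else:  # gof_like
        good = {("lof", "harmful"), ("gof", "beneficial")}
    therapeutic = [a for a in direct if (a.direction, a.valence) in good]
    aggravating = [a for a in direct if (a.direction, a.valence) not in good]

    if aggravating:  # conservative veto, even when therapeutic evidence coexists
        return CompatibilityVerdict(pair, "aggravating", aggravating)
    if therapeutic:
        return CompatibilityVerdict(pair, "therapeutic", therapeutic)
    return CompatibilityVerdict(pair, "indeterminate", direct)


def load_annotations(path) -> list[PathogenesisAnnotation]:
    """Read an annotation TSV (target_accession, direction, valence,
    link_scope, evidence_source, free_text)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"target_accession", "direction", "valence", "link_scope"}
    missing = needed - set(table.columns)
    if missing:
        raise ValidationError(
            f"{Path(path).name}: annotation table missing columns {sorted(missing)}"
        )
    annotations = []
    for row in table.itertuples(index=False):
        scope = str(row.link_scope).strip().casefold() or "direct_diabetes"
        annotations.append(
            PathogenesisAnnotation(
                target_accession=normalize_identifier(row.target_accession),
                direction=str(row.direction).strip().casefold() or None,
                valence=str(row.valence).strip().casefold() or None,
                link_scope=scope,
                evidence_source=str(getattr(row, "evidence_source", "")).strip(),
                free_text=str(getattr(row, "free_text", "")).strip(),
            )
        )
    return annotations


def apply_pathogenesis_filter(
    candidates: Sequence[DrugProject],
    annotations: Sequence[PathogenesisAnnotation],
) -> dict:
    """Run the rule engine over every candidate project row.

    Every annotation must reference a candidate target.  Returns a dict
    with the repurposing table (therapeutic rows plus their supporting
    annotation text, Table-1 shaped), the verdict partition logs, the
    per-verdict project lists, and unique-drug / unique-target counts.
    A drug that is therapeutic under one target but aggravating under
    another is dropped from the drug-level list (conservative veto across
    projects).
    """
    candidate_targets = {p.target_accession for p in candidates}
    by_target: dict[str, list[PathogenesisAnnotation]] = {
        t: [] for t in candidate_targets
    }
    for ann in annotations:
        if ann.target_accession not in candidate_targets:
            raise ValidationError(
                f"annotation references unknown target {ann.target_accession!r}"
            )
        by_target[ann.target_accession].append(ann)

    verdicts: list[CompatibilityVerdict] = []
    partition: dict[str, list[DrugProject]] = {v: [] for v in VERDICTS}
    for project in candidates:
        verdict = compatibility(
            drug_effect_direction(project.action_mode),
            by_target[project.target_accession],
            pair=(project.target_accession, project.drug_name),
        )
        verdicts.append(verdict)
        partition[verdict.verdict].append(project)

    table = projects_to_frame(partition["therapeutic"])
    table["pathogenesis"] = [
        "; ".join(a.free_text or f"{a.direction},{a.valence}"
                  for a in v.supporting_annotations)
        for v in verdicts if v.verdict == "therapeutic"
    ]

    drug_verdicts: dict[str, set[str]] = {}
    for project, verdict in zip(candidates, verdicts):
        drug_verdicts.setdefault(project.drug_name, set()).add(verdict.verdict)
    repurposed_drugs = sorted(
        d for d, vs in drug_verdicts.items()
        if "therapeutic" in vs and "aggravating" not in vs
    )
    return {
        "repurposing_table": table,
        "verdicts": verdicts,
        "partition": partition,
        "repurposed_drugs": repurposed_drugs,
        "n_unique_drugs": len(repurposed_drugs),
        "therapeutic_targets": sorted(
            {p.target_accession for p in partition["therapeutic"]}
        ),
        "n_therapeutic_targets": len(
            {p.target_accession for p in partition["therapeutic"]}
        ),
    }
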