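"""Pipeline orchestration, funnel accounting and fixture access.

Runs the whole repositioning funnel — risk-protein unification, drug
catalog join, stage filter, known/novel split, pathogenesis rule engine,
connectivity support classification — and reports the count at every
stage.  Two modes: ``synthetic`` regenerates all inputs with planted
ground truth; ``fixtures`` replays the packaged study tables (the
repurposing table, its structured annotations, the published
drug–reference association rows and printed flow counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import catalog as cat
from . import connectivity as conn
from . import evidence as ev
from . import network as net
from . import pathogenesis as patho
from . import simulate as sim
from .errors import ConfigurationError, EmptyInputError, ValidationError

FUNNEL_STAGES = (
    "risk_proteins",
    "targets_with_projects",
    "druggable_targets",
    "known_antidiabetic_targets",
    "novel_targets",
    "therapeutic_drugs",
    "therapeutic_targets",
    "supported_drugs",
)

#: (smaller stage, larger stage) pairs where set containment forces order
_MONOTONE_PAIRS = (
    ("targets_with_projects", "risk_proteins"),
    ("druggable_targets", "targets_with_projects"),
    ("therapeutic_targets", "druggable_targets"),
    ("supported_drugs", "therapeutic_drugs"),
)

DEFAULT_KNOWN_VOCABULARY = (
    "diabetes", "diabetic", "hyperglycemia", "glycemic control",
)


@dataclass
class FunnelReport:
    """Ordered stage counts of one pipeline run."""

    stage_counts: list[tuple[str, int]]

    def __post_init__(self):
        counts = dict(self.stage_counts)
        for smaller, larger in _MONOTONE_PAIRS:
            if smaller in counts and larger in counts:
                if counts[smaller] > counts[larger]:
                    raise ValidationError(
                        f"funnel monotonicity violated: {smaller}="
                        f"{counts[smaller]} > {larger}={counts[larger]}"
                    )

    def __getitem__(self, stage: str) -> int:
        return dict(self.stage_counts)[stage]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "count"])


# ---------------------------------------------------------------------------
# packaged fixtures

def _fixture(name: str) -> pd.DataFrame:
    with resources.files("drugrepo.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def load_repurposing_fixture() -> list[cat.DrugProject]:
    """The packaged repurposing table (12 targets, one row per project)."""
    table = _fixture("table1.tsv")
    return [
        cat.DrugProject(
            target_accession=ev.normalize_identifier(r.target_accession),
            target_name=r.target_name,
            drug_name=r.drug_name,
            indication=r.indication,
            stage_raw=r.stage,
            stage_class=cat.parse_stage(r.stage),
            action_mode=cat.parse_action_mode(r.action_mode),
        )
        for r in table.itertuples(index=False)
    ]


def load_annotation_fixture() -> list[patho.PathogenesisAnnotation]:
    table = _fixture("table1_annotations.tsv")
    return [
        patho.PathogenesisAnnotation(
            target_accession=ev.normalize_identifier(r.target_accession),
            direction=r.direction or None,
            valence=r.valence or None,
            link_scope=r.link_scope,
            evidence_source=r.evidence_source,
            free_text=r.free_text,
        )
        for r in table.itertuples(index=False)
    ]


def load_association_fixture() -> list[conn.ConnectivityResult]:
    """The published drug–reference association rows (score, p, polarity)."""
    table = _fixture("cmap_associations.tsv")
    return [
        conn.ConnectivityResult(
            subject=r.subject,
            reference=r.reference,
            enrichment=float(r.enrichment),
            p_value=float(r.p_value),
            n_instances=0,
            direction_of_reference=r.direction_of_reference,
        )
        for r in table.itertuples(index=False)
    ]


def load_flow_counts() -> pd.DataFrame:
    table = _fixture("flow_counts.tsv")
    table["count"] = table["count"].astype(int)
    return table


def load_known_target_fixture() -> set[str]:
    return set(_fixture("known_targets.tsv")["target_name"])


# ---------------------------------------------------------------------------
# operations

def split_known_vs_novel(
    druggable: list[cat.DrugProject],
    known_indications: tuple[str, ...] = DEFAULT_KNOWN_VOCABULARY,
) -> tuple[set[str], set[str]]:
    """Partition druggable targets into known anti-diabetic vs novel.

    A target is *known* when at least one of its projects carries an
    indication matching the vocabulary (case-insensitive substring).
    The partition is exhaustive and disjoint at target level.
    """
    if not known_indications:
        raise ConfigurationError("known-indication vocabulary is empty")
    vocab = tuple(v.casefold() for v in known_indications)
    known: set[str] = set()
    all_targets: set[str] = set()
    for project in druggable:
        all_targets.add(project.target_accession)
        indication = project.indication.casefold()
        if any(v in indication for v in vocab):
            known.add(project.target_accession)
    return known, all_targets - known


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict | str | Path, out_dir: Optional[Path] = None) -> dict:
    """Run the full funnel and write every stage output.

    *config* is a YAML path or an equivalent dict with keys ``mode``
    (``synthetic`` or ``fixtures``), ``seed``, ``alpha``, ``n_perm`` and,
    in synthetic mode, any :class:`~drugrepo.simulate.SimulationConfig`
    field under ``simulation``.  Returns a dict with the
    :class:`FunnelReport`, the repurposing table, the support
    classification and all intermediate artifacts; TSV outputs land in
    *out_dir* when given.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    mode = config.get("mode", "synthetic")
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    n_perm = int(config.get("n_perm", 1000))

    if mode == "fixtures":
        result = _run_fixture_mode(alpha)
    elif mode == "synthetic":
        sim_kwargs = dict(config.get("simulation", {}))
        sim_kwargs.setdefault("seed", seed)
        result = _run_synthetic_mode(
            sim.SimulationConfig(**sim_kwargs), alpha=alpha, n_perm=n_perm
        )
    else:
        raise ConfigurationError(f"unknown pipeline mode {mode!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        _write(result["funnel"].to_frame(), out_dir / "funnel.tsv")
        _write(result["repurposing_table"], out_dir / "repurposing_table.tsv")
        _write(result["supported_drugs"], out_dir / "supported_drugs.tsv")
        for name, frame in result.get("exclusions", {}).items():
            _write(frame, out_dir / "exclusions" / f"{name}.tsv")
        if "flow_comparison" in result:
            _write(result["flow_comparison"], out_dir / "flow_comparison.tsv")
    return result


def _support_frame(classification: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(classification.items()), columns=["drug_name", "support"]
    )


def _run_fixture_mode(alpha: float) -> dict:
    """Replay the packaged study tables through the downstream stages."""
    candidates = load_repurposing_fixture()
    annotations = load_annotation_fixture()

    retained, stage_log = cat.filter_stage(candidates)
    filtered = patho.apply_pathogenesis_filter(retained, annotations)
    results = load_association_fixture()
    classification = conn.classify_support(results, alpha=alpha)
    # drugs in the repurposing table without an association row have no
    # profile data at all
    for drug in {p.drug_name for p in retained}:
        classification.setdefault(drug, "no_data")
    supported = sorted(d for d, s in classification.items() if s == "supported")

    known_names = {n.casefold() for n in load_known_target_fixture()}
    known_here = {
        p.target_accession for p in retained
        if p.target_name.casefold() in known_names
    }

    flow = load_flow_counts()
    printed = dict(zip(flow["quantity"], flow["count"]))
    computed = {
        "druggable_targets": len({p.target_accession for p in retained}),
        "therapeutic_targets": filtered["n_therapeutic_targets"],
        "therapeutic_drugs": filtered["n_unique_drugs"],
        "supported_drugs": len(supported),
    }
    comparison = pd.DataFrame(
        [
            {
                "quantity": q,
                "computed": computed.get(q, pd.NA),
                "printed": printed.get(q, pd.NA),
                "agrees": computed.get(q) == printed.get(q)
                if q in computed and q in printed else pd.NA,
            }
            for q in sorted(set(computed) | set(printed))
        ]
    )

    funnel = FunnelReport(
        stage_counts=[
            ("risk_proteins", printed["risk_proteins"]),
            ("targets_with_projects", printed["targets_with_projects"]),
            ("druggable_targets", printed["druggable_targets"]),
            ("known_antidiabetic_targets", printed["known_antidiabetic_targets"]),
            ("novel_targets", printed["novel_targets"]),
            ("therapeutic_drugs", printed["therapeutic_drugs"]),
            ("therapeutic_targets", filtered["n_therapeutic_targets"]),
            ("supported_drugs", len(supported)),
        ]
    )
    return {
        "mode": "fixtures",
        "funnel": funnel,
        "repurposing_table": filtered["repurposing_table"],
        "filtered": filtered,
        "classification": classification,
        "supported_drugs": _support_frame(classification),
        "supported_list": supported,
        "known_targets_here": known_here,
        "flow_comparison": comparison,
        "exclusions": {"stage": stage_log},
    }


def _run_synthetic_mode(
    config: sim.SimulationConfig, *, alpha: float, n_perm: int
) -> dict:
    """End-to-end run on generated inputs; ground truth travels alongside."""
    gene_t, protein_t, metabolite_t, ev_truth = sim.generate_evidence(config)
    map_table, map_truth = sim.generate_metabolite_map(
        config, metabolites=metabolite_t["identifier"].tolist()
    )

    gene_records = [
        ev.EvidenceRecord(source="gwas", identifier=r.identifier,
                          accession=r.accession, phenotype=r.phenotype)
        for r in gene_t.itertuples(index=False)
    ]
    protein_records = [
        ev.EvidenceRecord(source="proteomics", identifier=r.identifier,
                          accession=r.accession, phenotype=r.phenotype)
        for r in protein_t.itertuples(index=False)
    ]
    links = [
        net.MetaboliteLink(metabolite=r.metabolite, protein=r.protein,
                           link_role=r.link_role)
        for r in map_table.itertuples(index=False)
    ]
    mapped_links, unmapped = net.map_metabolites(
        metabolite_t["identifier"].tolist(), links
    )
    graph = net.build_network(mapped_links)
    risk, unresolved = ev.unify_risk_proteins(
        gene_records, protein_records,
        metabolite_proteins={l.protein for l in mapped_links},
    )
    if not risk.members:
        raise EmptyInputError("risk-protein unification produced no members")

    catalog_table, cat_truth = sim.generate_drug_catalog(config, sorted(risk.members))
    projects = [
        cat.DrugProject(
            target_accession=r.target_accession, target_name=r.target_name,
            drug_name=r.drug_name, indication=r.indication, stage_raw=r.stage,
            stage_class=cat.parse_stage(r.stage),
            action_mode=r.action_mode,
        )
        for r in catalog_table.itertuples(index=False)
    ]
    candidates, join_summary = cat.join_targets(risk, projects)
    retained, stage_log = cat.filter_stage(candidates)
    known_targets, novel_targets = split_known_vs_novel(retained)

    annotations, expected_verdicts = sim.generate_annotations(config, retained)
    filtered = patho.apply_pathogenesis_filter(retained, annotations)

    therapeutic_drugs = filtered["repurposed_drugs"]
    signature = sim.generate_signature(config)
    if len(therapeutic_drugs) >= 2:
        # profile ~10 instances per perturbagen: set-level enrichment with
        # only 1-2 member instances has no useful permutation resolution;
        # a single perturbagen would own every position (t = N), which the
        # permutation test cannot score
        n_labels = min(len(therapeutic_drugs), max(2, config.n_instances // 10))
        labels = therapeutic_drugs[:n_labels]
        linked = labels[: max(1, n_labels // 3)]
        profiles = sim.generate_profiles(
            config, signature, linked_labels=linked,
            all_labels=labels,
        )
        query = conn.connectivity_query(
            signature, profiles, n_perm=n_perm, seed=config.seed,
            reference_label="synthetic_reference",
            direction_of_reference="anti_diabetic",
        )
        results = [
            conn.ConnectivityResult(**row) for row in query.to_dict(orient="records")
        ]
    else:
        linked, query, results = [], pd.DataFrame(), []
    classification = conn.classify_support(results, alpha=alpha)
    for drug in therapeutic_drugs:
        classification.setdefault(drug, "no_data")
    supported = sorted(d for d, s in classification.items() if s == "supported")

    funnel = FunnelReport(
        stage_counts=[
            ("risk_proteins", len(risk)),
            ("targets_with_projects",
             len(join_summary["targets_with_projects"])),
            ("druggable_targets", len({p.target_accession for p in retained})),
            ("known_antidiabetic_targets", len(known_targets)),
            ("novel_targets", len(novel_targets)),
            ("therapeutic_drugs", filtered["n_unique_drugs"]),
            ("therapeutic_targets", filtered["n_therapeutic_targets"]),
            ("supported_drugs", len(supported)),
        ]
    )
    return {
        "mode": "synthetic",
        "funnel": funnel,
        "repurposing_table": filtered["repurposing_table"],
        "filtered": filtered,
        "classification": classification,
        "supported_drugs": _support_frame(classification),
        "supported_list": supported,
        "connectivity": query,
        "exclusions": {"stage": stage_log},
        "graph": graph,
        "truth": {
            "evidence": ev_truth,
            "metabolite_map": map_truth,
            "catalog": cat_truth,
            "expected_verdicts": expected_verdicts,
            "linked_drugs": list(linked),
        },
        "risk": risk,
        "unmapped_metabolites": unmapped,
        "unresolved_identifiers": unresolved,
    }
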