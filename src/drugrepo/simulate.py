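"""Synthetic input generators with planted ground truth.

Every input class the pipeline consumes — evidence tables, the
metabolite->protein mapping, the drug-project catalog, pathogenesis
annotations, and rank-permutation expression profiles — can be generated
here with a known answer recorded alongside, so each downstream stage can
be checked for exact ground-truth recovery without any external
database.

Default sizes mirror the scale of the curated study inputs this package
models (115 GWAS genes, 56 proteomics proteins, 227 metabolomics
metabolites, ~7.3 protein links per metabolite); the profile universe
defaults to 1000 genes, a desk-scale stand-in for a genome-wide array.
Distributions are deliberately simple — uniform sampling over identifier
universes, categorical sampling for labels — because analyzability, not
biological realism, is the generators' job.

A single root seed drives the whole module; each generator derives its
own named substream, so adding a generator never perturbs another's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import DrugProject, INCLUDABLE_STAGES, parse_stage
from .connectivity import QuerySignature, RankedProfile
from .errors import ConfigurationError, ValidationError
from .evidence import PHENOTYPES
from .pathogenesis import PathogenesisAnnotation

# fixed substream keys: appending new generators must not shift existing ones
_STREAMS = {
    "evidence": 0,
    "metabolite_map": 1,
    "catalog": 2,
    "profiles": 3,
    "annotations": 4,
    "signature": 5,
}

#: raw stage dialects emitted per stage class, exercising the normaliser
STAGE_DIALECTS = {
    "approved": ("Approved", "Approval", "Marketed"),
    "clinical": ("Phase I", "Phase II", "Phase III", "Phase I/II",
                 "Phase III completed", "Clinical trial"),
    "preclinical": ("Preclinical", "Pre-clinical"),
    "research": ("Research", "Experimental"),
    "withdrawn_or_suspended_clinical": (
        "Withdrawn", "Suspended in Phase II", "Discontinued in phase II",
        "Terminated in phase I", "Phase III withdraw",
    ),
}


def _default_stage_distribution() -> dict[str, float]:
    return {
        "approved": 0.30,
        "clinical": 0.30,
        "preclinical": 0.20,
        "research": 0.15,
        "withdrawn_or_suspended_clinical": 0.05,
    }


def _default_action_distribution() -> dict[str, float]:
    return {
        "inhibitor": 0.30,
        "antagonist": 0.20,
        "agonist": 0.20,
        "activator": 0.15,
        "modulator_unknown": 0.15,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-input generators.

    ``n_genes`` is the identifier-universe size shared by evidence and
    profiles.  ``overlap_fraction`` controls how many accessions the gene
    and protein evidence share (``floor(overlap_fraction * min(hit
    counts))`` members).  ``signal_strength`` is the fraction of query
    tags planted into the extreme ranks of a linked perturbagen's
    profiles.
    """

    seed: int = 0
    n_genes: int = 1000
    n_gene_hits: int = 115
    n_protein_hits: int = 56
    n_metabolites: int = 227
    overlap_fraction: float = 0.1
    mean_links_per_metabolite: float = 7.3
    n_drug_projects: int = 500
    stage_distribution: dict[str, float] = field(
        default_factory=_default_stage_distribution
    )
    action_mode_distribution: dict[str, float] = field(
        default_factory=_default_action_distribution
    )
    n_instances: int = 100
    tag_size: int = 20
    signal_strength: float = 1.0
    risk_target_fraction: float = 0.5
    known_indication_fraction: float = 0.05

    def validate(self) -> None:
        for name in ("n_genes", "n_gene_hits", "n_protein_hits", "n_metabolites",
                     "n_drug_projects", "n_instances", "tag_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("overlap_fraction", "signal_strength",
                     "risk_target_fraction", "known_indication_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.mean_links_per_metabolite <= 0:
            raise ConfigurationError("mean_links_per_metabolite must be positive")
        if self.tag_size > self.n_genes / 2:
            raise ConfigurationError("tag_size must not exceed n_genes / 2")
        if max(self.n_gene_hits, self.n_protein_hits) > self.n_genes:
            raise ConfigurationError("hit counts cannot exceed n_genes universe")
        for name in ("stage_distribution", "action_mode_distribution"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"{name} contains a negative probability")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic named substream of the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )

    # identifier universes -------------------------------------------------
    def gene_universe(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    def protein_universe(self) -> list[str]:
        return [f"P{i:05d}" for i in range(1, self.n_genes + 1)]


@dataclass
class EvidenceTruth:
    gene_accessions: set[str]
    protein_accessions: set[str]
    union: set[str]


def generate_evidence(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, EvidenceTruth]:
    """Generate the three curated evidence tables plus the ground-truth union.

    The gene and protein tables share exactly
    ``floor(overlap_fraction * min(n_gene_hits, n_protein_hits))``
    accessions; metabolite evidence is a disjoint name list (its protein
    contribution arrives through the mapping table).
    """
    config.validate()
    rng = config.rng("evidence")
    universe = np.array(config.protein_universe())
    phenotypes = list(PHENOTYPES)

    gene_acc = rng.choice(universe, size=config.n_gene_hits, replace=False)
    n_shared = int(config.overlap_fraction * min(config.n_gene_hits,
                                                 config.n_protein_hits))
    shared = rng.choice(gene_acc, size=n_shared, replace=False)
    rest_pool = np.array(sorted(set(universe) - set(gene_acc)))
    n_new = config.n_protein_hits - n_shared
    if n_new > rest_pool.size:
        raise ConfigurationError("protein universe too small for requested hits")
    protein_acc = np.concatenate([shared, rng.choice(rest_pool, size=n_new,
                                                     replace=False)])

    def pick_phenotypes(k):
        return rng.choice(phenotypes, size=k)

    gene_table = pd.DataFrame(
        {
            "identifier": [f"SYM_{a}" for a in gene_acc],
            "accession": gene_acc,
            "phenotype": pick_phenotypes(config.n_gene_hits),
            "ethnicity": rng.choice(["european", "east_asian", "mixed"],
                                    size=config.n_gene_hits),
        }
    )
    protein_table = pd.DataFrame(
        {
            "identifier": protein_acc,
            "accession": protein_acc,
            "phenotype": pick_phenotypes(config.n_protein_hits),
            "direction": rng.choice(["up", "down"], size=config.n_protein_hits),
            "sample_type": rng.choice(["serum", "plasma", "tissue"],
                                      size=config.n_protein_hits),
        }
    )
    metabolites = [f"MET_{i:04d}" for i in range(1, config.n_metabolites + 1)]
    metabolite_table = pd.DataFrame(
        {
            "identifier": metabolites,
            "phenotype": pick_phenotypes(config.n_metabolites),
            "direction": rng.choice(["up", "down"], size=config.n_metabolites),
            "sample_type": rng.choice(["serum", "plasma", "urine"],
                                      size=config.n_metabolites),
        }
    )
    truth = EvidenceTruth(
        gene_accessions=set(gene_acc.tolist()),
        protein_accessions=set(protein_acc.tolist()),
        union=set(gene_acc.tolist()) | set(protein_acc.tolist()),
    )
    return gene_table, protein_table, metabolite_table, truth


@dataclass
class MetaboliteMapTruth:
    n_pairs: int
    degrees: dict[str, int]
    proteins: set[str]


def generate_metabolite_map(
    config: SimulationConfig,
    metabolites: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, MetaboliteMapTruth]:
    """Generate the HMDB-style metabolite->protein mapping table.

    Per-metabolite out-degree is ``floor(mean) + Bernoulli(frac(mean))``
    with a floor of 1, so an integer mean forces an exact out-degree.
    """
    config.validate()
    if metabolites is None:
        metabolites = [f"MET_{i:04d}" for i in range(1, config.n_metabolites + 1)]
    if not metabolites:
        raise ConfigurationError("n_metabolites must be positive")
    rng = config.rng("metabolite_map")
    universe = np.array(config.protein_universe())
    base = int(np.floor(config.mean_links_per_metabolite))
    frac = config.mean_links_per_metabolite - base

    rows, degrees = [], {}
    for met in metabolites:
        degree = max(1, base + (1 if rng.random() < frac else 0))
        degree = min(degree, universe.size)
        proteins = rng.choice(universe, size=degree, replace=False)
        roles = rng.choice(["enzyme", "transporter"], size=degree, p=[0.8, 0.2])
        for prot, role in zip(proteins, roles):
            rows.append({"metabolite": met, "protein": prot, "link_role": role})
        degrees[met] = degree
    table = pd.DataFrame(rows, columns=["metabolite", "protein", "link_role"])
    truth = MetaboliteMapTruth(
        n_pairs=len(table),
        degrees=degrees,
        proteins=set(table["protein"].tolist()),
    )
    return table, truth


@dataclass
class CatalogTruth:
    candidate_rows: list[int]           # catalog row ids targeting risk proteins
    survivor_rows: list[int]            # candidates that pass the stage filter
    targets_with_projects: set[str]
    known_targets: set[str]             # risk targets with a diabetes indication


def generate_drug_catalog(
    config: SimulationConfig, risk_proteins: Sequence[str]
) -> tuple[pd.DataFrame, CatalogTruth]:
    """Generate a TTD-style drug-project catalog with planted overlap.

    Each project targets a risk protein with probability
    ``risk_target_fraction`` (else a decoy accession outside the risk
    set); stage and action-mode labels are drawn from the configured
    categorical distributions, stages rendered in random raw dialects.
    """
    config.validate()
    risk = sorted(set(risk_proteins))
    if not risk:
        raise ConfigurationError("risk_proteins must be nonempty")
    rng = config.rng("catalog")
    stage_classes = list(config.stage_distribution)
    stage_p = np.array([config.stage_distribution[s] for s in stage_classes])
    modes = list(config.action_mode_distribution)
    mode_p = np.array([config.action_mode_distribution[m] for m in modes])

    rows = []
    candidate_rows, survivor_rows = [], []
    targets_with_projects: set[str] = set()
    known_targets: set[str] = set()
    for i in range(config.n_drug_projects):
        on_risk = rng.random() < config.risk_target_fraction
        if on_risk:
            target = risk[int(rng.integers(len(risk)))]
        else:
            target = f"DECOY{int(rng.integers(10 * config.n_genes)):06d}"
        stage_class = stage_classes[int(rng.choice(len(stage_classes), p=stage_p))]
        dialects = STAGE_DIALECTS[stage_class]
        stage_raw = dialects[int(rng.integers(len(dialects)))]
        assert parse_stage(stage_raw) == stage_class
        mode = modes[int(rng.choice(len(modes), p=mode_p))]
        diabetes = rng.random() < config.known_indication_fraction
        indication = "Type 2 diabetes" if diabetes else \
            ["Hypertension", "Pain", "Schizophrenia", "Asthma"][int(rng.integers(4))]
        rows.append(
            {
                "target_accession": target,
                "target_name": f"name_{target}",
                "drug_name": f"drug_{i:04d}",
                "indication": indication,
                "stage": stage_raw,
                "action_mode": mode,
            }
        )
        if on_risk:
            candidate_rows.append(i)
            targets_with_projects.add(target)
            if diabetes:
                known_targets.add(target)
            if stage_class in INCLUDABLE_STAGES:
                survivor_rows.append(i)
    table = pd.DataFrame(rows)
    truth = CatalogTruth(
        candidate_rows=candidate_rows,
        survivor_rows=survivor_rows,
        targets_with_projects=targets_with_projects,
        known_targets=known_targets,
    )
    return table, truth


#: scenario -> (annotation direction, valence, scope) planted per target
_ANNOTATION_SCENARIOS = (
    ("gof", "harmful", "direct_diabetes"),
    ("gof", "beneficial", "direct_diabetes"),
    ("lof", "harmful", "direct_diabetes"),
    ("lof", "beneficial", "direct_diabetes"),
    (None, None, "complication_only_marker"),
    (None, None, "none"),
)

# ground-truth verdict lookup, written straight from the mechanistic rule
# (LOF-like drug helped by harmful-GOF / beneficial-LOF targets, mirrored
# for GOF-like), independent of the rule engine's code path
_EXPECTED_VERDICT = {
    ("lof_like", ("gof", "harmful")): "therapeutic",
    ("lof_like", ("lof", "beneficial")): "therapeutic",
    ("lof_like", ("gof", "beneficial")): "aggravating",
    ("lof_like", ("lof", "harmful")): "aggravating",
    ("gof_like", ("gof", "harmful")): "aggravating",
    ("gof_like", ("lof", "beneficial")): "aggravating",
    ("gof_like", ("gof", "beneficial")): "therapeutic",
    ("gof_like", ("lof", "harmful")): "therapeutic",
}

_MODE_EFFECT = {
    "inhibitor": "lof_like",
    "antagonist": "lof_like",
    "agonist": "gof_like",
    "activator": "gof_like",
    "modulator_unknown": "unknown",
}


def generate_annotations(
    config: SimulationConfig, candidates: Sequence[DrugProject]
) -> tuple[list[PathogenesisAnnotation], dict[tuple[str, str], str]]:
    """Plant one pathogenesis scenario per candidate target.

    Returns the annotation list plus the expected verdict for every
    (target, drug) project pair, derived from a hand-written truth table
    rather than the rule engine itself.
    """
    config.validate()
    rng = config.rng("annotations")
    targets = sorted({p.target_accession for p in candidates})
    scenario_of: dict[str, tuple] = {}
    annotations: list[PathogenesisAnnotation] = []
    for target in targets:
        scenario = _ANNOTATION_SCENARIOS[int(rng.integers(len(_ANNOTATION_SCENARIOS)))]
        scenario_of[target] = scenario
        direction, valence, scope = scenario
        if scope == "none":
            annotations.append(
                PathogenesisAnnotation(target_accession=target, direction=None,
                                       valence=None, link_scope="none")
            )
        elif scope == "complication_only_marker":
            annotations.append(
                PathogenesisAnnotation(
                    target_accession=target, direction="gof", valence="harmful",
                    link_scope="complication_only",
                    free_text="synthetic complication-only link",
                )
            )
        else:
            annotations.append(
                PathogenesisAnnotation(
                    target_accession=target, direction=direction, valence=valence,
                    link_scope=scope,
                    free_text=f"synthetic {direction},{valence}",
                )
            )

    expected: dict[tuple[str, str], str] = {}
    for project in candidates:
        direction, valence, scope = scenario_of[project.target_accession]
        effect = _MODE_EFFECT[project.action_mode]
        key = (project.target_accession, project.drug_name)
        if scope == "none":
            expected[key] = "excluded_no_link"
        elif scope == "complication_only_marker":
            expected[key] = "excluded_complication"
        elif effect == "unknown":
            expected[key] = "indeterminate"
        else:
            expected[key] = _EXPECTED_VERDICT[(effect, (direction, valence))]
    return annotations, expected


def generate_signature(config: SimulationConfig) -> QuerySignature:
    """Draw disjoint up/down tag sets of size ``tag_size`` from the universe."""
    config.validate()
    rng = config.rng("signature")
    picks = rng.choice(config.gene_universe(), size=2 * config.tag_size,
                       replace=False)
    return QuerySignature(
        up_tags=frozenset(picks[: config.tag_size]),
        down_tags=frozenset(picks[config.tag_size:]),
    )


def generate_profiles(
    config: SimulationConfig,
    signature: QuerySignature,
    linked_labels: Sequence[str],
    all_labels: Optional[Sequence[str]] = None,
) -> list[RankedProfile]:
    """Generate ``n_instances`` rank-permutation profiles.

    Instances cycle through *all_labels* (default: the linked labels plus
    enough ``null_XX`` fill labels for ten perturbagens total).  For a
    linked perturbagen's instance, ``floor(signal_strength * |tags|)`` up
    tags are placed uniformly among the top ``tag_size`` ranks and as
    many down tags among the bottom ``tag_size`` ranks; all remaining
    genes receive a uniform random permutation of the remaining ranks.
    Unlinked instances are uniform random permutations.
    """
    config.validate()
    if signature.up_tags & signature.down_tags:
        raise ValidationError("up and down tag sets overlap")
    genes = config.gene_universe()
    missing = (set(signature.up_tags) | set(signature.down_tags)) - set(genes)
    if missing:
        raise ValidationError(f"signature tags outside universe: {sorted(missing)[:5]}")
    if all_labels is None:
        n_fill = max(0, 10 - len(linked_labels))
        all_labels = list(linked_labels) + [f"null_{i:02d}" for i in range(n_fill)]
    linked = set(linked_labels)
    rng = config.rng("profiles")
    n = config.n_genes
    top_zone = list(range(1, config.tag_size + 1))
    bottom_zone = list(range(n - config.tag_size + 1, n + 1))

    profiles = []
    for i in range(config.n_instances):
        label = all_labels[i % len(all_labels)]
        ranks: dict[str, int] = {}
        if label in linked and config.signal_strength > 0:
            n_up = int(np.floor(config.signal_strength * len(signature.up_tags)))
            n_down = int(np.floor(config.signal_strength * len(signature.down_tags)))
            up_planted = list(rng.choice(sorted(signature.up_tags), size=n_up,
                                         replace=False))
            down_planted = list(rng.choice(sorted(signature.down_tags), size=n_down,
                                           replace=False))
            up_ranks = rng.choice(top_zone, size=n_up, replace=False)
            down_ranks = rng.choice(bottom_zone, size=n_down, replace=False)
            ranks.update(zip(up_planted, (int(r) for r in up_ranks)))
            ranks.update(zip(down_planted, (int(r) for r in down_ranks)))
        remaining_genes = [g for g in genes if g not in ranks]
        remaining_ranks = sorted(set(range(1, n + 1)) - set(ranks.values()))
        perm = rng.permutation(len(remaining_ranks))
        for g, j in zip(remaining_genes, perm):
            ranks[g] = remaining_ranks[int(j)]
        profiles.append(
            RankedProfile(instance_id=f"inst_{i:04d}", perturbagen=label,
                          ranks=ranks)
        )
    return profiles


# ---------------------------------------------------------------------------
# TSV writers (one-line-header tab-separated outputs)

def write_profiles(profiles: Sequence[RankedProfile], out_dir) -> tuple[Path, Path]:
    """Write a gene-by-instance rank matrix TSV plus instance metadata TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = sorted(profiles[0].ranks)
    matrix = pd.DataFrame(
        {p.instance_id: [p.ranks[g] for g in genes] for p in profiles},
        index=pd.Index(genes, name="gene"),
    )
    matrix_path = out_dir / "profiles.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame(
        [{"instance_id": p.instance_id, "perturbagen": p.perturbagen}
         for p in profiles]
    )
    meta_path = out_dir / "instances.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    return matrix_path, meta_path


def read_profiles(matrix_path, meta_path) -> list[RankedProfile]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("instance_id")
    return [
        RankedProfile(
            instance_id=col,
            perturbagen=str(meta.loc[col, "perturbagen"]),
            ranks={g: int(r) for g, r in matrix[col].items()},
        )
        for col in matrix.columns
    ]
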