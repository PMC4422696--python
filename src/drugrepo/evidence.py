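"""Curated omics evidence ingest and risk-protein unification.

Reads the three curated evidence tables (GWAS genes, proteomics proteins,
metabolomics metabolites), validates them against the closed diabetes
phenotype vocabulary, and unifies gene- and protein-level accessions with
the metabolite-derived protein set into one deduplicated risk-protein set
with per-source provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

SOURCES = ("gwas", "proteomics", "metabolomics")

#: Closed phenotype vocabulary; keys are canonical codes, values the
#: case-folded synonyms accepted in input tables.
PHENOTYPES: dict[str, tuple[str, ...]] = {
    "t1d": ("t1d", "type 1 diabetes", "insulin dependent diabetes mellitus", "iddm"),
    "t2d": ("t2d", "type 2 diabetes", "niddm"),
    "gestational": ("gestational", "gestational diabetes"),
    "igt": ("igt", "impaired glucose tolerance"),
    "ifg": ("ifg", "impaired fasting glycemia", "impaired fasting glucose"),
    "insulin_resistance": ("insulin_resistance", "insulin resistance"),
}

_SYNONYM_TO_CODE = {
    syn: code for code, syns in PHENOTYPES.items() for syn in syns
}

DIRECTIONS = ("up", "down", "association_only")

_MANDATORY_COLUMNS = ("identifier", "phenotype")
_OPTIONAL_COLUMNS = ("accession", "direction", "sample_type", "ethnicity", "method")


def normalize_identifier(text: str) -> str:
    """Trim whitespace and case-fold; curated tables are typographically messy."""
    return str(text).strip().upper()


def normalize_phenotype(text: str) -> Optional[str]:
    """Map a free-text phenotype label onto its canonical code, or None."""
    return _SYNONYM_TO_CODE.get(str(text).strip().casefold())


@dataclass(frozen=True)
class EvidenceRecord:
    """One curated omics finding tied to a diabetes phenotype."""

    source: str
    identifier: str
    phenotype: str
    accession: Optional[str] = None
    direction: Optional[str] = None
    sample_type: Optional[str] = None
    ethnicity: Optional[str] = None
    method: Optional[str] = None

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValidationError(f"unknown evidence source {self.source!r}")
        if not self.identifier:
            raise ValidationError("identifier must be nonempty")
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype code {self.phenotype!r}")
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass
class RiskProteinSet:
    """Deduplicated union of risk-protein accessions with provenance."""

    members: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        missing = self.members - set(self.provenance)
        if missing or any(not v for v in self.provenance.values()):
            raise ValidationError("every member needs at least one provenance source")

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"accession": acc, "sources": ";".join(sorted(self.provenance[acc]))}
            for acc in sorted(self.members)
        ]
        return pd.DataFrame(rows, columns=["accession", "sources"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_evidence_table(path, source: str) -> list[EvidenceRecord]:
    """Read one curated evidence TSV into validated records.

    Mandatory columns: ``identifier`` and ``phenotype``; the optional
    extraction fields (accession, direction, sample type, ethnicity,
    method) are carried when present.  Rows whose phenotype falls outside
    the closed vocabulary are rejected together, with 1-based data row
    numbers in the error message.  Duplicate rows collapse to one record.
    """
    if source not in SOURCES:
        raise ValidationError(f"unknown evidence source {source!r}")
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing} for source {source!r}"
        )

    bad_rows = []
    records: dict[tuple, EvidenceRecord] = {}
    for i, row in enumerate(table.itertuples(index=False), start=1):
        row = row._asdict()
        code = normalize_phenotype(row["phenotype"])
        if code is None:
            bad_rows.append((i, row["phenotype"]))
            continue
        extras = {}
        for col in _OPTIONAL_COLUMNS:
            value = str(row.get(col, "")).strip()
            if value:
                extras[col] = (
                    normalize_identifier(value) if col == "accession"
                    else value.casefold()
                )
        rec = EvidenceRecord(
            source=source,
            identifier=normalize_identifier(row["identifier"]),
            phenotype=code,
            **extras,
        )
        records.setdefault((rec.identifier, rec.phenotype, rec.accession), rec)
    if bad_rows:
        listing = ", ".join(f"row {i}: {ph!r}" for i, ph in bad_rows)
        raise ValidationError(
            f"{path.name}: phenotype outside the closed vocabulary ({listing})"
        )
    return list(records.values())


def resolve_accessions(
    records: Sequence[EvidenceRecord],
    id_map: Optional[Mapping[str, str]] = None,
) -> tuple[set[str], list[str]]:
    """Resolve records to stable protein accessions.

    A record's own ``accession`` field wins; otherwise the symbol is
    looked up in *id_map* (symbol -> accession, matched after
    normalisation).  Unresolvable identifiers are returned for reporting,
    never silently dropped.
    """
    lookup = {
        normalize_identifier(k): normalize_identifier(v)
        for k, v in (id_map or {}).items()
    }
    resolved: set[str] = set()
    unresolved: list[str] = []
    for rec in records:
        ident = normalize_identifier(rec.identifier)
        if rec.accession:
            resolved.add(normalize_identifier(rec.accession))
        elif ident in lookup:
            resolved.add(lookup[ident])
        else:
            unresolved.append(rec.identifier)
    return resolved, unresolved


def unify_risk_proteins(
    gene_evidence: Sequence[EvidenceRecord] = (),
    protein_evidence: Sequence[EvidenceRecord] = (),
    metabolite_proteins: Iterable[str] = (),
    id_map: Optional[Mapping[str, str]] = None,
) -> tuple[RiskProteinSet, list[str]]:
    """Union the three accession sets into one risk-protein set.

    Returns the set plus the list of unresolvable gene/protein
    identifiers.  Provenance records every source that contributed each
    member; the union is idempotent and order-insensitive.
    """
    gene_acc, unresolved_g = resolve_accessions(gene_evidence, id_map)
    prot_acc, unresolved_p = resolve_accessions(protein_evidence, id_map)
    met_acc = {normalize_identifier(a) for a in metabolite_proteins}
    if not (gene_acc or prot_acc or met_acc):
        raise EmptyInputError("all three evidence inputs are empty")

    provenance: dict[str, set[str]] = {}
    for acc_set, source in (
        (gene_acc, "gwas"),
        (prot_acc, "proteomics"),
        (met_acc, "metabolomics"),
    ):
        for acc in acc_set:
            provenance.setdefault(acc, set()).add(source)
    risk = RiskProteinSet(members=set(provenance), provenance=provenance)
    return risk, unresolved_g + unresolved_p
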