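"""Bipartite metabolite–protein network construction and export.

Diabetes-associated metabolites are linked to the enzymes and
transporters that turn them over (an HMDB-style mapping table), and the
resulting bipartite graph is summarised and exported in
Cytoscape-readable formats (GraphML, SIF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .evidence import EvidenceRecord, normalize_identifier

LINK_ROLES = ("enzyme", "transporter")


@dataclass(frozen=True)
class MetaboliteLink:
    """One metabolite -> protein association (enzyme or transporter)."""

    metabolite: str
    protein: str
    link_role: str = "enzyme"

    def __post_init__(self):
        if not self.metabolite or not self.protein:
            raise ValidationError("metabolite and protein must be nonempty")
        # normalized plain-str identifiers (numpy scalars break GraphML export)
        object.__setattr__(self, "metabolite", normalize_identifier(self.metabolite))
        object.__setattr__(self, "protein", normalize_identifier(self.protein))
        if self.link_role not in LINK_ROLES:
            raise ValidationError(f"unknown link role {self.link_role!r}")


def load_mapping_table(path) -> list[MetaboliteLink]:
    """Read a metabolite->protein mapping TSV (metabolite, protein[, link_role])."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"metabolite", "protein"} <= set(table.columns):
        raise ValidationError(
            f"{Path(path).name}: mapping table needs 'metabolite' and 'protein' columns"
        )
    links = []
    for row in table.itertuples(index=False):
        role = getattr(row, "link_role", "") or "enzyme"
        links.append(
            MetaboliteLink(
                metabolite=normalize_identifier(row.metabolite),
                protein=normalize_identifier(row.protein),
                link_role=role.strip().casefold(),
            )
        )
    return links


def map_metabolites(
    metabolite_evidence: Sequence[Union[EvidenceRecord, str]],
    mapping_table: Sequence[MetaboliteLink],
) -> tuple[list[MetaboliteLink], list[str]]:
    """Select mapping rows whose metabolite occurs in the evidence.

    Returns the matching links plus the evidence metabolites that have no
    mapping at all (reported, not dropped silently).  Matching is by
    normalized metabolite name.
    """
    if not mapping_table:
        raise ConfigurationError("mapping table is empty")
    wanted = {
        normalize_identifier(m.identifier if isinstance(m, EvidenceRecord) else m)
        for m in metabolite_evidence
    }
    links = [l for l in mapping_table if normalize_identifier(l.metabolite) in wanted]
    mapped = {normalize_identifier(l.metabolite) for l in links}
    unmapped = sorted(wanted - mapped)
    return links, unmapped


class BipartiteGraph:
    """Strictly bipartite metabolite–protein graph.

    Thin wrapper over :class:`networkx.Graph`; every node carries a
    ``kind`` attribute (``metabolite`` or ``protein``) and duplicate
    (metabolite, protein) links collapse to one edge carrying the union
    of their roles.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.validate()

    @property
    def metabolite_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "metabolite"}

    @property
    def protein_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "protein"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        met = self.metabolite_nodes
        return {(u, v) if u in met else (v, u) for u, v in self.graph.edges()}

    def validate(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("kind") not in ("metabolite", "protein"):
                raise ValidationError(f"node {node!r} lacks a bipartite class")
        met = self.metabolite_nodes
        for u, v in self.graph.edges():
            if (u in met) == (v in met):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) joins two nodes of the same class"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BipartiteGraph)
            and self.metabolite_nodes == other.metabolite_nodes
            and self.protein_nodes == other.protein_nodes
            and self.edges == other.edges
        )


def build_network(links: Sequence[MetaboliteLink]) -> BipartiteGraph:
    """Build the deduplicated bipartite graph from a link list."""
    if not links:
        raise ValidationError("cannot build a network from zero links")
    g = nx.Graph()
    for link in links:
        m = f"met:{link.metabolite}"
        p = f"prot:{link.protein}"
        g.add_node(m, kind="metabolite", name=link.metabolite)
        g.add_node(p, kind="protein", name=link.protein)
        if g.has_edge(m, p):
            roles = set(g.edges[m, p]["roles"].split(";"))
            roles.add(link.link_role)
            g.edges[m, p]["roles"] = ";".join(sorted(roles))
        else:
            g.add_edge(m, p, roles=link.link_role)
    return BipartiteGraph(g)


def network_summary(graph: BipartiteGraph) -> dict:
    """Node/edge counts, per-class degree distributions and top-degree nodes."""
    g = graph.graph
    met, prot = graph.metabolite_nodes, graph.protein_nodes
    met_deg = {n: g.degree(n) for n in met}
    prot_deg = {n: g.degree(n) for n in prot}
    top = lambda d, k=5: sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return {
        "n_metabolites": len(met),
        "n_proteins": len(prot),
        "n_edges": g.number_of_edges(),
        "metabolite_degrees": met_deg,
        "protein_degrees": prot_deg,
        "top_metabolites": top(met_deg),
        "top_proteins": top(prot_deg),
    }


def export_graph(graph: BipartiteGraph, path, fmt: str = "graphml") -> Path:
    """Write the graph as GraphML or SIF (one edge per line)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph.graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            met = graph.metabolite_nodes
            for u, v in sorted(graph.graph.edges()):
                m, p = (u, v) if u in met else (v, u)
                fh.write(f"{graph.graph.nodes[m]['name']}\tlinks\t"
                         f"{graph.graph.nodes[p]['name']}\n")
    else:
        raise ConfigurationError(f"unsupported export format {fmt!r}")
    return path


def import_graphml(path) -> BipartiteGraph:
    """Round-trip reader for :func:`export_graph` GraphML output."""
    return BipartiteGraph(nx.read_graphml(path))
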