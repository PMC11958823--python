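"""The PD knowledge graph: a typed property graph over study measurements.

Node labels: Gene (genes and imaged proteins share one label; an imaged
protein is a Gene node that participates in core-protein measurement edges,
optionally carrying a protein accession), Pathway, Disease, Drug, and
CellLineTimePoint (one cell line sampled at one organoid-culture day, e.g.
"GBA_3 D30"). Edge types: MEASURED_IN (gene -> cell-line-time-point, carrying
dataset provenance and, for transcriptomic records, log2fc / p_adjust /
direction), INVOLVED_IN (gene -> pathway), ASSOCIATED_WITH (gene -> disease),
TARGETED_BY (gene -> drug), INTERACTS_WITH (gene -> gene).

The graph is held in a :class:`networkx.MultiDiGraph`; construction is fully
deterministic given its inputs (stable iteration order, no randomness).
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

NODE_LABELS = ("Gene", "Pathway", "Disease", "Drug", "CellLineTimePoint")

EDGE_SCHEMA = {
    "MEASURED_IN": ("Gene", "CellLineTimePoint"),
    "INVOLVED_IN": ("Gene", "Pathway"),
    "ASSOCIATED_WITH": ("Gene", "Disease"),
    "TARGETED_BY": ("Gene", "Drug"),
    "INTERACTS_WITH": ("Gene", "Gene"),
}


def gene_id(symbol: str) -> str:
    return f"gene:{symbol}"


def pathway_id(name: str) -> str:
    return f"pathway:{name}"


def disease_id(name: str) -> str:
    return f"disease:{name}"


def drug_id(name: str) -> str:
    return f"drug:{name}"


def clt_id(cell_line: str, timepoint: int) -> str:
    # id format "<LINE> D<day>", e.g. "GBA_3 D30"
    return f"clt:{cell_line} D{timepoint}"


class KnowledgeGraph:
    """Typed property graph with a closed node-label / edge-type vocabulary."""

    def __init__(self, provenance: Mapping | None = None):
        self.g = nx.MultiDiGraph()
        self.provenance: dict = dict(provenance or {})

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, label: str, **properties) -> None:
        if label not in NODE_LABELS:
            raise ValueError(f"unknown node label {label!r}; allowed: {NODE_LABELS}")
        if node_id in self.g:
            existing = self.g.nodes[node_id]
            if existing["label"] != label:
                raise ValueError(
                    f"node {node_id!r} already exists with label {existing['label']!r}"
                )
            existing["properties"].update({k: v for k, v in properties.items() if v is not None})
            return
        self.g.add_node(node_id, label=label, properties={k: v for k, v in properties.items() if v is not None})

    def add_edge(self, source: str, edge_type: str, target: str, **properties) -> None:
        if edge_type not in EDGE_SCHEMA:
            raise ValueError(f"unknown edge type {edge_type!r}; allowed: {sorted(EDGE_SCHEMA)}")
        for endpoint in (source, target):
            if endpoint not in self.g:
                raise ValueError(f"edge endpoint {endpoint!r} does not exist")
        src_label, tgt_label = EDGE_SCHEMA[edge_type]
        if self.g.nodes[source]["label"] != src_label or self.g.nodes[target]["label"] != tgt_label:
            raise ValueError(
                f"{edge_type} requires ({src_label})->({tgt_label}), got "
                f"({self.g.nodes[source]['label']})->({self.g.nodes[target]['label']})"
            )
        self.g.add_edge(source, target, type=edge_type, properties=dict(properties))

    # -- inspection ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def label_of(self, node_id: str) -> str:
        return self.g.nodes[node_id]["label"]

    def nodes_with_label(self, label: str) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["label"] == label]

    def iter_edges(self, edge_type: str | None = None):
        """Yield (source, type, target, properties) tuples."""
        for u, v, data in self.g.edges(data=True):
            if edge_type is None or data["type"] == edge_type:
                yield u, data["type"], v, data["properties"]

    def report(self) -> dict:
        nodes: dict[str, int] = {}
        for _, d in self.g.nodes(data=True):
            nodes[d["label"]] = nodes.get(d["label"], 0) + 1
        edges: dict[str, int] = {}
        for _, _, d in self.g.edges(data=True):
            edges[d["type"]] = edges.get(d["type"], 0) + 1
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_by_label": nodes,
            "edges_by_type": edges,
            "dropped_edges": self.provenance.get("dropped_edges", 0),
        }

    def equals(self, other: "KnowledgeGraph") -> bool:
        """Structural equality on node ids/labels/properties and edge multisets."""
        mine = sorted((n, d["label"], json.dumps(d["properties"], sort_keys=True, default=str))
                      for n, d in self.g.nodes(data=True))
        theirs = sorted((n, d["label"], json.dumps(d["properties"], sort_keys=True, default=str))
                        for n, d in other.g.nodes(data=True))
        if mine != theirs:
            return False
        mine_e = sorted((u, d["type"], v, json.dumps(d["properties"], sort_keys=True, default=str))
                        for u, v, d in self.g.edges(data=True))
        theirs_e = sorted((u, d["type"], v, json.dumps(d["properties"], sort_keys=True, default=str))
                          for u, v, d in other.g.edges(data=True))
        return mine_e == theirs_e


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

def map_gene_ids(
    symbols: Iterable[str],
    mapping_table: pd.DataFrame | None,
) -> tuple[dict[str, str], list[str]]:
    """Map gene symbols to protein accessions; returns (mapped, unmapped).

    The mapping table has columns ``symbol`` and ``accession``. On conflicting
    duplicate rows the first occurrence wins (logged as a warning); an empty
    or absent table leaves every symbol unmapped (warning, not an error).
    """
    symbols = list(dict.fromkeys(symbols))
    if mapping_table is None or mapping_table.empty:
        if symbols:
            warnings.warn("empty gene-ID mapping table: all symbols unmapped", stacklevel=2)
        return {}, symbols
    missing = [c for c in ("symbol", "accession") if c not in mapping_table.columns]
    if missing:
        raise ValueError(f"mapping table missing columns: {missing}")

    lookup: dict[str, str] = {}
    conflicts = 0
    for sym, acc in zip(mapping_table["symbol"], mapping_table["accession"]):
        sym = str(sym).strip().upper()
        if sym in lookup:
            if lookup[sym] != acc:
                conflicts += 1
            continue
        lookup[sym] = str(acc)
    if conflicts:
        warnings.warn(f"{conflicts} conflicting duplicate mapping rows; first occurrence kept", stacklevel=2)

    mapped = {s: lookup[s] for s in symbols if s in lookup}
    unmapped = [s for s in symbols if s not in lookup]
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResourceFilters:
    """Declarative ingest filters for resource slices.

    ``interaction_types``: whitelist of protein-interaction types (None keeps
    all); ``disease_categories``: whitelist of disease categories, e.g.
    {"central nervous system"} (None keeps all). Synthetic slices typically
    bypass filtering by leaving both at None.
    """

    interaction_types: frozenset[str] | None = None
    disease_categories: frozenset[str] | None = None


def build_graph(corpus, slices=None, filters: ResourceFilters | None = None) -> KnowledgeGraph:
    """Assemble the knowledge graph from a corpus and resource slices.

    Creates one Gene node per unique measured symbol (DEG or core protein),
    one CellLineTimePoint node per configured (cell line, timepoint), a
    MEASURED_IN edge per DEG record and per core-protein presence, and
    resource edges (pathway involvement, disease association, drug targeting,
    protein interaction) only between entities present in the graph and rows
    passing the declared filters. Resource edges referencing genes absent from
    the corpus are dropped and counted -- never left dangling.
    """
    filters = filters or ResourceFilters()
    kg = KnowledgeGraph()
    dropped = 0

    deg_symbols = list(dict.fromkeys(corpus.degs["gene"])) if len(corpus.degs) else []
    core_symbols = list(dict.fromkeys(corpus.core_proteins["protein"])) if len(corpus.core_proteins) else []
    symbols = list(dict.fromkeys(deg_symbols + core_symbols))

    accessions, _unmapped = ({}, symbols)
    if slices is not None and getattr(slices, "mapping", None) is not None and symbols:
        accessions, _unmapped = map_gene_ids(symbols, slices.mapping)

    for sym in symbols:
        kg.add_node(gene_id(sym), "Gene", symbol=sym, accession=accessions.get(sym))

    used_datasets = set(corpus.degs["dataset"]) | set(corpus.core_proteins.get("dataset", pd.Series(dtype=str)))
    for dataset in corpus.datasets:
        if dataset not in used_datasets:
            continue
        cell_line, timepoint = corpus.dataset_context[dataset]
        kg.add_node(clt_id(cell_line, timepoint), "CellLineTimePoint",
                    cell_line=cell_line, timepoint=timepoint, dataset=dataset)

    for row in corpus.degs.itertuples(index=False):
        cell_line, timepoint = corpus.dataset_context[row.dataset]
        kg.add_edge(
            gene_id(row.gene), "MEASURED_IN", clt_id(cell_line, timepoint),
            dataset=row.dataset, log2fc=float(row.log2fc),
            p_adjust=float(row.p_adjust), direction=row.direction,
        )
    for row in corpus.core_proteins.itertuples(index=False):
        cell_line, timepoint = corpus.dataset_context[row.dataset]
        kg.add_edge(
            gene_id(row.protein), "MEASURED_IN", clt_id(cell_line, timepoint),
            dataset=row.dataset, core_protein=True,
        )

    if slices is not None:
        for name, members in slices.gene_sets.items():
            kg.add_node(pathway_id(name), "Pathway", name=name)
            for sym in members:
                if gene_id(sym) in kg.g:
                    kg.add_edge(gene_id(sym), "INVOLVED_IN", pathway_id(name), resource="gene_sets")
                else:
                    dropped += 1

        if slices.diseases is not None and len(slices.diseases):
            for name in dict.fromkeys(slices.diseases["disease"]):
                kg.add_node(disease_id(name), "Disease", name=name)
            for row in slices.diseases.itertuples(index=False):
                category = getattr(row, "category", None)
                if (filters.disease_categories is not None
                        and category not in filters.disease_categories):
                    continue
                if gene_id(row.gene) in kg.g:
                    kg.add_edge(gene_id(row.gene), "ASSOCIATED_WITH", disease_id(row.disease),
                                category=category)
                else:
                    dropped += 1

        if slices.drugs is not None and len(slices.drugs):
            for name in dict.fromkeys(slices.drugs["drug"]):
                kg.add_node(drug_id(name), "Drug", name=name)
            for row in slices.drugs.itertuples(index=False):
                if gene_id(row.gene) in kg.g:
                    kg.add_edge(gene_id(row.gene), "TARGETED_BY", drug_id(row.drug))
                else:
                    dropped += 1

        if slices.ppi is not None and len(slices.ppi):
            for row in slices.ppi.itertuples(index=False):
                itype = getattr(row, "interaction_type", None)
                if (filters.interaction_types is not None
                        and itype not in filters.interaction_types):
                    continue
                if gene_id(row.source) in kg.g and gene_id(row.target) in kg.g:
                    kg.add_edge(gene_id(row.source), "INTERACTS_WITH", gene_id(row.target),
                                interaction_type=itype)
                else:
                    dropped += 1

    kg.provenance["dropped_edges"] = dropped
    kg.provenance["datasets"] = list(corpus.datasets)
    return kg


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

EXPORT_FORMATS = ("graphml", "tsv", "statements")


def export_graph(kg: KnowledgeGraph, outdir, formats: Iterable[str] = EXPORT_FORMATS) -> dict[str, str]:
    """Write the graph as GraphML, node/edge TSVs and a statement dump.

    Properties are serialized as JSON strings (GraphML attributes are scalar).
    The statement dump holds exactly one CREATE statement per node and per
    edge, so its line count equals node count + edge count and executing it
    against an empty graph store reproduces the same counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for fmt in formats:
        if fmt not in EXPORT_FORMATS:
            raise ValueError(f"unknown export format {fmt!r}; supported: {EXPORT_FORMATS}")

    if "graphml" in formats:
        flat = nx.MultiDiGraph()
        for n, d in kg.g.nodes(data=True):
            flat.add_node(n, label=d["label"], properties=json.dumps(d["properties"], sort_keys=True, default=str))
        for u, v, d in kg.g.edges(data=True):
            flat.add_edge(u, v, type=d["type"], properties=json.dumps(d["properties"], sort_keys=True, default=str))
        path = outdir / "graph.graphml"
        nx.write_graphml(flat, path)
        written["graphml"] = str(path)

    if "tsv" in formats:
        nodes = pd.DataFrame(
            [(n, d["label"], json.dumps(d["properties"], sort_keys=True, default=str))
             for n, d in kg.g.nodes(data=True)],
            columns=["id", "label", "properties"],
        )
        edges = pd.DataFrame(
            [(u, d["type"], v, json.dumps(d["properties"], sort_keys=True, default=str))
             for u, v, d in kg.g.edges(data=True)],
            columns=["source", "type", "target", "properties"],
        )
        nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        written["tsv"] = str(outdir)

    if "statements" in formats:
        lines = []
        for n, d in kg.g.nodes(data=True):
            props = {"id": n, **d["properties"]}
            lines.append(f"CREATE (:{d['label']} {json.dumps(props, sort_keys=True, default=str)});")
        for u, v, d in kg.g.edges(data=True):
            props = json.dumps(d["properties"], sort_keys=True, default=str)
            lines.append(
                f'MATCH (a {{id: {json.dumps(u)}}}), (b {{id: {json.dumps(v)}}}) '
                f"CREATE (a)-[:{d['type']} {props}]->(b);"
            )
        path = outdir / "statements.cypher"
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        written["statements"] = str(path)
    return written


def import_graphml(path) -> KnowledgeGraph:
    """Load a graph written by :func:`export_graph` back into a KnowledgeGraph."""
    flat = nx.read_graphml(path, force_multigraph=True)
    kg = KnowledgeGraph()
    for n, d in flat.nodes(data=True):
        kg.add_node(n, d["label"], **json.loads(d.get("properties", "{}")))
    for u, v, d in flat.edges(data=True):
        kg.add_edge(u, d["type"], v, **json.loads(d.get("properties", "{}")))
    return kg


def import_tsv(indir) -> KnowledgeGraph:
    indir = Path(indir)
    kg = KnowledgeGraph()
    nodes = pd.read_csv(indir / "nodes.tsv", sep="\t")
    edges = pd.read_csv(indir / "edges.tsv", sep="\t")
    for row in nodes.itertuples(index=False):
        kg.add_node(row.id, row.label, **json.loads(row.properties))
    for row in edges.itertuples(index=False):
        kg.add_edge(row.source, row.type, row.target, **json.loads(row.properties))
    return kg
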