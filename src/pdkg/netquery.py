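"""Network analyses over the knowledge graph.

Implements the in-silico network queries: genes shared between studies (with
direction concordance), gene-pathway linkage for a gene set of interest,
core-protein <-> top-DEG links through shared pathways within one study, and
keyword-driven pathway-gene-drug subnetworks.

A transcriptomic MEASURED_IN edge is one carrying ``log2fc``/``direction``
provenance; core-protein presence edges carry ``core_protein=True`` and are
excluded from DEG-level queries.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .kg import KnowledgeGraph, gene_id


@dataclass
class SharedGeneReport:
    """Genes measured in at least ``min_datasets`` distinct studies."""

    genes: pd.DataFrame  # gene, datasets, directions, n_datasets, concordant
    pairwise_overlap: dict[tuple[str, str], int]
    min_datasets: int
    datasets: tuple[str, ...]

    def symbols(self) -> tuple[str, ...]:
        return tuple(self.genes["gene"])


@dataclass
class Subnetwork:
    """A node/edge subset of a parent knowledge graph."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (source, type, target)
    meta: dict = field(default_factory=dict)

    def is_subgraph_of(self, kg: KnowledgeGraph) -> bool:
        if any(n not in kg.g for n in self.nodes):
            return False
        parent = {(u, t, v) for u, t, v, _ in kg.iter_edges()}
        return all(e in parent for e in self.edges)

    def to_graph(self) -> "nx.MultiDiGraph":
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for u, t, v in self.edges:
            g.add_edge(u, v, type=t)
        return g


def _deg_measurements(kg: KnowledgeGraph, datasets: Sequence[str] | None = None):
    """Yield (symbol, dataset, direction, clt_node) for transcriptomic edges."""
    allowed = set(datasets) if datasets is not None else None
    for u, _t, v, props in kg.iter_edges("MEASURED_IN"):
        if props.get("core_protein"):
            continue
        if allowed is not None and props.get("dataset") not in allowed:
            continue
        symbol = kg.g.nodes[u]["properties"].get("symbol", u)
        yield symbol, props["dataset"], props.get("direction"), v


# ---------------------------------------------------------------------------
# Shared genes and concordance
# ---------------------------------------------------------------------------

def shared_genes(
    kg: KnowledgeGraph,
    min_datasets: int = 2,
    datasets: Sequence[str] | None = None,
) -> SharedGeneReport:
    """Genes whose transcriptomic measurements span >= min_datasets studies.

    ``datasets`` restricts the query to a study subset (e.g. the monogenic
    studies only); pairwise overlap counts are reported over the shared set,
    counting a gene toward every dataset pair it belongs to. A gene is
    concordant when all its datasets agree on the direction of dysregulation.
    """
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    configured = tuple(datasets) if datasets is not None else tuple(kg.provenance.get("datasets", ()))
    if configured and min_datasets > len(configured):
        warnings.warn(
            f"min_datasets={min_datasets} exceeds the {len(configured)} configured datasets",
            stacklevel=2,
        )

    per_gene: dict[str, dict[str, str]] = {}
    for symbol, dataset, direction, _ in _deg_measurements(kg, datasets):
        per_gene.setdefault(symbol, {})[dataset] = direction

    rows = []
    for symbol in sorted(per_gene):
        hits = per_gene[symbol]
        if len(hits) < min_datasets:
            continue
        ds = tuple(sorted(hits))
        dirs = tuple(hits[d] for d in ds)
        rows.append((symbol, ds, dirs, len(ds), len(set(dirs)) == 1))
    genes = pd.DataFrame(rows, columns=["gene", "datasets", "directions", "n_datasets", "concordant"])

    universe = configured or tuple(sorted({d for hits in per_gene.values() for d in hits}))
    pairwise = {pair: 0 for pair in itertools.combinations(sorted(universe), 2)}
    for _, row in genes.iterrows():
        for pair in itertools.combinations(row["datasets"], 2):
            if pair in pairwise:
                pairwise[pair] += 1
    return SharedGeneReport(genes=genes, pairwise_overlap=pairwise,
                            min_datasets=min_datasets, datasets=tuple(universe))


@dataclass
class ConcordanceSummary:
    n_shared: int
    n_concordant: int
    n_discordant: int
    table: pd.DataFrame


def direction_concordance(report: SharedGeneReport) -> ConcordanceSummary:
    """Split a shared-gene report into direction-concordant vs discordant."""
    n_conc = int(report.genes["concordant"].sum())
    return ConcordanceSummary(
        n_shared=len(report.genes),
        n_concordant=n_conc,
        n_discordant=len(report.genes) - n_conc,
        table=report.genes.loc[:, ["gene", "datasets", "directions", "concordant"]].copy(),
    )


# ---------------------------------------------------------------------------
# Gene-pathway linkage
# ---------------------------------------------------------------------------

@dataclass
class PathwayLinkResult:
    subnetwork: Subnetwork
    per_gene_counts: pd.DataFrame  # gene, n_pathways
    n_genes_with_pathway: int
    n_pathways: int


def genes_to_pathways(kg: KnowledgeGraph, genes: Iterable[str]) -> PathwayLinkResult:
    """Bipartite gene-pathway subnetwork restricted to the input genes.

    Genes without any pathway involvement contribute no nodes or edges and are
    excluded from the ">= 1 pathway" count; unknown symbols are skipped with a
    warning.
    """
    wanted = []
    for sym in dict.fromkeys(genes):
        if gene_id(sym) in kg.g:
            wanted.append(sym)
        else:
            warnings.warn(f"unknown gene symbol {sym!r} skipped", stacklevel=2)

    involvement: dict[str, list[str]] = {}
    for u, _t, v, _p in kg.iter_edges("INVOLVED_IN"):
        involvement.setdefault(u, []).append(v)

    node_ids: set[str] = set()
    edges: list[tuple[str, str, str]] = []
    counts: dict[str, int] = {}
    for sym in wanted:
        gid = gene_id(sym)
        linked = involvement.get(gid, [])
        for v in linked:
            node_ids.update((gid, v))
            edges.append((gid, "INVOLVED_IN", v))
        counts[sym] = len(linked)

    pathways = {v for _, _, v in edges}
    sub = Subnetwork(nodes=tuple(sorted(node_ids)), edges=tuple(sorted(edges)),
                     meta={"query": "genes_to_pathways"})
    per_gene = pd.DataFrame(sorted(counts.items()), columns=["gene", "n_pathways"])
    return PathwayLinkResult(
        subnetwork=sub,
        per_gene_counts=per_gene,
        n_genes_with_pathway=int((per_gene["n_pathways"] > 0).sum()) if len(per_gene) else 0,
        n_pathways=len(pathways),
    )


# ---------------------------------------------------------------------------
# Core-protein <-> DEG pathway links
# ---------------------------------------------------------------------------

def core_protein_pathway_links(kg: KnowledgeGraph, dataset: str) -> Subnetwork:
    """Length-2 paths (core protein)-(pathway)-(top DEG) within one study.

    Both endpoints must carry the study's dataset tag: the source gene via a
    core-protein MEASURED_IN edge and the target gene via a transcriptomic
    MEASURED_IN edge. An empty subnetwork is a valid result.
    """
    configured = kg.provenance.get("datasets")
    if configured is not None and dataset not in configured:
        raise ValueError(f"unknown dataset {dataset!r}; configured: {configured}")

    core_nodes = {
        u for u, _t, _v, p in kg.iter_edges("MEASURED_IN")
        if p.get("core_protein") and p.get("dataset") == dataset
    }
    deg_nodes = {
        gene_id(sym) for sym, ds, _dir, _clt in _deg_measurements(kg) if ds == dataset
    }

    membership: dict[str, set[str]] = {}
    for u, _t, v, _p in kg.iter_edges("INVOLVED_IN"):
        membership.setdefault(v, set()).add(u)

    node_ids: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    paths = []
    for pathway, members in membership.items():
        for core in members & core_nodes:
            for deg in members & deg_nodes:
                if deg == core:
                    continue
                paths.append((core, pathway, deg))
                node_ids.update((core, pathway, deg))
                edges.add((core, "INVOLVED_IN", pathway))
                edges.add((deg, "INVOLVED_IN", pathway))
    return Subnetwork(
        nodes=tuple(sorted(node_ids)),
        edges=tuple(sorted(edges)),
        meta={"query": "core_protein_pathway_links", "dataset": dataset, "paths": sorted(paths)},
    )


# ---------------------------------------------------------------------------
# Keyword-driven pathway-gene-drug subnetworks
# ---------------------------------------------------------------------------

def pathway_keyword_subnetwork(
    kg: KnowledgeGraph,
    keyword: str,
    include_drugs: bool = True,
) -> Subnetwork:
    """Subnetwork of pathways matching a name keyword and their measured genes.

    Pathway names are matched by case-insensitive substring. Member genes are
    restricted to genes with at least one transcriptomic measurement; their
    MEASURED_IN edges (with the cell-line-time-point nodes) are included, and,
    when ``include_drugs`` is set, so are the TARGETED_BY edges of those genes
    with the corresponding Drug nodes. ``meta['genes_per_dataset']`` reports
    how many matched genes each study contributes.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    needle = keyword.lower()

    matched_pathways = {
        n for n in kg.nodes_with_label("Pathway")
        if needle in str(kg.g.nodes[n]["properties"].get("name", n)).lower()
    }

    measured: dict[str, set[str]] = {}
    measured_edges: dict[str, list[tuple[str, str, str]]] = {}
    for sym, dataset, _direction, clt in _deg_measurements(kg):
        gid = gene_id(sym)
        measured.setdefault(gid, set()).add(dataset)
        measured_edges.setdefault(gid, []).append((gid, "MEASURED_IN", clt))

    node_ids: set[str] = set(matched_pathways)
    edges: set[tuple[str, str, str]] = set()
    member_genes: set[str] = set()
    for u, _t, v, _p in kg.iter_edges("INVOLVED_IN"):
        if v in matched_pathways and u in measured:
            member_genes.add(u)
            edges.add((u, "INVOLVED_IN", v))
    node_ids.update(member_genes)

    for gid in member_genes:
        for edge in measured_edges[gid]:
            edges.add(edge)
            node_ids.add(edge[2])

    n_drugs = 0
    if include_drugs:
        for u, _t, v, _p in kg.iter_edges("TARGETED_BY"):
            if u in member_genes:
                edges.add((u, "TARGETED_BY", v))
                node_ids.add(v)
        n_drugs = len({v for _u, t, v in edges if t == "TARGETED_BY"})

    genes_per_dataset: dict[str, int] = {}
    for gid in member_genes:
        for dataset in measured[gid]:
            genes_per_dataset[dataset] = genes_per_dataset.get(dataset, 0) + 1

    if not matched_pathways:
        node_ids, edges = set(), set()

    return Subnetwork(
        nodes=tuple(sorted(node_ids)),
        edges=tuple(sorted(edges)),
        meta={
            "query": "pathway_keyword_subnetwork",
            "keyword": keyword,
            "n_pathways": len(matched_pathways),
            "n_genes": len(member_genes),
            "n_drugs": n_drugs,
            "genes_per_dataset": genes_per_dataset,
        },
    )
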