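"""Independent oracles used by the test suite.

Everything here is deliberately naive -- exact rational arithmetic, literal
enumeration, or plain dictionary scans over raw tables -- and shares no code
with the library paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def hypergeom_tail_exact(k: int, N: int, m: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, m, n) by exact combinatorial summation."""
    if k <= 0:
        return Fraction(1)
    acc = sum(comb(m, j) * comb(N - m, n - j) for j in range(k, min(m, n) + 1))
    return Fraction(acc, comb(N, n))


def hypergeom_tail_enumerate(k: int, universe, members, n: int) -> Fraction:
    """Literal enumeration of all C(N, n) draws from the universe."""
    members = set(members)
    hits = total = 0
    for draw in itertools.combinations(sorted(universe), n):
        total += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def bh_stepup(p_values):
    """Textbook Benjamini-Hochberg step-up, returned in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# Graph-query oracles (brute force from raw tables / raw edge scans)
# ---------------------------------------------------------------------------

def shared_genes_from_tables(tables, min_datasets, datasets=None):
    """Shared-gene set straight from the per-study DEG tables."""
    hits = {}
    for dataset, table in tables.items():
        if datasets is not None and dataset not in datasets:
            continue
        for gene in table["gene"]:
            hits.setdefault(gene, set()).add(dataset)
    return {g for g, ds in hits.items() if len(ds) >= min_datasets}


def concordant_from_tables(tables, min_datasets, datasets=None):
    """Direction-concordant shared genes straight from the tables."""
    directions = {}
    for dataset, table in tables.items():
        if datasets is not None and dataset not in datasets:
            continue
        for gene, fc in zip(table["gene"], table["log2fc"]):
            directions.setdefault(gene, {})[dataset] = "UP" if fc > 0 else "DOWN"
    return {
        g for g, per in directions.items()
        if len(per) >= min_datasets and len(set(per.values())) == 1
    }


def pathway_counts_from_slices(slices, genes):
    """Per-gene pathway-membership counts straight from the gene sets."""
    return {
        g: sum(1 for members in slices.gene_sets.values() if g in members)
        for g in genes
    }


def core_links_from_raw(tables, core_proteins, slices, dataset):
    """(core protein, pathway, DEG) triples by scanning the raw inputs."""
    degs = set(tables[dataset]["gene"])
    cores = set(core_proteins.get(dataset, ()))
    triples = set()
    for pathway, members in slices.gene_sets.items():
        members = set(members)
        for core in members & cores:
            for deg in members & degs:
                if deg != core:
                    triples.add((core, pathway, deg))
    return triples


def keyword_genes_from_raw(tables, slices, keyword):
    """Measured member genes of keyword-matching pathways, from raw inputs."""
    measured = {g for t in tables.values() for g in t["gene"]}
    needle = keyword.lower()
    genes = set()
    for name, members in slices.gene_sets.items():
        if needle in name.lower():
            genes |= set(members) & measured
    return genes
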