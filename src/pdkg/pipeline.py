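"""End-to-end pipeline orchestration.

Runs simulate -> corpus -> kg -> query -> enrich -> stratify from a single
config mapping, writing each stage's outputs under one directory together
with a JSON manifest (seed, per-stage timings, sha256 checksums of every
artifact). Stages read their inputs from the previous stage's on-disk
outputs, so deleting downstream outputs and rerunning from any stage
reproduces them.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import corpus as corpus_mod
from . import enrich as enrich_mod
from . import kg as kg_mod
from . import netquery, strat, synthetic

STAGES = ("simulate", "corpus", "kg", "query", "enrich", "stratify")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "pdkg_run",
    "simulate": {"universe_size": 1000, "group_sizes": [3, 2, 4], "n_layer_features": 10},
    "corpus": {"top_n": 100},
    "query": {"min_datasets": 2, "keyword": "ROBO",
              "shared_datasets": list(synthetic.MONOGENIC_DATASETS)},
    "enrich": {"min_overlap": 1},
    "stratify": {"K": 3, "mu": 0.5, "t": 20, "clusters": 3},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _merge_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: dict, out: Path) -> None:
    seed = int(cfg["seed"])
    sim = cfg["simulate"]
    scenario = synthetic.pd_study_scenario(seed=seed, universe_size=sim["universe_size"])
    inputs = out / "inputs"
    synthetic.write_deg_tables(scenario.deg_tables, inputs / "deg")
    rows = [(p, d) for d, prots in scenario.core_proteins.items() for p in prots]
    pd.DataFrame(rows, columns=["protein", "dataset"]).to_csv(
        inputs / "core_proteins.tsv", sep="\t", index=False
    )
    scenario.imaging.to_csv(inputs / "imaging.tsv", sep="\t", index=False)
    slices = synthetic.generate_resource_slices(
        synthetic.pd_resource_spec(seed=seed, universe_size=sim["universe_size"])
    )
    synthetic.write_resource_slices(slices, inputs / "resources")
    layers, labels = synthetic.generate_cohort_layers(
        group_sizes=tuple(sim["group_sizes"]), n_features=sim["n_layer_features"], seed=seed
    )
    for i, layer in enumerate(layers, start=1):
        layer.to_csv(inputs / f"layer{i}.tsv", sep="\t", index_label="sample")
    pd.DataFrame({"sample": layers[0].index, "group": labels}).to_csv(
        inputs / "planted_groups.tsv", sep="\t", index=False
    )


def _stage_corpus(cfg: dict, out: Path) -> None:
    inputs = out / "inputs"
    top_n = int(cfg["corpus"]["top_n"])
    tables = {}
    for path in sorted((inputs / "deg").glob("*_degs.tsv")):
        dataset = path.name[: -len("_degs.tsv")]
        tables[dataset] = corpus_mod.select_top_degs(corpus_mod.read_deg_table(path, sep="\t"), top_n)
    core = pd.read_csv(inputs / "core_proteins.tsv", sep="\t")
    core_lists = {d: tuple(g["protein"]) for d, g in core.groupby("dataset")}
    imaging = corpus_mod.normalize_imaging(pd.read_csv(inputs / "imaging.tsv", sep="\t"))
    ordered = [d for d in synthetic.ALL_DATASETS if d in tables]
    ordered += [d for d in tables if d not in ordered]
    corpus = corpus_mod.aggregate_corpus(
        {d: tables[d] for d in ordered},
        core_protein_lists={d: core_lists.get(d, ()) for d in ordered},
        imaging=imaging,
        dataset_context={d: synthetic.DATASET_CONTEXT[d] for d in ordered
                         if d in synthetic.DATASET_CONTEXT},
    )
    corpus_mod.write_corpus(corpus, out / "corpus")


def _stage_kg(cfg: dict, out: Path) -> None:
    corpus = corpus_mod.read_corpus(out / "corpus")
    slices = synthetic.read_resource_slices(out / "inputs" / "resources")
    graph = kg_mod.build_graph(corpus, slices)
    kgdir = out / "kg"
    kg_mod.export_graph(graph, kgdir)
    (kgdir / "report.json").write_text(json.dumps(graph.report(), indent=2, sort_keys=True))


def _stage_query(cfg: dict, out: Path) -> None:
    graph = kg_mod.import_tsv(out / "kg")
    graph.provenance["datasets"] = json.loads((out / "corpus" / "manifest.json").read_text())["datasets"]
    qcfg = cfg["query"]
    qdir = out / "query"
    qdir.mkdir(parents=True, exist_ok=True)

    report = netquery.shared_genes(
        graph, min_datasets=int(qcfg["min_datasets"]), datasets=qcfg.get("shared_datasets")
    )
    shared = report.genes.copy()
    shared["datasets"] = shared["datasets"].map(",".join)
    shared["directions"] = shared["directions"].map(",".join)
    shared.to_csv(qdir / "shared_genes.tsv", sep="\t", index=False)
    summary = netquery.direction_concordance(report)
    (qdir / "shared_summary.json").write_text(json.dumps({
        "n_shared": summary.n_shared,
        "n_concordant": summary.n_concordant,
        "n_discordant": summary.n_discordant,
        "pairwise_overlap": {f"{a}&{b}": v for (a, b), v in report.pairwise_overlap.items()},
    }, indent=2, sort_keys=True))

    sub = netquery.pathway_keyword_subnetwork(graph, qcfg["keyword"], include_drugs=True)
    pd.DataFrame(sub.edges, columns=["source", "type", "target"]).to_csv(
        qdir / "keyword_subnetwork_edges.tsv", sep="\t", index=False
    )
    (qdir / "keyword_subnetwork.json").write_text(json.dumps(sub.meta, indent=2, sort_keys=True))

    core_links = {}
    for dataset in graph.provenance["datasets"]:
        link = netquery.core_protein_pathway_links(graph, dataset)
        core_links[dataset] = {"n_paths": len(link.meta["paths"]), "paths": link.meta["paths"]}
    (qdir / "core_protein_links.json").write_text(json.dumps(core_links, indent=2, sort_keys=True))


def _stage_enrich(cfg: dict, out: Path) -> None:
    corpus = corpus_mod.read_corpus(out / "corpus")
    gene_sets = synthetic.read_gmt(out / "inputs" / "resources" / "gene_sets.gmt")
    universe = set(corpus.unique_genes()) | {g for m in gene_sets.values() for g in m}
    result = enrich_mod.ora(
        corpus.unique_genes(), gene_sets, universe=universe,
        min_overlap=int(cfg["enrich"]["min_overlap"]),
    )
    result = result.assign(overlap_genes=result["overlap_genes"].map(",".join))
    edir = out / "enrich"
    edir.mkdir(parents=True, exist_ok=True)
    result.to_csv(edir / "enrichment.tsv", sep="\t", index=False)


def _stage_stratify(cfg: dict, out: Path) -> None:
    inputs = out / "inputs"
    scfg = cfg["stratify"]
    layers = [
        pd.read_csv(path, sep="\t", index_col="sample")
        for path in sorted(inputs.glob("layer*.tsv"))
    ]
    fused = strat.snf(
        layers, K=int(scfg["K"]), mu=float(scfg["mu"]), t=int(scfg["t"]),
        n_clusters=int(scfg["clusters"]), seed=int(cfg["seed"]),
    )
    sdir = out / "stratify"
    sdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fused.W_fused, index=fused.samples, columns=fused.samples).to_csv(
        sdir / "fused_similarity.tsv", sep="\t"
    )
    pd.DataFrame({"sample": fused.samples, "cluster": fused.labels}).to_csv(
        sdir / "clusters.tsv", sep="\t", index=False
    )
    corpus = corpus_mod.read_corpus(out / "corpus")
    matrix = strat.log2fc_matrix(corpus.degs)
    pca = strat.pca_embed(matrix)
    coords = pca.coordinates.copy()
    coords.to_csv(sdir / "pca_coordinates.tsv", sep="\t", index_label="dataset")
    pd.DataFrame({"component": coords.columns,
                  "explained_variance_ratio": pca.explained_variance_ratio}).to_csv(
        sdir / "pca_variance.tsv", sep="\t", index=False
    )
    tree = strat.hclust(matrix)
    (sdir / "dendrogram.newick").write_text(tree.newick() + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "corpus": _stage_corpus,
    "kg": _stage_kg,
    "query": _stage_query,
    "enrich": _stage_enrich,
    "stratify": _stage_stratify,
}


def run_pipeline(config: dict | None = None, stages=STAGES) -> dict:
    """Run the requested stages and return the output manifest."""
    cfg = _merge_config(config)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    timings = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        start = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
        timings[stage] = round(time.perf_counter() - start, 3)

    manifest = {
        "seed": int(cfg["seed"]),
        "stages_run": list(stages),
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "checksums": _checksums(out),
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
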