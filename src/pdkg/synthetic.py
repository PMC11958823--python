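"""Synthetic study generators with planted, known structure.

Every downstream stage of the pipeline (corpus harmonisation, knowledge-graph
construction, network queries, over-representation analysis, stratification)
can be exercised against inputs produced here, where the ground truth -- which
gene sits in which study's top-DEG list and with which direction, which
pathway/drug/disease annotates which gene, which cell lines belong to which
group -- is planted by construction rather than estimated.

The module also ships :func:`pd_study_scenario`, a fully synthetic corpus whose
*overlap structure* mirrors the organoid study design this package targets:
four monogenic Parkinson's studies (LRRK2-G2019S, SNCA triplication,
GBA-N370S, MIRO1-R272Q) plus one idiopathic (IPD) study, each contributing a
top-100 DEG list, with 25 genes planted into at least two monogenic lists
(15 of them into LRRK2 and MIRO1, 12 direction-concordant), 35 genes shared
between one monogenic list and the IPD list (so the five lists merge to 440
unique genes), and 12 core imaging proteins across the monogenic studies
extended to 13 by the IPD study. Gene symbols are synthetic ("G000001", ...);
core-protein names reuse standard organoid immunostaining markers (TH, GFAP,
TUBB3, ...) because those are marker vocabulary, not data.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UP = "UP"
DOWN = "DOWN"

MONOGENIC_DATASETS = ("LRRK2", "SNCA", "GBA", "MIRO1")
IPD_DATASET = "IPD"
ALL_DATASETS = MONOGENIC_DATASETS + (IPD_DATASET,)

#: cell line / organoid-culture day context of each synthetic study
DATASET_CONTEXT = {
    "LRRK2": ("LRRK2_1", 35),
    "SNCA": ("SNCA_1", 30),
    "GBA": ("GBA_3", 30),
    "MIRO1": ("MIRO1_1", 30),
    "IPD": ("IPD_1", 50),
}

#: core imaging proteins per synthetic study: 12 unique across the four
#: monogenic studies, 13 once the IPD panel (8 markers) is merged in.
CORE_PROTEINS = {
    "LRRK2": ("TH", "TUBB3", "MAP2", "FOXA2", "NES"),
    "SNCA": ("TH", "TUBB3", "GFAP", "S100B", "ASYN"),
    "GBA": ("TH", "TUBB3", "GFAP", "S100B", "SOX2", "NURR1"),
    "MIRO1": ("TH", "TUBB3", "GFAP", "S100B", "MAP2", "PAX6", "CASP3"),
    "IPD": ("TUBB3", "S100B", "GFAP", "TH", "MAP2", "PAX6", "KI67", "SOX2"),
}


def gene_universe(n: int) -> tuple[str, ...]:
    """Synthetic uppercase gene symbols G000001..G<n>."""
    return tuple(f"G{i:06d}" for i in range(1, n + 1))


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapSpec:
    """Planted cross-study overlap structure for top-DEG lists.

    ``shared_assignments`` maps a gene symbol to ``{dataset: "UP"|"DOWN"}``:
    the gene appears in exactly those datasets' tables with exactly those
    log2FC signs. All remaining ("fill") slots are drawn from the universe so
    that every fill gene appears in exactly one dataset.
    """

    datasets: tuple[str, ...]
    universe_size: int
    top_n: int
    shared_assignments: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    seed: int = 0

    def planted_per_dataset(self) -> dict[str, int]:
        counts = {d: 0 for d in self.datasets}
        for assign in self.shared_assignments.values():
            for d in assign:
                counts[d] += 1
        return counts

    def validate(self) -> None:
        if not self.datasets or len(set(self.datasets)) != len(self.datasets):
            raise ValueError("datasets must be a non-empty set of unique identifiers")
        if self.top_n < 1 or self.top_n > self.universe_size:
            raise ValueError("require 1 <= top_n <= universe_size")
        for gene, assign in self.shared_assignments.items():
            if not assign:
                raise ValueError(f"empty dataset assignment for planted gene {gene!r}")
            for d, sign in assign.items():
                if d not in self.datasets:
                    raise ValueError(f"planted gene {gene!r} assigned to unknown dataset {d!r}")
                if sign not in (UP, DOWN):
                    raise ValueError(f"direction for {gene!r} in {d!r} must be UP or DOWN, got {sign!r}")
        for d, cnt in self.planted_per_dataset().items():
            if cnt > self.top_n:
                raise ValueError(
                    f"infeasible spec: {cnt} planted genes for dataset {d!r} "
                    f"exceed the {self.top_n} available top slots"
                )
        planted = set(self.shared_assignments)
        pool = sum(1 for g in gene_universe(self.universe_size) if g not in planted)
        fill_needed = sum(self.top_n - c for c in self.planted_per_dataset().values())
        if fill_needed > pool:
            raise ValueError(
                f"infeasible spec: {fill_needed} fill slots but only {pool} unplanted universe genes"
            )


def generate_deg_tables(spec: OverlapSpec) -> dict[str, pd.DataFrame]:
    """Generate per-dataset top-DEG tables honouring a planted overlap spec.

    Returns one DataFrame per dataset with columns ``gene``, ``log2fc``,
    ``p_adjust``; rows sorted by strictly increasing adjusted p-value.
    Regeneration with the same spec (same seed) is bit-identical; changing the
    seed changes only fill genes and numeric noise, never planted membership
    or planted signs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    planted: dict[str, list[tuple[str, str]]] = {d: [] for d in spec.datasets}
    for gene in sorted(spec.shared_assignments):
        for d in spec.datasets:
            if d in spec.shared_assignments[gene]:
                planted[d].append((gene, spec.shared_assignments[gene][d]))

    pool = [g for g in gene_universe(spec.universe_size) if g not in spec.shared_assignments]
    pool = [pool[i] for i in rng.permutation(len(pool))]

    tables: dict[str, pd.DataFrame] = {}
    cursor = 0
    for d in spec.datasets:
        rows = list(planted[d])
        n_fill = spec.top_n - len(rows)
        for g in pool[cursor:cursor + n_fill]:
            rows.append((g, UP if rng.random() < 0.5 else DOWN))
        cursor += n_fill

        order = rng.permutation(len(rows))
        p = np.sort(rng.uniform(1e-12, 0.05, size=spec.top_n))
        while np.any(np.diff(p) <= 0):  # strict increase; collisions are measure-zero
            p = np.sort(rng.uniform(1e-12, 0.05, size=spec.top_n))
        mags = rng.uniform(0.5, 3.0, size=spec.top_n)

        genes = [rows[i][0] for i in order]
        signs = np.array([1.0 if rows[i][1] == UP else -1.0 for i in order])
        tables[d] = pd.DataFrame(
            {"gene": genes, "log2fc": signs * mags, "p_adjust": p}
        )
    return tables


# ---------------------------------------------------------------------------
# Resource slices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResourceSliceSpec:
    """Planted annotation-resource slices over a gene universe.

    ``membership`` pins the member genes of named entities (pathways, drugs or
    diseases); every other generated entity receives random members. Pathway
    names listed in ``keyword_pathways`` are included verbatim so keyword
    queries have a planted target.
    """

    universe: tuple[str, ...]
    n_pathways: int = 0
    n_drugs: int = 0
    n_diseases: int = 0
    n_ppi: int = 0
    membership: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    keyword_pathways: tuple[str, ...] = ()
    seed: int = 0
    set_size: tuple[int, int] = (2, 6)

    def pathway_names(self) -> tuple[str, ...]:
        total = max(self.n_pathways, len(self.keyword_pathways))
        extra = total - len(self.keyword_pathways)
        return self.keyword_pathways + tuple(f"PATHWAY_{i:03d}" for i in range(1, extra + 1))

    def drug_names(self) -> tuple[str, ...]:
        return tuple(f"DRUG_{i:03d}" for i in range(1, self.n_drugs + 1))

    def disease_names(self) -> tuple[str, ...]:
        return tuple(f"DISEASE_{i:03d}" for i in range(1, self.n_diseases + 1))

    def validate(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        names = self.pathway_names() + self.drug_names() + self.disease_names()
        if len(set(names)) != len(names):
            raise ValueError("entity names must be unique across pathways/drugs/diseases")
        universe = set(self.universe)
        known = set(names)
        for entity, members in self.membership.items():
            if entity not in known:
                raise ValueError(f"membership for unknown entity {entity!r}")
            bad = sorted(set(members) - universe)
            if bad:
                raise ValueError(f"membership of {entity!r} references unknown genes: {bad}")


INTERACTION_TYPES = ("association", "physical association", "colocalization", "proximity")
DISEASE_CATEGORIES = ("central nervous system", "other")


@dataclass
class ResourceSlices:
    """In-memory annotation slices consumed by the knowledge-graph builder."""

    gene_sets: dict[str, tuple[str, ...]]
    ppi: pd.DataFrame        # source, target, interaction_type
    diseases: pd.DataFrame   # gene, disease, category
    drugs: pd.DataFrame      # gene, drug
    mapping: pd.DataFrame    # symbol, accession


def generate_resource_slices(spec: ResourceSliceSpec) -> ResourceSlices:
    """Generate GMT-serializable gene sets, edge lists and an ID mapping."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    universe = list(spec.universe)
    lo, hi = spec.set_size

    def members_of(entity: str) -> tuple[str, ...]:
        if entity in spec.membership:
            return tuple(spec.membership[entity])
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        return tuple(sorted(universe[i] for i in idx))

    gene_sets = {name: members_of(name) for name in spec.pathway_names()}

    disease_rows = [
        (g, dis, DISEASE_CATEGORIES[int(rng.random() < 0.3)])
        for dis in spec.disease_names()
        for g in members_of(dis)
    ]
    drug_rows = [(g, drug) for drug in spec.drug_names() for g in members_of(drug)]

    ppi_rows = []
    for _ in range(spec.n_ppi):
        i, j = rng.choice(len(universe), size=2, replace=False)
        ppi_rows.append((universe[i], universe[j], INTERACTION_TYPES[int(rng.integers(4))]))

    mapping = pd.DataFrame(
        {"symbol": universe, "accession": [f"P{i:05d}" for i in range(1, len(universe) + 1)]}
    )
    return ResourceSlices(
        gene_sets=gene_sets,
        ppi=pd.DataFrame(ppi_rows, columns=["source", "target", "interaction_type"]),
        diseases=pd.DataFrame(disease_rows, columns=["gene", "disease", "category"]),
        drugs=pd.DataFrame(drug_rows, columns=["gene", "drug"]),
        mapping=mapping,
    )


# ---------------------------------------------------------------------------
# Imaging features and stratification cohorts
# ---------------------------------------------------------------------------

def generate_imaging_features(
    n_lines: int,
    n_features: int,
    group_effect: float,
    seed: int = 0,
    n_control: int | None = None,
    noise_sd: float = 0.1,
    timepoint: int = 30,
) -> pd.DataFrame:
    """Long-format imaging feature table for a two-group cell-line cohort.

    Cell lines split into a control group (condition ``CTRL``) and an affected
    group (``PD``) whose feature values are scaled by ``group_effect``.
    ``noise_sd`` is the standard deviation of multiplicative log-normal noise;
    0 disables noise so affected values are exactly ``group_effect`` times the
    control values of the same feature.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 cell lines")
    if group_effect <= 0:
        raise ValueError("group_effect must be positive")
    if n_control is None:
        n_control = max(1, round(n_lines / 3))
    if not 1 <= n_control < n_lines:
        raise ValueError("n_control must leave at least one affected line")

    rng = np.random.default_rng(seed)
    base = rng.uniform(10.0, 100.0, size=n_features)
    features = [f"FEAT{i:02d}" for i in range(1, n_features + 1)]
    lines = [(f"CTRL_{i}", "CTRL") for i in range(1, n_control + 1)] + [
        (f"PD_{i}", "PD") for i in range(1, n_lines - n_control + 1)
    ]

    rows = []
    for line, condition in lines:
        scale = group_effect if condition == "PD" else 1.0
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_features)) if noise_sd > 0 else np.ones(n_features)
        values = base * scale * noise
        rows.extend(
            (line, condition, timepoint, feat, val)
            for feat, val in zip(features, values)
        )
    return pd.DataFrame(rows, columns=["cell_line", "condition", "timepoint", "feature", "value_raw"])


def imaging_layer_matrix(table: pd.DataFrame, value_col: str = "value_raw") -> pd.DataFrame:
    """Pivot a long imaging table into a cell-line x feature matrix."""
    return table.pivot_table(index="cell_line", columns="feature", values=value_col).sort_index()


def generate_cohort_layers(
    group_sizes: Sequence[int] = (3, 6),
    n_features: int = 10,
    n_layers: int = 2,
    effect: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Multi-layer feature matrices with planted group structure.

    Each layer draws a per-group centre from N(0, effect^2) per feature and
    adds N(0, noise_sd^2) sample noise; all layers share the same sample order
    and the same planted labels. Defaults emulate the stratification
    cohort this pipeline targets: 9 cell lines, two data layers (imaging and transcriptomics), and a
    group effect strong enough that the planted structure dominates the noise.
    Returns (layers, labels).
    """
    if any(s < 1 for s in group_sizes) or len(group_sizes) < 2:
        raise ValueError("need >= 2 groups with >= 1 sample each")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(group_sizes)), group_sizes)
    n = len(labels)
    samples = [f"LINE{i:02d}" for i in range(1, n + 1)]
    layers = []
    for li in range(n_layers):
        centers = rng.normal(0.0, effect, size=(len(group_sizes), n_features))
        X = centers[labels] + rng.normal(0.0, noise_sd, size=(n, n_features))
        layers.append(
            pd.DataFrame(X, index=samples, columns=[f"L{li + 1}F{j:02d}" for j in range(1, n_features + 1)])
        )
    return layers, labels


# ---------------------------------------------------------------------------
# The default study scenario
# ---------------------------------------------------------------------------

def pd_overlap_spec(seed: int = 0, universe_size: int = 1000) -> OverlapSpec:
    """Overlap spec planting the five-study structure described above.

    Genes G000001..G000025 are the monogenic shared genes: each appears in
    exactly two of the four monogenic lists (15 in LRRK2+MIRO1, the rest
    spread over the remaining pairs), the first 12 with concordant signs and
    the other 13 with discordant signs. Genes G000026..G000060 each appear in
    one monogenic list and the IPD list, so merging all five top-100 lists
    yields 25 + 35 + 380 fill = 440 unique genes.
    """
    pair_plan = (
        [("LRRK2", "MIRO1")] * 15
        + [("SNCA", "GBA")] * 3
        + [("LRRK2", "SNCA")] * 2
        + [("LRRK2", "GBA")] * 2
        + [("MIRO1", "SNCA")] * 2
        + [("MIRO1", "GBA")] * 1
    )
    assignments: dict[str, dict[str, str]] = {}
    for i, (a, b) in enumerate(pair_plan, start=1):
        gene = f"G{i:06d}"
        if i <= 12:  # concordant
            sign = UP if i % 2 else DOWN
            assignments[gene] = {a: sign, b: sign}
        else:  # discordant
            assignments[gene] = {a: UP, b: DOWN}
    for j in range(35):
        gene = f"G{j + 26:06d}"
        mono = MONOGENIC_DATASETS[j % 4]
        assignments[gene] = {mono: UP, IPD_DATASET: UP}
    return OverlapSpec(
        datasets=ALL_DATASETS,
        universe_size=universe_size,
        top_n=100,
        shared_assignments=assignments,
        seed=seed,
    )


@dataclass
class StudyScenario:
    """A complete synthetic five-study input bundle."""

    spec: OverlapSpec
    deg_tables: dict[str, pd.DataFrame]
    core_proteins: dict[str, tuple[str, ...]]
    imaging: pd.DataFrame
    dataset_context: dict[str, tuple[str, int]]


def pd_study_scenario(seed: int = 0, universe_size: int = 1000) -> StudyScenario:
    """Generate the default synthetic five-study scenario (see module docs)."""
    spec = pd_overlap_spec(seed=seed, universe_size=universe_size)
    tables = generate_deg_tables(spec)
    imaging = generate_imaging_features(
        n_lines=9, n_features=9, group_effect=0.7, seed=spec.seed + 1, n_control=3, timepoint=50
    )
    return StudyScenario(
        spec=spec,
        deg_tables=tables,
        core_proteins={d: CORE_PROTEINS[d] for d in spec.datasets},
        imaging=imaging,
        dataset_context=dict(DATASET_CONTEXT),
    )


def pd_resource_spec(seed: int = 0, universe_size: int = 1000) -> ResourceSliceSpec:
    """Resource slices matching :func:`pd_study_scenario`.

    Two ROBO-named pathways are planted over shared genes so keyword-driven
    subnetwork queries have a known target, alongside random pathways, drug
    targets, CNS disease associations and protein-protein interactions.
    """
    return ResourceSliceSpec(
        universe=gene_universe(universe_size),
        n_pathways=30,
        n_drugs=12,
        n_diseases=6,
        n_ppi=40,
        keyword_pathways=("ROBO RECEPTOR SIGNALLING", "REGULATION OF EXPRESSION BY ROBO"),
        membership={
            "ROBO RECEPTOR SIGNALLING": ("G000001", "G000002", "G000016"),
            "REGULATION OF EXPRESSION BY ROBO": ("G000016", "G000026", "G000061"),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_deg_tables(tables: Mapping[str, pd.DataFrame], outdir) -> list[str]:
    """Write one ``<dataset>_degs.tsv`` per dataset; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for dataset, table in tables.items():
        path = outdir / f"{dataset}_degs.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths.append(str(path))
    return paths


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path) -> None:
    """Write gene sets in GMT (name, description, members; tab-separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "synthetic", *genes]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, ...]]:
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                sets[parts[0]] = tuple(parts[2:])
    return sets


def write_resource_slices(slices: ResourceSlices, outdir) -> dict[str, str]:
    """Write slices as a directory of plain-text files; returns name->path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "ppi": str(outdir / "ppi.tsv"),
        "diseases": str(outdir / "disease_gene.tsv"),
        "drugs": str(outdir / "drug_gene.tsv"),
        "mapping": str(outdir / "id_mapping.tsv"),
    }
    write_gmt(slices.gene_sets, paths["gene_sets"])
    slices.ppi.to_csv(paths["ppi"], sep="\t", index=False)
    slices.diseases.to_csv(paths["diseases"], sep="\t", index=False)
    slices.drugs.to_csv(paths["drugs"], sep="\t", index=False)
    slices.mapping.to_csv(paths["mapping"], sep="\t", index=False)
    return paths


def read_resource_slices(indir) -> ResourceSlices:
    from pathlib import Path

    indir = Path(indir)
    return ResourceSlices(
        gene_sets=read_gmt(indir / "gene_sets.gmt"),
        ppi=pd.read_csv(indir / "ppi.tsv", sep="\t"),
        diseases=pd.read_csv(indir / "disease_gene.tsv", sep="\t"),
        drugs=pd.read_csv(indir / "drug_gene.tsv", sep="\t"),
        mapping=pd.read_csv(indir / "id_mapping.tsv", sep="\t"),
    )
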