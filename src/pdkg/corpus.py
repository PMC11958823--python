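"""Harmonisation of per-study inputs into the core data corpus.

The corpus is the substrate of every downstream analysis: per-study top-N
differential-expression lists (gene symbol, log2 fold change PD vs control,
adjusted p-value), the per-study core imaging proteins, and the harmonised,
mean-normalised imaging feature table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections.abc import Collection, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEG_COLUMNS = ("gene", "log2fc", "p_adjust")
IMAGING_COLUMNS = ("cell_line", "condition", "timepoint", "feature", "value_raw")
EXCLUDED_BIOTYPES = frozenset({"lncRNA", "pseudogene"})


class SchemaError(ValueError):
    """A table does not carry the required columns or types."""


def direction_of(log2fc: float) -> str:
    return "UP" if log2fc > 0 else "DOWN"


def _clean_symbols(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.upper()


def read_deg_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited DEG table (tab or comma; sniffed when sep is None)."""
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


# ---------------------------------------------------------------------------
# Top-DEG selection
# ---------------------------------------------------------------------------

def select_top_degs(
    table: pd.DataFrame,
    n: int,
    exclude: Collection[str] | Mapping[str, str] = (),
) -> pd.DataFrame:
    """Select the ``n`` most significant eligible genes of one study.

    Rows flagged as long-non-coding RNA or pseudogene are removed before
    ranking: ``exclude`` is either a collection of gene symbols to drop, or a
    gene->biotype mapping of which the lncRNA/pseudogene entries are dropped.
    Ranking is by adjusted p-value ascending; ties break by |log2fc|
    descending, then gene symbol, so truncation at ``n`` is deterministic.
    """
    if table.empty:
        raise ValueError("empty DEG table")
    if n < 1:
        raise ValueError("n must be >= 1")
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"DEG table missing required columns: {missing}")

    out = table.loc[:, list(DEG_COLUMNS)].copy()
    out["gene"] = _clean_symbols(out["gene"])
    for col in ("log2fc", "p_adjust"):
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as err:
            raise SchemaError(f"non-numeric values in column {col!r}: {err}") from err

    if isinstance(exclude, Mapping):
        flagged = {str(g).strip().upper() for g, b in exclude.items() if b in EXCLUDED_BIOTYPES}
    else:
        flagged = {str(g).strip().upper() for g in exclude}
    if flagged:
        out = out[~out["gene"].isin(flagged)]

    out["_absfc"] = out["log2fc"].abs()
    out = out.sort_values(
        ["p_adjust", "_absfc", "gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absfc")
    out = out.head(min(n, len(out))).reset_index(drop=True)
    out["direction"] = np.where(out["log2fc"] > 0, "UP", "DOWN")
    return out


# ---------------------------------------------------------------------------
# Corpus aggregation
# ---------------------------------------------------------------------------

@dataclass
class Corpus:
    """The merged multi-study data corpus.

    ``degs`` holds one row per (gene, dataset) with log2fc, p_adjust and
    direction; ``core_proteins`` one row per (protein, dataset);
    ``n_records`` counts the concatenated DEG rows before deduplication.
    """

    degs: pd.DataFrame
    core_proteins: pd.DataFrame
    datasets: tuple[str, ...]
    dataset_context: dict[str, tuple[str, int]] = field(default_factory=dict)
    imaging: pd.DataFrame | None = None
    n_records: int = 0

    @property
    def n_unique_genes(self) -> int:
        return self.degs["gene"].nunique()

    @property
    def n_unique_core_proteins(self) -> int:
        return self.core_proteins["protein"].nunique() if len(self.core_proteins) else 0

    def unique_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.degs["gene"].unique()))

    def gene_directions(self) -> pd.DataFrame:
        """Per gene: the datasets carrying it and the direction in each."""
        rows = [
            (gene, tuple(grp["dataset"]), tuple(grp["direction"]))
            for gene, grp in self.degs.sort_values(["gene", "dataset"]).groupby("gene", sort=True)
        ]
        return pd.DataFrame(rows, columns=["gene", "datasets", "directions"])


def aggregate_corpus(
    per_study_lists: Mapping[str, pd.DataFrame],
    core_protein_lists: Mapping[str, Sequence[str]] | None = None,
    imaging: pd.DataFrame | None = None,
    dataset_context: Mapping[str, tuple[str, int]] | None = None,
) -> Corpus:
    """Merge per-study DEG lists and core-protein sets into a Corpus.

    Duplicate (gene, dataset) rows are collapsed to the smallest adjusted
    p-value with a warning. The corpus reports both the concatenated record
    count and the deduplicated unique-gene count.
    """
    datasets = tuple(per_study_lists)
    if len(set(datasets)) != len(datasets):
        raise ValueError("study identifiers must be unique")

    frames = []
    for dataset, table in per_study_lists.items():
        missing = [c for c in DEG_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"{dataset}: DEG table missing columns {missing}")
        frame = table.loc[:, list(DEG_COLUMNS)].copy()
        frame["gene"] = _clean_symbols(frame["gene"])
        frame["dataset"] = dataset
        frames.append(frame)
    if frames:
        degs = pd.concat(frames, ignore_index=True)
    else:
        degs = pd.DataFrame(columns=[*DEG_COLUMNS, "dataset"])
    n_records = len(degs)

    dup_mask = degs.duplicated(["gene", "dataset"], keep=False)
    if dup_mask.any():
        n_dup = degs.loc[dup_mask, ["gene", "dataset"]].drop_duplicates().shape[0]
        warnings.warn(
            f"collapsed {n_dup} duplicated (gene, dataset) pairs, keeping smallest p_adjust",
            stacklevel=2,
        )
        degs = (
            degs.sort_values("p_adjust", kind="mergesort")
            .drop_duplicates(["gene", "dataset"], keep="first")
            .sort_index()
        )
    degs = degs.reset_index(drop=True)
    degs["direction"] = np.where(degs["log2fc"] > 0, "UP", "DOWN")

    core_rows = []
    for dataset, proteins in (core_protein_lists or {}).items():
        if dataset not in per_study_lists:
            raise ValueError(f"core proteins for unknown dataset {dataset!r}")
        core_rows.extend((str(p).strip().upper(), dataset) for p in proteins)
    core = pd.DataFrame(core_rows, columns=["protein", "dataset"]).drop_duplicates()

    context = dict(dataset_context or {})
    for dataset in datasets:
        context.setdefault(dataset, (f"{dataset}_1", 30))

    return Corpus(
        degs=degs,
        core_proteins=core,
        datasets=datasets,
        dataset_context=context,
        imaging=imaging,
        n_records=n_records,
    )


# ---------------------------------------------------------------------------
# Imaging harmonisation and normalisation
# ---------------------------------------------------------------------------

def harmonize_imaging(
    sources: Mapping[str, pd.DataFrame],
    column_map: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Rename heterogeneous imaging tables onto canonical columns and stack.

    ``column_map[source]`` maps each source's column names onto the canonical
    ones (cell_line, condition, timepoint, feature, value_raw). The output is
    one long table with a ``source`` provenance column; rows whose timepoint
    occurs in only one source are kept and flagged ``unpaired``.
    """
    frames = []
    for name, table in sources.items():
        mapping = dict(column_map.get(name, {}))
        renamed = table.rename(columns=mapping)
        missing = [c for c in IMAGING_COLUMNS if c not in renamed.columns]
        if missing:
            raise SchemaError(
                f"source {name!r}: cannot map to canonical columns {missing}; "
                f"available headers: {sorted(table.columns)}"
            )
        frame = renamed.loc[:, list(IMAGING_COLUMNS)].copy()
        frame["source"] = name
        frames.append(frame)
    merged = pd.concat(frames, ignore_index=True)
    shared = merged.groupby("timepoint")["source"].nunique()
    merged["unpaired"] = merged["timepoint"].map(shared).eq(1) & (len(sources) > 1)
    return merged


def normalize_imaging(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("feature", "condition", "timepoint"),
) -> pd.DataFrame:
    """Fill ``value_norm`` = value_raw / mean over unique cell lines.

    Within each (feature, condition, timepoint) group the reference is the
    mean of per-cell-line means, so lines measured repeatedly do not dominate;
    the resulting value_norm averages to 1 over the unique lines of a group.
    """
    required = set(group_keys) | {"cell_line", "value_raw"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise SchemaError(f"imaging table missing columns: {missing}")
    keys = list(group_keys)
    per_line = table.groupby(keys + ["cell_line"], sort=False)["value_raw"].mean()
    group_mean = per_line.groupby(level=keys, sort=False).mean()
    if (group_mean == 0).any():
        bad = group_mean[group_mean == 0].index.tolist()
        raise ValueError(f"group mean is zero (normalisation undefined) for: {bad}")
    out = table.copy()
    ref = out.set_index(keys).index.map(group_mean)
    out["value_norm"] = out["value_raw"].to_numpy() / np.asarray(ref, dtype=float)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_corpus(corpus: Corpus, outdir) -> dict:
    """Write the corpus as canonical TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus.degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
    corpus.core_proteins.to_csv(outdir / "core_proteins.tsv", sep="\t", index=False)
    files = ["degs.tsv", "core_proteins.tsv"]
    if corpus.imaging is not None:
        corpus.imaging.to_csv(outdir / "imaging.tsv", sep="\t", index=False)
        files.append("imaging.tsv")
    manifest = {
        "datasets": list(corpus.datasets),
        "dataset_context": {d: list(v) for d, v in corpus.dataset_context.items()},
        "n_records": corpus.n_records,
        "n_unique_genes": corpus.n_unique_genes,
        "n_unique_core_proteins": corpus.n_unique_core_proteins,
        "checksums": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_corpus(indir) -> Corpus:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    imaging_path = indir / "imaging.tsv"
    return Corpus(
        degs=pd.read_csv(indir / "degs.tsv", sep="\t"),
        core_proteins=pd.read_csv(indir / "core_proteins.tsv", sep="\t"),
        datasets=tuple(manifest["datasets"]),
        dataset_context={d: (v[0], int(v[1])) for d, v in manifest["dataset_context"].items()},
        imaging=pd.read_csv(imaging_path, sep="\t") if imaging_path.exists() else None,
        n_records=int(manifest["n_records"]),
    )
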