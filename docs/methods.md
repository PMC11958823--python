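# Methods

This note documents the models and procedures implemented in `pdkg`, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical choices a maintainer should know about.

## Corpus construction

Each study enters as a table of differential-expression results (gene
symbol, log2 fold change PD vs control, BH-adjusted p-value). The corpus
keeps the top *N* = 100 most significant genes per study — ranked by
adjusted p-value after removing rows flagged as lncRNA or pseudogene — which
is the conventional "signature" size for cross-study comparison of organoid
transcriptomes. Ranking ties at the truncation boundary are broken by
|log2fc| descending and then by gene symbol; the tie rule is a documented
package choice (any deterministic rule works, but one must be fixed for
reproducibility). Gene symbols are uppercased and stripped at ingestion
because upstream sources mix case conventions. `select_top_degs` is
idempotent, and duplicated (gene, dataset) rows collapse to the smallest
adjusted p-value with a warning.

Imaging features from heterogeneous sources are harmonized by a per-source
column map onto canonical columns (cell_line, condition, timepoint, feature,
value_raw), stacked with a provenance column, and mean-normalized within
each (feature, condition, timepoint) group: the reference is the mean of
per-cell-line means, so a line measured repeatedly is not over-weighted, and
normalized values average to 1 over the unique lines of a group.
Normalization is scale-invariant and refuses groups with zero mean.
Condition is a grouping key because disease-vs-control comparisons are made
within condition; normalizing across conditions would erase the group
effect.

## Knowledge graph

The graph is a typed property graph (networkx `MultiDiGraph` behind a
closed-vocabulary API). Genes and imaged proteins share the `Gene` label —
core proteins are matched to gene symbols and differ only in carrying
core-protein measurement edges and, where the mapping provides one, a
protein accession. One `CellLineTimePoint` node represents a cell line at an
organoid-culture day (id `"<LINE> D<day>"`); study provenance lives on
`MEASURED_IN` edges, so one gene node can carry measurements from several
studies. Resource slices are treated as pre-filtered scopes: every pathway,
disease and drug in a slice becomes a node, while resource *edges* attach
only to genes present in the graph and to rows passing the declarative
filters (interaction-type whitelist, disease-category whitelist). Edges
referencing absent genes are dropped and counted in the build report — the
graph never contains dangling edges. Construction is deterministic; exports
(GraphML, node/edge TSVs with JSON-encoded properties, and a one-CREATE-
per-element statement dump) round-trip to a structurally equal graph.

## Network queries

*Shared genes*: a gene is shared at level *k* when its transcriptomic
measurement edges span ≥ *k* distinct studies; the query can be restricted
to a study subset (e.g. the monogenic studies). A shared gene is
direction-concordant only when **all** studies containing it agree on
UP/DOWN; pairwise overlap counts a gene toward every study pair it belongs
to. *Keyword subnetworks* match pathway display names by case-insensitive
substring — the pragmatic way to collect, say, every ROBO-signalling-related
pathway without maintaining an identifier list (an explicit list can be
passed by naming planted pathways); member genes are restricted to measured
DEGs and extended with their measurement and drug-target edges.
*Core-protein links* enumerate (core protein)–pathway–(top DEG) length-2
paths whose endpoints both carry the requested study tag; an empty result is
meaningful (it states that no imaged protein shares a pathway with any top
DEG in that study). All queries are checked in the test suite against
brute-force scans over the raw generating tables, independent of the graph
path.

## Over-representation analysis

The hypergeometric upper tail is evaluated through `scipy.stats.hypergeom`
(log-space-safe for large universes). The default universe is the union of
all genes annotated in the gene-set collection — the standard ORA convention
when no custom background is supplied — and is overridable because
enrichment rankings depend on it. Sets are intersected with the universe
before testing; sets with overlap below `min_overlap` (default 1) are
excluded *before* BH adjustment, which is performed across all tested sets
via `statsmodels`. The suite verifies p-values against an exact
rational-arithmetic oracle (and a literal enumeration of all draws on a
small case) to 10 significant digits, and BH against an independently coded
step-up.

## Similarity network fusion

Implemented from scratch (it is the methodological core). Per layer,
features are z-scored and Euclidean distances d(i,j) feed the scaled
exponential kernel W(i,j) = exp(−d²/(μ·ε_ij)) with
ε_ij = (mean_K(i) + mean_K(j) + d(i,j))/3, where mean_K(i) is the mean
distance of i to its K nearest neighbours. A floor of 1e−12 on μ·ε guards
duplicate samples. Two operators derive from W: the full kernel P with
P(i,i) = 1/2 and off-diagonal rows scaled to mass 1/2 (rows sum to 1), and
the local kernel S, row-stochastic on each sample's K nearest neighbours.
Fusion runs t parallel rounds of P_v ← S_v · mean(P_w, w≠v) · S_vᵀ,
re-normalizing after every round so the diagonal-1/2 / row-sum-1 invariant
holds throughout; with a single layer the update is skipped entirely, making
fusion the identity on P.

The fused matrix is the mean of the final per-layer kernels. A single
symmetrize-then-normalize pass cannot make it simultaneously symmetric and
row-normalized, so the final step rescales the off-diagonal part as
D·A·D (symmetric diagonal scaling: Sinkhorn warm start plus Newton
iterations on the scaling vector, tolerance 1e−15) until every row's
off-diagonal mass is 1/2, then pins the diagonal at 1/2. The result is
exactly symmetric with self-similarity exactly 0.5 and unit row sums to
machine precision; plain Sinkhorn alone converges too slowly when clusters
are well separated, which is why the Newton step exists.

Defaults: K = 3 (appropriate for the 9-sample cohorts this pipeline
targets — 3 controls plus 6 patient lines), μ = 0.5 and t = 20, all inside
the ranges recommended for this family of kernels, and all overridable.
Spectral clustering embeds samples in the k lowest eigenvectors of the
symmetric normalized Laplacian, row-normalizes, and runs k-means with a
fixed seed and 50 restarts; given the seed the whole stage is deterministic.
A warning fires when the similarity graph has more connected components than
clusters.

## PCA and hierarchical clustering

Both operate on the rectangular log2FC matrix over the union of all
studies' top genes. A gene absent from a study's top list gets log2FC 0
("no measured change") — the neutral fill for fold-change data, and
configurable. PCA uses the full SVD solver (deterministic); components are
orthonormal and explained-variance fractions non-increasing. Agglomerative
clustering defaults to average linkage on Euclidean distances; correlation
distance is refused for constant rows (undefined) with guidance to use
Euclidean. Dendrograms export as Newick with merge-height branch lengths.

## Synthetic data: what it emulates and what it does not

The generators plant structure rather than simulate measurement: adjusted
p-values are sorted uniform draws from (0, 0.05) and |log2FC| uniform in
(0.5, 3) — placeholders whose ranks and signs alone matter downstream.
The default five-study scenario (`pd_study_scenario`) reproduces the design
of the organoid corpus this pipeline targets: four monogenic top-100 lists
plus one IPD list over a 1000-gene synthetic universe (symbols G000001…, so
no real biology is implied), with 25 genes planted into exactly two of the
four monogenic lists (15 into LRRK2∩MIRO1, 12 direction-concordant, 13
discordant, none in all four), 35 genes shared between one monogenic list
and the IPD list (the five lists then merge to 440 unique genes), 12 unique
core imaging proteins across the monogenic studies and 13 once the IPD
8-marker panel is added. Core-protein names reuse standard immunostaining
markers (TH, TUBB3, GFAP, …) as vocabulary. Stratification cohorts draw
per-group feature centres from N(0, effect²) with N(0, noise²) sample noise;
the defaults (9 samples in groups 3+6 or 3+2+4, 10 features per layer,
effect 4, noise 1) represent a strongly separated cohort of the size this
pipeline is meant for.

What passing tests on these inputs show: the set arithmetic, graph queries,
enrichment statistics and fusion/clustering machinery are correct on data
with known truth at realistic sizes. What they do not show: robustness to
real-data pathologies — symbol aliasing, batch effects, heavy-tailed noise,
correlated features, annotation incompleteness — none of which the
generators model.

## Scale of the shipped analyses

The test suite and the acceptance script run entirely on generated inputs:
five 100-gene study lists over a 1000-gene universe, resource slices of a
few dozen entities, 9-sample two-layer cohorts (20 replicate seeds for the
recovery checks, where recovery is summarized as the mean adjusted Rand
index across replicates), and enrichment oracles on universes up to 25
genes. These sizes were chosen so every expected value can be verified by
hand or by exact enumeration.

## Known limitations

- Differential expression is an input, not a computation: the pipeline
  starts from per-study DEG tables (no count-level or single-cell
  processing).
- Resource adapters consume frozen slices; there is no live fetching of
  pathway/interaction/drug databases, and absolute node/edge counts on real
  snapshots depend on the snapshot date.
- Keyword-based pathway selection is a name heuristic; identifier lists are
  more precise when available.
- The 0-fill rule for missing log2FC values biases cross-study distances
  toward the origin for studies with little overlap; alternative imputations
  may reorder PCA/clustering results.
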