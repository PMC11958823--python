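"""Over-representation analysis of gene lists against gene-set collections.

For a query list of n genes drawn from a universe of N genes, a gene set with
m members inside the universe and k of them in the query list is scored with
the hypergeometric upper tail p = P(X >= k), X ~ Hypergeom(N, m, n), followed
by Benjamini-Hochberg adjustment across the tested sets. By the standard ORA
convention the default universe is the union of all genes annotated in the
collection.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ("name", "k", "m", "n_list", "N", "p", "p_adjust", "overlap_genes")


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, m successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p_adj(i) = min over j with p(j) >= p(i) of min(1, p(j) * m / rank(j)).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str] | None = None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Rank gene sets by hypergeometric over-representation of a gene list.

    Gene sets are intersected with the universe before testing; sets whose
    overlap with the query list falls below ``min_overlap`` are excluded
    before multiple-testing correction. Results are sorted by ascending p
    (ties by set name), with columns name/k/m/n_list/N/p/p_adjust/
    overlap_genes. Gene order in the inputs never affects the result.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if universe is None:
        uni = {g for members in gene_sets.values() for g in members}
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    outside = sorted(genes - uni)
    if outside:
        raise ValueError(f"gene list contains symbols outside the universe: {outside}")

    N = len(uni)
    n_list = len(genes)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & uni
        overlap = sorted(in_universe & genes)
        k, m = len(overlap), len(in_universe)
        if k < min_overlap:
            continue
        p = hypergeom_upper_tail(k, N, m, n_list)
        rows.append((name, k, m, n_list, N, p, tuple(overlap)))

    result = pd.DataFrame(rows, columns=["name", "k", "m", "n_list", "N", "p", "overlap_genes"])
    if len(result):
        result["p_adjust"] = bh_adjust(result["p"].to_numpy())
    else:
        result["p_adjust"] = pd.Series(dtype=float)
    result = result.sort_values(["p", "name"], kind="mergesort").reset_index(drop=True)
    return result.loc[:, list(RESULT_COLUMNS)]
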