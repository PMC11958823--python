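"""Sample stratification: similarity network fusion, spectral clustering,
PCA and unsupervised hierarchical clustering.

Similarity network fusion (SNF) integrates several feature layers measured on
the same ordered sample set. Per layer, a scaled exponential kernel

    W(i, j) = exp(-d^2(i, j) / (mu * eps_ij)),
    eps_ij = (mean_K(i) + mean_K(j) + d(i, j)) / 3,

with d the Euclidean distance on per-feature standardized values and
mean_K(i) the mean distance of sample i to its K nearest neighbours, yields a
full kernel P (row-normalized so that P(i,i) = 1/2 and each row's off-diagonal
mass is 1/2) and a sparse local kernel S (row-stochastic, supported on each
sample's K nearest neighbours). Fusion cross-diffuses the full kernels through
the local ones, P_v <- S_v (mean of the other layers' P) S_v^T, re-normalizing
after every step, and averages the diffused kernels into one fused similarity
matrix used for spectral clustering. Self-similarity is pinned at 0.5
throughout, and every row of every normalized matrix sums to 1.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

# distance floor guarding the kernel bandwidth against duplicate samples
EPS_FLOOR = 1e-12

DEFAULT_K = 3
DEFAULT_MU = 0.5
DEFAULT_T = 20


def standardize(X: np.ndarray) -> np.ndarray:
    """Per-feature z-scores; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _as_matrix(layer) -> tuple[np.ndarray, list | None]:
    if isinstance(layer, pd.DataFrame):
        return layer.to_numpy(dtype=float), list(layer.index)
    return np.asarray(layer, dtype=float), None


def _pnorm(W: np.ndarray) -> np.ndarray:
    """Row-normalize so the diagonal is exactly 1/2 and each row sums to 1."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    sums = off.sum(axis=1)
    P = np.empty_like(off)
    for i in range(n):
        if sums[i] > 0:
            P[i] = off[i] / (2.0 * sums[i])
        else:  # isolated row: spread the off-diagonal half uniformly
            P[i] = 0.5 / (n - 1) if n > 1 else 0.0
            P[i, i] = 0.0
    np.fill_diagonal(P, 0.5)
    return P


def _symmetric_pnorm(A: np.ndarray, tol: float = 1e-15, max_iter: int = 100) -> np.ndarray:
    """Nearest normalization of a symmetric kernel that keeps it symmetric.

    Rescales the off-diagonal part as D*A*D (symmetric Sinkhorn scaling) until
    every row's off-diagonal mass is 1/2, then pins the diagonal at 1/2 -- so
    the result is simultaneously symmetric, row-stochastic and has
    self-similarity exactly 0.5.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    zero_rows = off.sum(axis=1) == 0
    if zero_rows.any() and n > 1:  # isolated samples: connect uniformly, symmetrically
        for i in np.where(zero_rows)[0]:
            off[i, :] = off[:, i] = 1.0 / (n - 1)
            off[i, i] = 0.0
    # Sinkhorn warm start, then Newton on F(s) = s * (O s) - 1/2 = 0
    # (plain Sinkhorn converges too slowly when clusters are well separated)
    s = np.ones(n)
    for _ in range(50):
        rows = s * (off @ s)
        if np.max(np.abs(rows - 0.5)) < tol:
            break
        s *= np.sqrt(0.5 / rows)
    for _ in range(max_iter):
        Os = off @ s
        F = s * Os - 0.5
        if np.max(np.abs(F)) < tol:
            break
        J = np.diag(Os) + s[:, None] * off
        delta = np.linalg.solve(J, F)
        while np.any(s - delta <= 0):
            delta *= 0.5
        s = s - delta
    W = off * np.outer(s, s)
    np.fill_diagonal(W, 0.5)
    return W


def _local_kernel(W: np.ndarray, D: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic kernel supported on each row's K nearest neighbours."""
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        neighbours = [j for j in order if j != i][:K]
        denom = W[i, neighbours].sum()
        if denom <= 0:
            S[i, neighbours] = 1.0 / len(neighbours)
        else:
            S[i, neighbours] = W[i, neighbours] / denom
    return S


def affinity(
    layer,
    K: int = DEFAULT_K,
    mu: float = DEFAULT_MU,
    standardize_features: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Full kernel P and local kernel S of one feature layer.

    ``layer`` is a samples x features matrix (DataFrame or array). Features
    are standardized before Euclidean distances unless disabled. Requires
    1 <= K < n_samples and mu > 0.
    """
    X, _ = _as_matrix(layer)
    n = X.shape[0]
    if not 1 <= K < n:
        raise ValueError(f"require 1 <= K < n_samples, got K={K}, n={n}")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if standardize_features:
        X = standardize(X)
    D = squareform(pdist(X, metric="euclidean"))
    nearest = np.sort(D, axis=1)[:, 1:K + 1]  # exclude self-distance 0
    mean_k = nearest.mean(axis=1)
    eps = (mean_k[:, None] + mean_k[None, :] + D) / 3.0
    eps = np.maximum(eps, EPS_FLOOR)
    W = np.exp(-(D ** 2) / (mu * eps))
    return _pnorm(W), _local_kernel(W, D, K)


def snf_fuse(
    Ps: Sequence[np.ndarray],
    Ss: Sequence[np.ndarray],
    t: int = DEFAULT_T,
) -> np.ndarray:
    """Fuse per-layer kernels by t rounds of cross-diffusion.

    Each round updates every layer in parallel, P_v <- S_v * mean(P_w, w != v)
    * S_v^T, re-normalizing afterwards so diagonals stay at 1/2 and rows sum
    to 1. The fused matrix is the mean of the final per-layer kernels, brought
    to a simultaneously symmetric and row-normalized fixed point. With a
    single layer, fusion is the identity on the normalized kernel.
    """
    if len(Ps) != len(Ss) or not Ps:
        raise ValueError("need matching, non-empty P and S lists")
    if t < 1:
        raise ValueError("t must be >= 1")
    shapes = {P.shape for P in Ps} | {S.shape for S in Ss}
    if len(shapes) != 1:
        raise ValueError("all layers must share the same sample set and order")

    m = len(Ps)
    if m == 1:
        return Ps[0].copy()

    P = [np.array(p, dtype=float) for p in Ps]
    for _ in range(t):
        P_new = []
        for v in range(m):
            others = sum(P[w] for w in range(m) if w != v) / (m - 1)
            P_new.append(_pnorm(Ss[v] @ others @ Ss[v].T))
        P = P_new

    fused = sum(P) / m
    return _symmetric_pnorm((fused + fused.T) / 2.0)


@dataclass
class FusedNetwork:
    """Per-layer and fused similarity matrices plus optional cluster labels."""

    samples: tuple[str, ...]
    layer_names: tuple[str, ...]
    P: list[np.ndarray]
    S: list[np.ndarray]
    W_fused: np.ndarray
    labels: np.ndarray | None = None


def validate_layers(layers: Sequence) -> tuple[list[np.ndarray], tuple[str, ...]]:
    """Check shared sample order and absence of missing values."""
    if not layers:
        raise ValueError("need at least one layer")
    mats, names = [], None
    for layer in layers:
        X, idx = _as_matrix(layer)
        if np.isnan(X).any():
            raise ValueError("layers must be complete (no missing values)")
        if idx is not None:
            if names is None:
                names = idx
            elif idx != names:
                raise ValueError("mismatched sample orderings across layers")
        mats.append(X)
    n = {X.shape[0] for X in mats}
    if len(n) != 1:
        raise ValueError("all layers must have the same number of samples")
    if names is None:
        names = [f"S{i + 1}" for i in range(mats[0].shape[0])]
    return mats, tuple(str(s) for s in names)


def snf(
    layers: Sequence,
    K: int = DEFAULT_K,
    mu: float = DEFAULT_MU,
    t: int = DEFAULT_T,
    n_clusters: int | None = None,
    seed: int = 0,
    layer_names: Sequence[str] | None = None,
) -> FusedNetwork:
    """Run the full SNF stage: per-layer kernels, fusion, optional clustering."""
    mats, samples = validate_layers(layers)
    Ps, Ss = [], []
    for X in mats:
        P, S = affinity(X, K=K, mu=mu)
        Ps.append(P)
        Ss.append(S)
    W = snf_fuse(Ps, Ss, t=t)
    labels = spectral_cluster(W, n_clusters, seed=seed) if n_clusters else None
    names = tuple(layer_names) if layer_names else tuple(f"layer{i + 1}" for i in range(len(mats)))
    return FusedNetwork(samples=samples, layer_names=names, P=Ps, S=Ss, W_fused=W, labels=labels)


def spectral_cluster(W: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of a symmetric similarity matrix.

    Embeds samples into the k eigenvectors of the symmetric normalized
    Laplacian with smallest eigenvalues, row-normalizes the embedding, and
    partitions it with k-means (fixed seed, 50 restarts) for a deterministic
    contract.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("W must be square")
    if np.max(np.abs(W - W.T)) > 1e-8:
        raise ValueError("W must be symmetric")
    if np.min(W) < 0:
        raise ValueError("W must be non-negative")
    if not 2 <= k < n:
        raise ValueError(f"require 2 <= k < n_samples, got k={k}, n={n}")

    Wsym = (W + W.T) / 2.0
    d = Wsym.sum(axis=1)
    d[d == 0] = 1.0
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(n) - inv_sqrt[:, None] * Wsym * inv_sqrt[None, :]
    evals, evecs = eigh(L)
    if int(np.sum(evals < 1e-10)) > k:
        warnings.warn(
            f"similarity graph has more than {k} connected components; "
            "clusters may merge components arbitrarily",
            stacklevel=2,
        )
    U = evecs[:, :k]
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    U = U / norms[:, None]
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return km.fit_predict(U)


# ---------------------------------------------------------------------------
# PCA and hierarchical clustering on log2FC profiles
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame          # samples x components
    explained_variance_ratio: np.ndarray
    components: np.ndarray             # components x features (orthonormal rows)


def pca_embed(matrix, n_components: int = 2) -> PCAResult:
    """Principal-component embedding of sample profiles (e.g. log2FC rows)."""
    X, idx = _as_matrix(matrix)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    index = idx if idx is not None else [f"S{i + 1}" for i in range(X.shape[0])]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=index,
                                 columns=[f"PC{i + 1}" for i in range(n_components)]),
        explained_variance_ratio=model.explained_variance_ratio_,
        components=model.components_,
    )


@dataclass
class HclustResult:
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    labels: tuple[str, ...]

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            bl_l = node.dist - node.left.dist
            bl_r = node.dist - node.right.dist
            return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

        return walk(tree) + ";"


def hclust(matrix, method: str = "average", metric: str = "euclidean") -> HclustResult:
    """Deterministic agglomerative clustering of sample profiles.

    Correlation distance on a constant row is undefined (zero variance); that
    case raises with guidance to use Euclidean distance instead.
    """
    X, idx = _as_matrix(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    labels = tuple(str(s) for s in (idx if idx is not None else range(1, X.shape[0] + 1)))
    if metric == "correlation" and np.any(X.std(axis=1) == 0):
        raise ValueError(
            "correlation distance undefined for constant rows; use metric='euclidean'"
        )
    dists = pdist(X, metric=metric)
    if np.any(~np.isfinite(dists)):
        raise ValueError(f"non-finite distances under metric {metric!r}; use metric='euclidean'")
    Z = hierarchy.linkage(dists, method=method)
    order = hierarchy.leaves_list(Z)
    return HclustResult(linkage=Z, leaf_order=tuple(labels[i] for i in order), labels=labels)


def log2fc_matrix(degs: pd.DataFrame, fill: float = 0.0) -> pd.DataFrame:
    """Datasets x union-of-genes log2FC matrix from long-form DEG records.

    Genes absent from a dataset's top list get ``fill`` (default 0: no
    measured change), producing the rectangular matrix that PCA and
    hierarchical clustering require.
    """
    required = {"gene", "dataset", "log2fc"}
    missing = sorted(required - set(degs.columns))
    if missing:
        raise ValueError(f"DEG records missing columns: {missing}")
    wide = degs.pivot_table(index="dataset", columns="gene", values="log2fc", aggfunc="mean")
    return wide.fillna(fill).sort_index()
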