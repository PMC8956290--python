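"""Per-age dimensionality reduction, graph clustering, and DE-based refinement.

The latent dimension is chosen by random-matrix theory: the number of
eigenvalues of the gene-gene correlation matrix exceeding the 99th percentile
of the Tracy-Widom largest-eigenvalue law for a matched pure-noise matrix.
Cells are embedded either by PCA (single batch) or by an integrative
non-negative matrix factorization that shares a gene-factor matrix across
batches with batch-specific terms, followed by quantile normalization of the
loadings. Clustering builds a 30-nearest-neighbor graph, weights edges by the
Jaccard overlap of neighbor sets, and runs Louvain community detection.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .preprocess import annotate_classes

# 99th percentile of the Tracy-Widom distribution (beta = 1, real case)
TRACY_WIDOM_99 = 2.0234


def choose_dim_rmt(X: np.ndarray) -> int:
    """Latent dimension from the Tracy-Widom null for correlation eigenvalues.

    ``X`` is genes x cells (HVG-restricted). Each gene is standardized, the
    eigenvalues of the gene-gene correlation matrix are computed via SVD, and
    the count above the Tracy-Widom 99th-percentile threshold (real Wishart
    centering and scaling) is returned.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if n < 2:
        raise ValueError("need at least 2 cells")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = sd.ravel() > 0
    Z = (X[keep] - mean[keep]) / sd[keep]
    m = Z.shape[0]
    # eigenvalues of Z Z^T / n
    svals = np.linalg.svd(Z, compute_uv=False)
    evals = svals**2 / n
    mu = (np.sqrt(n - 1) + np.sqrt(m)) ** 2 / n
    sigma = (np.sqrt(n - 1) + np.sqrt(m)) / n * (1.0 / np.sqrt(n - 1) + 1.0 / np.sqrt(m)) ** (1.0 / 3.0)
    threshold = mu + TRACY_WIDOM_99 * sigma
    return int((evals > threshold).sum())


@dataclass
class Embedding:
    """Cells x k factor loadings with the batch assignment used."""

    H: np.ndarray
    k: int
    batches: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.H).all():
            raise ValueError("loadings must be finite")


def _quantile_normalize_loadings(H: np.ndarray, batches: np.ndarray) -> np.ndarray:
    """Match each batch's per-factor loading quantiles to the largest batch."""
    H = H.copy()
    ids, counts = np.unique(batches, return_counts=True)
    ref = ids[np.argmax(counts)]
    ref_mask = batches == ref
    for b in ids:
        if b == ref:
            continue
        mask = batches == b
        for f in range(H.shape[1]):
            src = H[mask, f]
            ref_sorted = np.sort(H[ref_mask, f])
            ranks = scipy.stats.rankdata(src, method="average")
            q = (ranks - 0.5) / len(src)
            H[mask, f] = np.quantile(ref_sorted, q)
    return H


def _inmf(
    Xb: list[np.ndarray], k: int, lam: float = 5.0, n_iter: int = 100, seed: int = 0
) -> list[np.ndarray]:
    """Integrative NMF: per-batch X_b ~ H_b (W + V_b), multiplicative updates.

    W is the shared gene-factor matrix; V_b absorbs batch-specific expression
    modules and is shrunk by the penalty ``lam * ||H_b V_b||^2``.
    """
    rng = np.random.default_rng(seed)
    n_genes = Xb[0].shape[1]
    eps = 1e-10
    W = rng.uniform(0, 1, size=(k, n_genes))
    V = [rng.uniform(0, 0.1, size=(k, n_genes)) for _ in Xb]
    H = [rng.uniform(0, 1, size=(x.shape[0], k)) for x in Xb]
    for _ in range(n_iter):
        for b, X in enumerate(Xb):
            Wb = W + V[b]
            num = X @ Wb.T
            den = H[b] @ (Wb @ Wb.T + lam * (V[b] @ V[b].T)) + eps
            H[b] *= num / den
        num_W = sum(H[b].T @ Xb[b] for b in range(len(Xb)))
        den_W = sum(H[b].T @ H[b] @ (W + V[b]) for b in range(len(Xb))) + eps
        W *= num_W / den_W
        for b, X in enumerate(Xb):
            HtH = H[b].T @ H[b]
            num_V = H[b].T @ X
            den_V = HtH @ (W + (1.0 + lam) * V[b]) + eps
            V[b] *= num_V / den_V
    return H


def embed(
    X: np.ndarray,
    batches: np.ndarray | None = None,
    k: int | None = None,
    mode: str = "auto",
    seed: int = 0,
) -> Embedding:
    """Embed cells in a k-dimensional latent space, integrating batches.

    ``X`` is cells x genes (HVG-restricted normalized log values). With one
    batch (or ``mode='pca'``) loadings are standard PCA scores. With several
    batches (``mode='inmf'``), a shared-factor non-negative factorization with
    batch-specific terms is fitted and the loadings are quantile-normalized
    across batches.
    """
    X = np.asarray(X, dtype=float)
    n_cells, n_genes = X.shape
    if batches is None:
        batches = np.zeros(n_cells, dtype=int)
    batches = np.asarray(batches)
    if k is None:
        k = max(choose_dim_rmt(X.T), 2)
    if k > min(n_genes, n_cells):
        raise ValueError(f"k={k} exceeds min(genes, cells)={min(n_genes, n_cells)}")
    n_batches = len(np.unique(batches))
    if mode == "auto":
        mode = "pca" if n_batches == 1 else "inmf"
    if mode == "pca":
        Xc = X - X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        H = PCA(n_components=k, random_state=seed).fit_transform(Xc / sd)
    elif mode == "inmf":
        if X.min() < 0:
            raise ValueError("iNMF requires nonnegative input")
        ids = np.unique(batches)
        idx = [np.where(batches == b)[0] for b in ids]
        Hb = _inmf([X[i] for i in idx], k=k, seed=seed)
        H = np.zeros((n_cells, k))
        for i, h in zip(idx, Hb):
            H[i] = h
        rowsum = H.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        H = H / rowsum
        H = _quantile_normalize_loadings(H, batches)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Embedding(H=H, k=k, batches=batches, mode=mode)


@dataclass
class ClusterPartition:
    """Per-cell cluster ids (contiguous from 1, ordered by decreasing size)."""

    labels: np.ndarray
    age: float | str | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self._relabel()

    def _relabel(self) -> None:
        """Renumber clusters 1..K by decreasing size."""
        ids, counts = np.unique(self.labels, return_counts=True)
        order = ids[np.argsort(-counts, kind="stable")]
        mapping = {old: new + 1 for new, old in enumerate(order)}
        self.labels = np.array([mapping[v] for v in self.labels])

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    @property
    def sizes(self) -> pd.Series:
        ids, counts = np.unique(self.labels, return_counts=True)
        return pd.Series(counts, index=ids, name="size")

    def frequencies(self) -> np.ndarray:
        return (self.sizes / len(self.labels)).to_numpy()


def graph_cluster(
    emb: Embedding | np.ndarray,
    n_neighbors: int = 30,
    resolution: float = 0.5,
    seed: int = 0,
    age=None,
) -> ClusterPartition:
    """kNN graph + Jaccard edge weights + Louvain community detection."""
    H = emb.H if isinstance(emb, Embedding) else np.asarray(emb)
    n = H.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(H)
    _, idx = nn.kneighbors(H)
    neigh = idx[:, 1:]  # drop self
    # adjacency of the (directed) kNN graph, symmetrized
    rows = np.repeat(np.arange(n), n_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * n_neighbors), (rows, neigh.ravel())), shape=(n, n)
    )
    A = ((A + A.T) > 0).astype(float)
    # Jaccard overlap of neighbor sets for each edge
    inter = (A @ A.T).multiply(A)  # shared neighbors, restricted to edges
    deg = np.asarray(A.sum(axis=1)).ravel()
    inter = sp.coo_matrix(sp.triu(inter, k=1))
    union = deg[inter.row] + deg[inter.col] - inter.data
    weights = inter.data / np.maximum(union, 1.0)
    edges = list(zip(inter.row.tolist(), inter.col.tolist()))
    g = igraph.Graph(n=n, edges=edges)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=weights.tolist(), resolution=resolution)
    return ClusterPartition(labels=np.asarray(part.membership) + 1, age=age)


def de_genes(
    em: ExpressionMatrix,
    labels: np.ndarray,
    a: int,
    b: int,
    logfc_threshold: float = 0.5,
    alpha: float = 1e-5,
    logfc_cap: float = 10.0,
) -> pd.DataFrame:
    """Differential expression between clusters ``a`` and ``b``.

    The log fold change uses the size-balanced form
    ln[(|Cb| * sum_a X) / (|Ca| * sum_b X)]; p-values come from a Wilcoxon
    rank-sum test on normalized log values (a pluggable substitute for a
    hurdle-model test) with Benjamini-Hochberg correction. A gene is
    significant if |logFC| > ``logfc_threshold`` and adjusted p < ``alpha``.
    Genes with zero expression in both clusters are skipped; one-sided zeros
    are capped at +/- ``logfc_cap``.
    """
    labels = np.asarray(labels)
    ma, mb = labels == a, labels == b
    if not ma.any() or not mb.any():
        raise ValueError(f"clusters {a} and {b} must both be nonempty")
    X = em.dense()
    Xa, Xb = X[:, ma], X[:, mb]
    sum_a, sum_b = Xa.sum(axis=1), Xb.sum(axis=1)
    na, nb = int(ma.sum()), int(mb.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.log((nb * sum_a) / (na * sum_b))
    logfc = np.clip(logfc, -logfc_cap, logfc_cap)
    tested = (sum_a + sum_b) > 0
    stat = scipy.stats.mannwhitneyu(Xa, Xb, axis=1, alternative="two-sided")
    pvals = stat.pvalue
    padj = np.full_like(pvals, np.nan)
    padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    table = pd.DataFrame(
        {"logfc": logfc, "pval": pvals, "padj": padj, "tested": tested},
        index=em.genes,
    )
    table["significant"] = (
        tested & (np.abs(logfc) > logfc_threshold) & (table["padj"] < alpha)
    )
    return table


def n_significant_de(em, labels, a, b, **kwargs) -> int:
    return int(de_genes(em, labels, a, b, **kwargs)["significant"].sum())


def refine_partition(
    partition: ClusterPartition,
    em: ExpressionMatrix,
    embedding: np.ndarray | None = None,
    marker_sets: dict[str, list[str]] | None = None,
    primary_class: str | None = None,
    min_de_genes: int = 10,
    **de_kwargs,
) -> ClusterPartition:
    """Merge indistinct sibling clusters; drop contaminant clusters.

    A dendrogram (average linkage) over cluster centroids in embedding space
    nominates terminal sibling pairs; pairs separated by fewer than
    ``min_de_genes`` significant DE genes are merged, iterating until stable.
    If ``marker_sets`` and ``primary_class`` are given, clusters annotated to
    a different class (or flagged as doublets) are removed. Every action is
    logged; refinement never increases the cluster count.
    """
    labels = partition.labels.copy()
    log = list(partition.log)
    coords = embedding if embedding is not None else em.dense().T

    def centroids(lbls):
        ids = np.unique(lbls)
        return ids, np.vstack([coords[lbls == i].mean(axis=0) for i in ids])

    changed = True
    while changed and len(np.unique(labels)) > 1:
        changed = False
        ids, cent = centroids(labels)
        if len(ids) == 2:
            sib_pairs = [(ids[0], ids[1])]
        else:
            link = scipy.cluster.hierarchy.linkage(cent, method="average")
            sib_pairs = []
            for row in link:
                i, j = int(row[0]), int(row[1])
                if i < len(ids) and j < len(ids):  # both original leaves
                    sib_pairs.append((ids[i], ids[j]))
        for a, b in sib_pairs:
            n_de = n_significant_de(em, labels, a, b, **de_kwargs)
            if n_de < min_de_genes:
                labels[labels == b] = a
                log.append(f"merged cluster {b} into {a} ({n_de} DE genes)")
                changed = True
                break  # recompute dendrogram after each merge

    if marker_sets is not None and primary_class is not None:
        ann = annotate_classes(em, labels, marker_sets)
        bad = ann.index[(ann["label"] != primary_class) | ann["doublet"]]
        for c in bad:
            reason = "doublet" if ann.loc[c, "doublet"] else f"class {ann.loc[c, 'label']}"
            log.append(f"removed cluster {c} ({reason})")
        keep_mask = ~np.isin(labels, bad)
        if not keep_mask.all() and keep_mask.any():
            out = ClusterPartition(labels=labels[keep_mask], age=partition.age, log=log)
            out.kept_cells = keep_mask
            return out

    out = ClusterPartition(labels=labels, age=partition.age, log=log)
    out.kept_cells = np.ones(len(labels), dtype=bool)
    return out
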