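"""Quality filtering, normalization, Gamma-Poisson HVG selection, annotation.

Highly variable genes are selected against a technical-noise null in which
UMI counts are Poisson with Gamma-distributed library sizes: for a gene with
mean count mu the null coefficient of variation is sqrt(1/mu + 1/alpha),
where alpha is the Gamma shape fitted by maximum likelihood to the normalized
library sizes. Genes whose deviation d = log(CV / CV_null) exceeds
mean(d) + z * sd(d) (z = 0.8 by default) are flagged as HVGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import CountMatrix, ExpressionMatrix


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every cell."""


def filter_cells_genes(
    cm: CountMatrix,
    min_genes_per_cell: int = 700,
    min_cells_per_gene: int = 10,
) -> CountMatrix:
    """Drop cells detecting too few genes, then genes seen in too few cells.

    The two passes run in that order (cells first); the numbers removed are
    recorded in ``result.obs.attrs['filter_log']``.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be nonnegative")
    detected = cm.counts.copy()
    detected.data = np.ones_like(detected.data)
    genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell
    if not cell_mask.any():
        raise EmptyResultError(
            f"no cell detects >= {min_genes_per_cell} genes "
            f"(max observed {int(genes_per_cell.max()) if len(genes_per_cell) else 0})"
        )
    kept_cells = cm.subset(cell_mask=cell_mask)
    detected = kept_cells.counts.copy()
    detected.data = np.ones_like(detected.data)
    cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    gene_mask = cells_per_gene >= min_cells_per_gene
    out = kept_cells.subset(gene_mask=gene_mask)
    out.obs.attrs["filter_log"] = {
        "cells_removed": int((~cell_mask).sum()),
        "genes_removed": int((~gene_mask).sum()),
    }
    return out


def normalize_log(cm: CountMatrix, target: float | None = None) -> ExpressionMatrix:
    """Scale each cell to a common total then apply log(1 + x).

    The default total is the median of the per-cell count sums of the data at
    hand (the published analysis used its own dataset's median, 8340; that
    number is dataset-specific, so it is recomputed here unless overridden).
    """
    colsums = np.asarray(cm.counts.sum(axis=0)).ravel()
    if (colsums <= 0).any():
        raise ValueError("every cell must have a positive total count; filter first")
    if target is None:
        target = float(np.median(colsums))
    X = cm.counts.astype(float).multiply(sp.csr_matrix(np.reciprocal(colsums / target)[None, :]))
    X = sp.csr_matrix(X)
    X.data = np.log1p(X.data)
    return ExpressionMatrix(X=X, genes=cm.genes, cells=cm.cells, target=target, obs=cm.obs)


@dataclass
class HVGResult:
    """Per-gene variability statistics and the fitted Gamma shape ``alpha``."""

    table: pd.DataFrame  # mean, cv, cv_null, d, selected
    alpha: float
    z_factor: float

    @property
    def selected_genes(self) -> pd.Index:
        return self.table.index[self.table["selected"]]

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def fit_library_gamma(cm: CountMatrix) -> float:
    """ML fit of the Gamma shape to normalized library sizes T_n."""
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    T = totals / totals.sum()
    if (T <= 0).any():
        raise ValueError("cells with zero totals present; filter first")
    try:
        alpha, _, _ = scipy.stats.gamma.fit(T, floc=0)
    except Exception as exc:  # pragma: no cover - scipy fit rarely fails
        raise RuntimeError(
            f"Gamma fit to library sizes failed: {exc}; "
            f"T range [{T.min():.3g}, {T.max():.3g}], n={len(T)}"
        ) from exc
    return float(alpha)


def select_hvgs(cm: CountMatrix, z_factor: float = 0.8) -> HVGResult:
    """Gamma-Poisson highly-variable-gene selection on raw UMI counts.

    Genes with zero mean are excluded from the deviation statistics; genes
    with zero variance get d = -inf and are never selected.
    """
    alpha = fit_library_gamma(cm)
    C = cm.counts
    n = C.shape[1]
    mu = np.asarray(C.mean(axis=1)).ravel()
    ex2 = np.asarray(C.multiply(C).mean(axis=1)).ravel()
    var = ex2 - mu**2
    # clamp float cancellation noise so constant genes get CV exactly 0
    var[var <= 1e-10 * np.maximum(mu, 1.0) ** 2] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / mu
        cv_null = np.sqrt(1.0 / mu + 1.0 / alpha)
        d = np.log(cv / cv_null)
    d[np.isnan(d)] = -np.inf  # mu = 0
    d[cv == 0] = -np.inf
    finite = np.isfinite(d)
    if finite.sum() < 2:
        raise ValueError("too few expressed genes to compute deviation statistics")
    d_mean = d[finite].mean()
    d_sd = d[finite].std(ddof=0)
    selected = finite & (d > d_mean + z_factor * d_sd)
    table = pd.DataFrame(
        {"mean": mu, "cv": cv, "cv_null": cv_null, "d": d, "selected": selected},
        index=cm.genes,
    )
    return HVGResult(table=table, alpha=alpha, z_factor=z_factor)


# default marker sets for class annotation (retinal cell classes)
DEFAULT_MARKERS: dict[str, list[str]] = {
    "RGC": ["Rbpms", "Slc17a6", "Sncg", "Nefl"],
    "microglia": ["P2ry12", "C1qa", "C1qb", "C1qc", "Tmem119"],
    "photoreceptor": ["Otx2", "Gngt2", "Gnb3"],
    "amacrine": ["Tfap2a", "Tfap2b", "Onecut2"],
    "anterior_segment": ["Mgp", "Col3a1", "Igfbp7"],
    "cycling_progenitor": ["Ccnd1", "Fgf15", "Hes5"],
    "neurogenic_progenitor": ["Hes6", "Ascl1", "Neurog2"],
}


def annotate_classes(
    em: ExpressionMatrix,
    cluster_labels: np.ndarray,
    marker_sets: dict[str, list[str]] | None = None,
    doublet_z: float = 0.5,
) -> pd.DataFrame:
    """Assign a cell-class label per cluster from marker-set scores.

    Each class score is the mean (across its marker genes present in the
    matrix) of per-gene z-scored log expression, averaged over the cluster's
    cells. The cluster label is the argmax class; clusters scoring above
    ``doublet_z`` on two or more classes are flagged as doublets. Returns a
    per-cluster table (label, doublet flag, per-class scores).
    """
    marker_sets = marker_sets or DEFAULT_MARKERS
    if any(len(v) == 0 for v in marker_sets.values()) or not marker_sets:
        raise ValueError("every marker set must be non-empty")
    X = em.dense()
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    rows = []
    any_marker = False
    for cl in clusters:
        in_cl = labels == cl
        scores = {}
        for cname, genes in marker_sets.items():
            idx = em.genes.get_indexer(pd.Index(genes))
            idx = idx[idx >= 0]
            if len(idx) == 0:
                scores[cname] = np.nan
                continue
            any_marker = True
            scores[cname] = float(Z[np.ix_(idx, np.where(in_cl)[0])].mean())
        vals = pd.Series(scores)
        if vals.notna().any() and vals.max() > 0:
            label = vals.idxmax()
        else:
            label = "unassigned"
        doublet = bool((vals.dropna() > doublet_z).sum() >= 2)
        rows.append({"cluster": cl, "label": label, "doublet": doublet, **scores})
    if not any_marker:
        warnings.warn("no marker genes found in the matrix; all clusters unassigned")
    return pd.DataFrame(rows).set_index("cluster")
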