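"""Per-age cluster diversity and inter-cluster distinctiveness statistics.

Diversity of a clustered population with frequencies p and pairwise
inter-cluster distances d (scaled to [0, 1]):

* Rao quadratic entropy  sum_ij p_i p_j d_ij
* Shannon index          -sum_i p_i ln p_i
* Simpson index          sum_i p_i^2  (decreases with diversity)

Distinctiveness is measured by the held-out error of a multi-class
gradient-boosted tree classifier and by the mean relative cluster diameter
r_C / d_C in standardized principal-component space.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
import xgboost as xgb


class DiversityIndices(NamedTuple):
    rao: float
    shannon: float
    simpson: float


def diversity_indices(p, D) -> DiversityIndices:
    """Rao, Shannon, and Simpson indices for frequencies ``p``, distances ``D``."""
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum():.10f})")
    if D.shape != (len(p), len(p)):
        raise ValueError("distance matrix shape must match frequency vector")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("D must be symmetric with zero diagonal")
    if D.min() < 0 or D.max() > 1 + 1e-12:
        raise ValueError("distances must lie in [0, 1]")
    rao = float(p @ D @ p)
    nz = p > 0
    shannon = float(-(p[nz] * np.log(p[nz])).sum())
    simpson = float((p**2).sum())
    return DiversityIndices(rao=rao, shannon=shannon, simpson=simpson)


def cluster_distance_matrix(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Correlation distance between cluster centroids, min-max scaled to [0, 1].

    ``X`` is genes x cells (typically restricted to HVGs); the number of genes
    used may vary without materially changing the Rao index.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    cent = np.vstack([np.asarray(X[:, labels == i].mean(axis=1)).ravel() for i in ids])
    if len(ids) == 1:
        return np.zeros((1, 1))
    corr = np.corrcoef(cent)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    hi = D.max()
    if hi > 0:
        D = D / hi
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 1.0)


def classifier_error(
    E: np.ndarray,
    labels: np.ndarray,
    split_frac: float = 0.5,
    seed: int = 0,
    min_cluster_size: int = 4,
    num_boost_round: int = 50,
) -> float:
    """Mean per-cluster held-out misclassification rate.

    A gradient-boosted tree classifier is trained on ``split_frac`` of the
    cells (stratified by cluster) and evaluated on the rest; the per-cluster
    error rates are averaged. Clusters below ``min_cluster_size`` cells are
    excluded with a warning. A single cluster has error 0 by convention.
    """
    E = np.asarray(E, dtype=float)
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    small = ids[counts < min_cluster_size]
    if len(small):
        warnings.warn(f"excluding clusters with < {min_cluster_size} cells: {small.tolist()}")
        keep = ~np.isin(labels, small)
        E, labels = E[keep], labels[keep]
        ids = np.unique(labels)
    if len(ids) <= 1:
        return 0.0
    code = {c: i for i, c in enumerate(ids)}
    y = np.array([code[v] for v in labels])
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(y), dtype=bool)
    for c in range(len(ids)):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        n_tr = max(1, int(round(split_frac * len(idx))))
        train_mask[idx[:n_tr]] = True
    params = {
        "objective": "multi:softprob",
        "eval_metric": "mlogloss",
        "num_class": len(ids),
        "eta": 0.2,
        "max_depth": 6,
        "subsample": 0.6,
        "seed": seed,
        "nthread": 1,
    }
    booster = xgb.train(params, xgb.DMatrix(E[train_mask], label=y[train_mask]), num_boost_round)
    prob = booster.predict(xgb.DMatrix(E[~train_mask]))
    pred = prob.argmax(axis=1)
    y_test = y[~train_mask]
    errors = []
    for c in range(len(ids)):
        mask = y_test == c
        if mask.any():
            errors.append(float((pred[mask] != c).mean()))
    return float(np.mean(errors))


def relative_diameter(X_pcs: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of r_C / d_C in standardized PC coordinates.

    r_C is the median distance of a cluster's cells to its centroid; d_C the
    median distance of those cells to the centroid of the nearest external
    cluster. Lower values indicate better-separated clusters; the ratio is
    invariant to a common rescaling of the coordinates.
    """
    X = np.asarray(X_pcs, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("relative diameter requires at least 2 clusters")
    sd = X.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0, keepdims=True)) / sd
    cents = {i: Z[labels == i].mean(axis=0) for i in ids}
    ratios = []
    for i in ids:
        cells = Z[labels == i]
        r = np.median(np.linalg.norm(cells - cents[i], axis=1))
        others = [j for j in ids if j != i]
        nearest = min(others, key=lambda j: np.linalg.norm(cents[i] - cents[j]))
        d = np.median(np.linalg.norm(cells - cents[nearest], axis=1))
        ratios.append(r / d if d > 0 else np.inf if r > 0 else 0.0)
    return float(np.mean(ratios))


def diversity_report(
    X: np.ndarray, labels: np.ndarray, E: np.ndarray, age=None, seed: int = 0
) -> pd.Series:
    """Bundle the per-age diversity and distinctiveness statistics."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    D = cluster_distance_matrix(X, labels)
    idx = diversity_indices(p, D)
    err = classifier_error(E, labels, seed=seed)
    rd = relative_diameter(E, labels) if len(ids) > 1 else np.nan
    return pd.Series(
        {
            "age": age,
            "n_clusters": len(ids),
            "rao": idx.rao,
            "shannon": idx.shannon,
            "simpson": idx.simpson,
            "classifier_error": err,
            "relative_diameter": rd,
        }
    )
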