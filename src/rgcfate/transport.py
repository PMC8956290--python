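"""Entropic (unbalanced) optimal transport between ages and fate statistics.

Consecutive-age snapshots are coupled by minimizing

    <C, Pi> - eps * H(Pi) + lam1 * KL(row_marginal(Pi) || p)
                          + lam2 * KL(col_marginal(Pi) || q)

where C is the (squared) Euclidean cost in the shared-HVG log-expression
space, H the entropy of the coupling, p the growth-rescaled source
distribution and q the empirical (uniform) target distribution. The entropic
term makes couplings one-to-many, which is what lets the composed maps
express partial fate commitment. The solver runs stabilized log-domain
scaling (Sinkhorn) iterations; in the balanced limit (lam -> inf) the
marginal constraints are enforced exactly.

Long-range couplings are matrix products of consecutive maps; summing a
composed map over terminal clusters and normalizing per source cell yields
the fate matrix f, whose inverse participation ratio 1 / sum_k f_k^2 is the
"potential" (1 = committed, n_types = uninformative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit, logsumexp


@dataclass
class TransportMap:
    """Nonnegative source x target coupling with solver metadata."""

    Pi: np.ndarray
    eps: float | None = None
    lam1: float | None = None
    lam2: float | None = None
    growth: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    cost: str | None = None

    def __post_init__(self) -> None:
        self.Pi = np.asarray(self.Pi, dtype=float)
        if not np.isfinite(self.Pi).all():
            raise ValueError("coupling contains non-finite entries")
        if (self.Pi < 0).any():
            raise ValueError("coupling must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Pi.shape

    @property
    def row_marginal(self) -> np.ndarray:
        return self.Pi.sum(axis=1)

    @property
    def col_marginal(self) -> np.ndarray:
        return self.Pi.sum(axis=0)


def cost_matrix(
    X_i: np.ndarray, X_j: np.ndarray, metric: str = "sqeuclidean", scale: str | None = "median"
) -> np.ndarray:
    """Pairwise transport costs; optionally scaled by the median cost."""
    if metric not in ("sqeuclidean", "euclidean"):
        raise ValueError("metric must be 'sqeuclidean' or 'euclidean'")
    C = cdist(np.asarray(X_i, float), np.asarray(X_j, float), metric=metric)
    if np.isnan(C).any():
        raise ValueError("NaN in cost matrix")
    if scale == "median":
        med = np.median(C)
        if med > 0:
            C = C / med
    elif scale is not None:
        raise ValueError("scale must be 'median' or None")
    return C


def sinkhorn(
    C: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    eps: float,
    lam1: float | None = None,
    lam2: float | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, bool, int]:
    """Stabilized log-domain scaling iterations for (un)balanced entropic OT.

    ``lam1``/``lam2`` of ``None`` (or ``inf``) enforce the corresponding
    marginal exactly (balanced). Returns (coupling, converged, n_iter).
    """
    C = np.asarray(C, float)
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("marginals must be strictly positive")
    phi1 = 1.0 if lam1 is None or np.isinf(lam1) else lam1 / (lam1 + eps)
    phi2 = 1.0 if lam2 is None or np.isinf(lam2) else lam2 / (lam2 + eps)
    log_p = np.log(p)
    log_q = np.log(q)
    f = np.zeros(len(p))
    g = np.zeros(len(q))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_old, g_old = f, g
        # softmin over targets / sources with current duals
        f = phi1 * eps * (log_p - logsumexp((g[None, :] - C) / eps, axis=1))
        g = phi2 * eps * (log_q - logsumexp((f[:, None] - C) / eps, axis=0))
        delta = max(np.abs(f - f_old).max(), np.abs(g - g_old).max())
        if delta < tol:
            converged = True
            break
    Pi = np.exp((f[:, None] + g[None, :] - C) / eps)
    return Pi, converged, it


def solve_coupling(
    X_i: np.ndarray,
    X_j: np.ndarray,
    eps: float = 0.005,
    lam1: float | None = 1.0,
    lam2: float | None = 50.0,
    g: np.ndarray | None = None,
    days_gap: float = 1.0,
    cost: str = "sqeuclidean",
    scale_cost: str | None = "median",
    C: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> TransportMap:
    """Entropic unbalanced OT coupling between two age snapshots.

    The source marginal is the empirical distribution reweighted by the
    per-cell growth factor ``g`` raised to the day gap (then renormalized);
    the target marginal is empirical uniform. Non-convergence is flagged on
    the result, never silent.
    """
    X_i = np.atleast_2d(np.asarray(X_i, float))
    X_j = np.atleast_2d(np.asarray(X_j, float))
    n_i, n_j = X_i.shape[0], X_j.shape[0]
    if C is None:
        C = cost_matrix(X_i, X_j, metric=cost, scale=scale_cost)
    if g is None:
        g = np.ones(n_i)
    g = np.asarray(g, float)
    if (g <= 0).any():
        raise ValueError("growth factors must be strictly positive")
    p = g**days_gap
    p = p / p.sum()
    q = np.full(n_j, 1.0 / n_j)
    Pi, converged, it = sinkhorn(C, p, q, eps, lam1, lam2, max_iter=max_iter, tol=tol)
    if not converged:
        warnings.warn(f"Sinkhorn did not reach tol={tol} in {max_iter} iterations")
    return TransportMap(
        Pi=Pi, eps=eps, lam1=lam1, lam2=lam2, growth=g,
        converged=converged, n_iter=it, cost=cost,
    )


def estimate_growth(
    X_i: np.ndarray,
    X_j: np.ndarray,
    proliferation_scores: np.ndarray | None = None,
    apoptosis_scores: np.ndarray | None = None,
    growth_iters: int = 3,
    days_gap: float = 1.0,
    g_min: float = 0.2,
    g_max: float = 1.8,
    **solve_kwargs,
) -> np.ndarray:
    """Iterative growth estimation within the unbalanced OT framework.

    The growth vector is initialized by a logistic map of the
    proliferation-minus-apoptosis score (neutral score -> growth 1, floor
    ``g_min``); after each unbalanced solve, g is updated to the realized
    per-cell source-mass change, and the solve repeats ``growth_iters``
    times. With no marker scores the initialization is g = 1 everywhere.
    """
    n_i = np.atleast_2d(X_i).shape[0]
    if proliferation_scores is None and apoptosis_scores is None:
        g = np.ones(n_i)
    else:
        score = np.zeros(n_i)
        if proliferation_scores is not None:
            score = score + np.asarray(proliferation_scores, float)
        if apoptosis_scores is not None:
            score = score - np.asarray(apoptosis_scores, float)
        # logistic map with g(0) = 1 and floor g_min
        g = g_min + (g_max - g_min) * expit(
            score + np.log((1.0 - g_min) / (g_max - 1.0))
        )
    for _ in range(int(growth_iters)):
        tmap = solve_coupling(X_i, X_j, g=g, days_gap=days_gap, **solve_kwargs)
        realized = tmap.row_marginal * n_i  # relative mass change per source cell
        g = np.clip(realized ** (1.0 / days_gap), g_min, None)
    return g


def compose(maps: list[TransportMap | np.ndarray]) -> TransportMap:
    """Long-range coupling as the ordered matrix product of consecutive maps."""
    if not maps:
        raise ValueError("need at least one map")
    mats = [m.Pi if isinstance(m, TransportMap) else np.asarray(m, float) for m in maps]
    for a, b in zip(mats, mats[1:]):
        if a.shape[1] != b.shape[0]:
            raise ValueError(f"incompatible shapes {a.shape} x {b.shape}")
    out = mats[0]
    for m in mats[1:]:
        out = out @ m
    return TransportMap(Pi=out)


@dataclass
class FateMatrix:
    """Cells x terminal-clusters fate probabilities, rows summing to 1."""

    F: np.ndarray
    cluster_ids: np.ndarray
    source_age: float | str | None = None
    terminal_age: float | str | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, float)
        if (self.F < 0).any():
            raise ValueError("fate probabilities must be nonnegative")
        if np.abs(self.F.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("fate rows must sum to 1 within 1e-9")

    @property
    def n_types(self) -> int:
        return self.F.shape[1]


def fate_vectors(
    Pi_long: TransportMap | np.ndarray,
    terminal_labels: np.ndarray,
    source_age=None,
    terminal_age=None,
) -> FateMatrix:
    """Sum a composed coupling over terminal clusters; normalize per cell.

    f(beta; u) = sum_{v in C_beta} Pi(u, v), normalized so each cell's fate
    vector sums to 1. Cells with zero transported mass fall back to the
    uniform fate with a warning.
    """
    Pi = Pi_long.Pi if isinstance(Pi_long, TransportMap) else np.asarray(Pi_long, float)
    terminal_labels = np.asarray(terminal_labels)
    ids = np.unique(terminal_labels)
    F = np.column_stack([Pi[:, terminal_labels == c].sum(axis=1) for c in ids])
    tot = F.sum(axis=1)
    zero = tot <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero transported mass; uniform fallback")
        F[zero] = 1.0 / len(ids)
        tot[zero] = 1.0
    F = F / tot[:, None]
    return FateMatrix(F=F, cluster_ids=ids, source_age=source_age, terminal_age=terminal_age)


def ancestors_descendants(
    Pi: TransportMap | np.ndarray,
    cluster_mask: np.ndarray,
    direction: str = "ancestors",
) -> np.ndarray:
    """Normalized ancestor / descendant distribution of a cluster.

    ``Pi`` couples an earlier snapshot (rows) to a later one (columns);
    ``cluster_mask`` selects the cluster's cells among the columns
    (ancestors) or rows (descendants). The returned vector is a probability
    distribution over cells of the other snapshot.
    """
    P = Pi.Pi if isinstance(Pi, TransportMap) else np.asarray(Pi, float)
    mask = np.asarray(cluster_mask, bool)
    if direction == "ancestors":
        if len(mask) != P.shape[1]:
            raise ValueError("mask must select target (later) cells")
        v = P[:, mask].sum(axis=1)
    elif direction == "descendants":
        if len(mask) != P.shape[0]:
            raise ValueError("mask must select source (earlier) cells")
        v = P[mask, :].sum(axis=0)
    else:
        raise ValueError("direction must be 'ancestors' or 'descendants'")
    tot = v.sum()
    if tot <= 0:
        raise ValueError("cluster carries no transported mass")
    return v / tot


def potential(f: np.ndarray) -> np.ndarray | float:
    """Inverse participation ratio P = 1 / sum_k f_k^2 of fate vectors.

    Ranges from 1 (point mass: fully committed) to the number of terminal
    types (uniform: maximally multipotential). Accepts a single vector or a
    cells x types matrix.
    """
    f = np.asarray(f, float)
    if f.ndim == 1:
        return float(1.0 / (f**2).sum())
    return 1.0 / (f**2).sum(axis=1)
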