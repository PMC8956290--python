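"""Fate couplings, randomization null, decay fits, and specification times.

The fate coupling C(alpha, beta; t) between two terminal types at an age t is
the Pearson correlation of their fate probabilities across the cells of that
age: high coupling means the two types still share precursors. Couplings
decay with age; each pair's decay is fit by a logistic 1 / (1 + exp(b0 +
b1 t)). A type's "localization" measures how concentrated its biased
precursors are among the age's clusters, and the age at which a logistic fit
of localization crosses 0.95 * (1 - 1/N(t)) is the type's specification time
tau_sp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from .transport import FateMatrix


def _fate_array(F) -> np.ndarray:
    return F.F if isinstance(F, FateMatrix) else np.asarray(F, float)


def coupling_matrix(F) -> np.ndarray:
    """Pairwise Pearson correlations of fate-probability columns.

    Types whose fate probability has zero variance across cells get NaN
    couplings (reported as missing, not as zero).
    """
    X = _fate_array(F)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(np.asarray(C, float))
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, np.where(sd > 0, 1.0, np.nan))
    return C


@dataclass
class CouplingNull:
    """Randomization null for fate couplings."""

    max_abs_per_perm: np.ndarray
    max_abs: float
    pair_q99: np.ndarray  # per-pair 99th percentile of |C| under the null


def coupling_null(F, n_perm: int = 100, seed: int = 0) -> CouplingNull:
    """Null couplings from permuting each cell's fate vector across types.

    Each permutation shuffles every cell's fate probabilities independently
    across type labels (preserving each cell's value multiset), recomputes
    all pairwise couplings, and records the maximum absolute value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _fate_array(F)
    rng = np.random.default_rng(seed)
    n_cells, n_types = X.shape
    iu = np.triu_indices(n_types, k=1)
    maxima = np.empty(n_perm)
    abs_vals = np.empty((n_perm, len(iu[0])))
    for p in range(n_perm):
        keys = rng.random((n_cells, n_types))
        perm = np.argsort(keys, axis=1)
        Xp = np.take_along_axis(X, perm, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(Xp, rowvar=False)
        vals = np.abs(C[iu])
        vals = vals[np.isfinite(vals)] if np.isnan(vals).any() else vals
        abs_full = np.abs(C[iu])
        abs_full[~np.isfinite(abs_full)] = 0.0
        abs_vals[p] = abs_full
        maxima[p] = vals.max() if len(vals) else 0.0
    return CouplingNull(
        max_abs_per_perm=maxima,
        max_abs=float(maxima.max()),
        pair_q99=np.quantile(abs_vals, 0.99, axis=0),
    )


def export_network(
    C: np.ndarray,
    threshold: float = 0.2,
    type_names=None,
    layout_seed: int | None = None,
    path=None,
) -> pd.DataFrame:
    """Edge list of couplings above ``threshold`` (+ optional layout).

    The optional force-directed layout is computed once (seeded) so node
    positions can be reused across ages when edges are redrawn.
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    names = list(type_names) if type_names is not None else list(range(n))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            w = C[i, j]
            if np.isfinite(w) and w > threshold:
                rows.append({"type_a": names[i], "type_b": names[j], "weight": float(w)})
    edges = pd.DataFrame(rows, columns=["type_a", "type_b", "weight"])
    if layout_seed is not None:
        import random

        import igraph

        igraph.set_random_number_generator(random.Random(layout_seed))
        g = igraph.Graph(
            n=n,
            edges=[(names.index(r.type_a), names.index(r.type_b)) for r in edges.itertuples()],
        )
        lay = g.layout_fruchterman_reingold(
            weights=edges["weight"].tolist() if len(edges) else None
        )
        edges.attrs["layout"] = pd.DataFrame(
            np.asarray(lay.coords) if len(lay) else np.zeros((n, 2)),
            index=names, columns=["x", "y"],
        )
    if path is not None:
        edges.to_csv(path, sep="\t", index=False)
    return edges


def _logistic_decay(t, b0, b1):
    return scipy.special.expit(-(b0 + b1 * t))


def fit_coupling_decay(
    C_series: np.ndarray,
    t_grid=(0.0, 1.0, 3.0, 6.0, 11.0),
    terminal_t: float = 36.0,
    include_threshold: float = 0.2,
    n_restarts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair logistic decay fits C(t) = 1 / (1 + exp(b0 + b1 t)).

    ``C_series`` is ages x pairs (or ages x types x types, flattened over the
    upper triangle). Each included pair is fit over the observed ages plus an
    anchor C = 0 at ``terminal_t``; pairs whose earliest-age coupling does not
    exceed ``include_threshold`` are skipped. Near-constant series are
    flagged as degenerate. Fitting uses Levenberg-Marquardt least squares
    with seeded random restarts.
    """
    C_series = np.asarray(C_series, float)
    if C_series.ndim == 3:
        iu = np.triu_indices(C_series.shape[1], k=1)
        pair_idx = list(zip(iu[0].tolist(), iu[1].tolist()))
        C_series = C_series[:, iu[0], iu[1]]
    else:
        pair_idx = [(i, i) for i in range(C_series.shape[1])]
    t_grid = np.asarray(t_grid, float)
    if C_series.shape[0] != len(t_grid):
        raise ValueError("C_series rows must match t_grid")
    rng = np.random.default_rng(seed)
    t_all = np.append(t_grid, terminal_t)
    rows = []
    for k in range(C_series.shape[1]):
        series = C_series[:, k]
        if np.isnan(series).all() or not series[0] > include_threshold:
            continue
        y = np.append(np.nan_to_num(np.clip(series, 0.0, 1.0)), 0.0)
        best = None
        starts = [(0.0, 0.3)] + [tuple(rng.normal([0.0, 0.3], [2.0, 0.3])) for _ in range(n_restarts)]
        for p0 in starts:
            try:
                popt, _ = scipy.optimize.curve_fit(
                    _logistic_decay, t_all, y, p0=p0, method="lm", maxfev=5000
                )
            except RuntimeError:
                continue
            rss = float(((_logistic_decay(t_all, *popt) - y) ** 2).sum())
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            warnings.warn(f"decay fit failed for pair {pair_idx[k]}")
            continue
        rss, (b0, b1) = best
        rows.append(
            {
                "type_a": pair_idx[k][0],
                "type_b": pair_idx[k][1],
                "beta0": float(b0),
                "beta1": float(b1),
                "rmse": float(np.sqrt(rss / len(t_all))),
                "degenerate": bool(abs(b1) < 1e-3),
            }
        )
    return pd.DataFrame(rows, columns=["type_a", "type_b", "beta0", "beta1", "rmse", "degenerate"])


def localization(F, labels: np.ndarray, type_beta: int) -> float:
    """Cluster-space localization of a type's biased precursors, in [0, 1-1/N].

    The precursor set of a type is the cells whose fate argmax is that type
    (ties break to the lowest type index); with p_k the fraction of those
    cells in cluster k and N the number of clusters,
    localization = 1 - (1 / sum_k p_k^2) / N. Returns NaN when the precursor
    set is empty.
    """
    X = _fate_array(F)
    labels = np.asarray(labels)
    assign = X.argmax(axis=1)
    prec = assign == type_beta
    if not prec.any():
        return float("nan")
    ids = np.unique(labels)
    N = len(ids)
    frac = np.array([(labels[prec] == c).mean() for c in ids])
    participation = 1.0 / float((frac**2).sum())
    return 1.0 - participation / N


def _logistic_rise(t, g0, g1):
    return scipy.special.expit(g0 + g1 * t)


@dataclass
class SpecificationFit:
    tau_sp: float
    censored: bool
    gamma0: float
    gamma1: float


def specification_time(
    localization_series,
    N_series,
    t_grid,
    t_max: float = 36.0,
    threshold_factor: float = 0.95,
    n_restarts: int = 10,
    seed: int = 0,
) -> SpecificationFit:
    """Logistic fit of localization vs age; earliest threshold crossing.

    The fitted curve exp(g0 + g1 t) / (1 + exp(g0 + g1 t)) is compared with
    the moving threshold y(t) = ``threshold_factor`` * (1 - 1/N(t)), where
    N(t) holds the last observed cluster count between sampled ages (so the
    threshold curve bends as cluster number grows). tau_sp is the smallest
    t in [t0, t_max] with fit >= y(t); if no crossing occurs the estimate is
    censored at ``t_max``.
    """
    t_grid = np.asarray(t_grid, float)
    loc = np.asarray(localization_series, float)
    N_series = np.asarray(N_series, float)
    usable = np.isfinite(loc)
    if usable.sum() < 3:
        raise ValueError("need at least 3 usable localization points")
    t_fit, y_fit = t_grid[usable], np.clip(loc[usable], 0.0, 1.0)
    rng = np.random.default_rng(seed)
    best = None
    starts = [(-1.0, 0.3)] + [
        (float(a), abs(float(b)))
        for a, b in (rng.normal([0.0, 0.3], [2.0, 0.3]) for _ in range(n_restarts))
    ]
    for p0 in starts:
        try:
            # localization cannot decrease as restriction proceeds: g1 >= 0
            popt, _ = scipy.optimize.curve_fit(
                _logistic_rise, t_fit, y_fit, p0=p0,
                bounds=([-np.inf, 0.0], [np.inf, np.inf]), maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(((_logistic_rise(t_fit, *popt) - y_fit) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("logistic localization fit failed from all starts")
    g0, g1 = best[1]

    def n_of_t(t):
        """Step interpolation: hold the last observed cluster count."""
        idx = np.searchsorted(t_grid, t, side="right") - 1
        return N_series[np.clip(idx, 0, len(N_series) - 1)]

    ts = np.arange(t_grid[0], t_max + 1e-9, 0.01)
    fit_vals = _logistic_rise(ts, g0, g1)
    thresh = threshold_factor * (1.0 - 1.0 / n_of_t(ts))
    crossing = np.where(fit_vals >= thresh)[0]
    if len(crossing):
        return SpecificationFit(float(ts[crossing[0]]), False, float(g0), float(g1))
    return SpecificationFit(float(t_max), True, float(g0), float(g1))


def subclass_coupling_test(C: np.ndarray, subclass_labels) -> dict:
    """Within- vs between-subclass coupling comparison (two-sided t-test)."""
    C = np.asarray(C, float)
    labels = np.asarray(subclass_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 subclasses")
    iu = np.triu_indices(C.shape[0], k=1)
    vals = C[iu]
    same = labels[iu[0]] == labels[iu[1]]
    finite = np.isfinite(vals)
    within = vals[same & finite]
    between = vals[~same & finite]
    if len(within) == 0 or len(between) == 0:
        raise ValueError("both within- and between-subclass pair sets must be non-empty")
    stat, pval = scipy.stats.ttest_ind(within, between, equal_var=False)
    summarize = lambda v: {
        "median": float(np.median(v)),
        "iqr": float(np.subtract(*np.percentile(v, [75, 25]))),
        "n": int(len(v)),
    }
    return {
        "within": summarize(within),
        "between": summarize(between),
        "t_stat": float(stat),
        "p_value": float(pval),
    }
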