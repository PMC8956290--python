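"""Supervised cross-age cluster correspondence and its summary metrics.

A gradient-boosted tree classifier trained on an older ("reference") age
assigns reference labels to cells of a younger ("test") age; the resulting
contingency table N_ij (reference assignment i x test cluster j) is
summarized by the adjusted Rand index (ARI), the normalized conditional
entropy (NCE), and a per-reference-label occupancy fraction (OF).

The training protocol: z-score features; train classifiers on both atlases
on 60% of each cluster (capped at 300 cells); retrain with upsampling if any
cluster's held-out error exceeds 10%; intersect the two top-500
information-gain feature sets; retrain the reference classifier on the
intersection; assign each test cell by softmax argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import comb


@dataclass
class ConfusionTable:
    """Contingency counts N_ij with reference rows and test columns."""

    N: np.ndarray
    ref_ids: np.ndarray | None = None
    test_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if self.N.ndim != 2 or (self.N < 0).any():
            raise ValueError("N must be a nonnegative 2-D count table")
        if self.ref_ids is None:
            self.ref_ids = np.arange(1, self.N.shape[0] + 1)
        if self.test_ids is None:
            self.test_ids = np.arange(1, self.N.shape[1] + 1)

    @property
    def a(self) -> np.ndarray:  # reference marginals
        return self.N.sum(axis=1)

    @property
    def b(self) -> np.ndarray:  # test marginals
        return self.N.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.N.sum())

    @property
    def q(self) -> np.ndarray:
        return self.N / self.total


def ari(table: ConfusionTable | np.ndarray) -> float:
    """Adjusted Rand index in pair-count form.

    1 for a one-to-one correspondence, 0 in expectation for random
    association (a product-of-marginals table evaluates to exactly 0).
    """
    N = table.N if isinstance(table, ConfusionTable) else np.asarray(table, float)
    n = N.sum()
    sum_cells = comb(N, 2).sum()
    sum_a = comb(N.sum(axis=1), 2).sum()
    sum_b = comb(N.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 0.0
    return float((sum_cells - expected) / (max_index - expected))


def nce(table: ConfusionTable | np.ndarray) -> float:
    """Normalized conditional entropy H(test | reference) / H(test).

    0 for a fully specific (diagonal-like) mapping; 1 when the joint equals
    the product of the marginals (no information). Natural logarithms are
    used throughout; the ratio is invariant to the base.
    """
    N = table.N if isinstance(table, ConfusionTable) else np.asarray(table, float)
    q = N / N.sum()
    qi = q.sum(axis=1, keepdims=True)
    qj = q.sum(axis=0)
    nzj = qj > 0
    h_test = float(-(qj[nzj] * np.log(qj[nzj])).sum())
    if h_test == 0:
        raise ValueError("test partition has a single cluster; NCE undefined")
    nz = q > 0
    ce = float(-(q[nz] * np.log((q / np.where(qi > 0, qi, 1.0))[nz])).sum())
    return ce / h_test


def occupancy_fraction(table: ConfusionTable | np.ndarray, i: int) -> float:
    """Occupancy fraction of reference row ``i`` (0-based) over test clusters.

    The bracketed participation number 1 / sum_j (q_ij / q_i.)^2 ranges from
    1 (row concentrated in one test cluster) to t (spread uniformly); OF
    divides it by t, the number of test clusters.
    """
    N = table.N if isinstance(table, ConfusionTable) else np.asarray(table, float)
    t = N.shape[1]
    row = N[i]
    tot = row.sum()
    if tot == 0:
        raise ValueError(f"reference row {i} is empty")
    frac = row / tot
    occupation = 1.0 / float((frac**2).sum())
    return occupation / t


def _train_xgb(E, y, n_class, seed, num_boost_round=60):
    params = {
        "objective": "multi:softprob",
        "eval_metric": "mlogloss",
        "num_class": n_class,
        "eta": 0.2,
        "max_depth": 6,
        "subsample": 0.6,
        "seed": seed,
        "nthread": 1,
    }
    feat_names = [f"f{j}" for j in range(E.shape[1])]
    dtrain = xgb.DMatrix(E, label=y, feature_names=feat_names)
    return xgb.train(params, dtrain, num_boost_round)


def _split_train(y, frac, cap, rng):
    train_idx, valid_idx = [], []
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        n_tr = min(max(1, int(round(frac * len(idx)))), cap)
        train_idx.extend(idx[:n_tr])
        valid_idx.extend(idx[n_tr:])
    return np.array(train_idx), np.array(valid_idx)


def _cluster_errors(booster, E, y, n_class):
    feat_names = [f"f{j}" for j in range(E.shape[1])]
    prob = booster.predict(xgb.DMatrix(E, feature_names=feat_names))
    pred = prob.argmax(axis=1) if prob.ndim == 2 else np.zeros(len(prob), dtype=int)
    errs = {}
    for c in range(n_class):
        mask = y == c
        if mask.any():
            errs[c] = float((pred[mask] != c).mean())
    return errs


def _fit_with_retrain(E, y, seed, frac, cap, err_thresh, rng, max_rounds=3):
    """Train, validate per cluster, upsample high-error clusters, retrain."""
    n_class = int(y.max()) + 1
    if n_class == 1:  # degenerate single-cluster atlas
        return None
    tr, va = _split_train(y, frac, cap, rng)
    booster = _train_xgb(E[tr], y[tr], n_class, seed)
    for _ in range(max_rounds):
        if len(va) == 0:
            break
        errs = _cluster_errors(booster, E[va], y[va], n_class)
        bad = [c for c, e in errs.items() if e > err_thresh]
        if not bad:
            break
        extra = []
        for c in bad:
            pool = tr[y[tr] == c]
            # bootstrap-duplicate training cells up to twice the cap
            n_extra = min(len(pool), 2 * cap - len(pool))
            if n_extra > 0:
                extra.append(rng.choice(pool, size=n_extra, replace=True))
        if not extra:
            break
        tr_up = np.concatenate([tr, *extra])
        booster = _train_xgb(E[tr_up], y[tr_up], n_class, seed)
    return booster


def _top_features(booster, n_top):
    if booster is None:
        return None
    gain = booster.get_score(importance_type="gain")
    order = sorted(gain, key=gain.get, reverse=True)[:n_top]
    return {int(name[1:]) for name in order}


def map_clusters(
    X_ref: np.ndarray,
    labels_ref: np.ndarray,
    X_test: np.ndarray,
    labels_test: np.ndarray,
    seed: int = 0,
    train_frac: float = 0.6,
    max_cells: int = 300,
    err_thresh: float = 0.10,
    n_top_features: int = 500,
    min_common_features: int = 50,
) -> ConfusionTable:
    """Full cross-age mapping protocol; returns the confusion table N_ij.

    ``X_ref`` and ``X_test`` are cells x features over the *same* ordered
    feature set (the common HVGs of the two ages; at least
    ``min_common_features`` columns).
    """
    X_ref = np.asarray(X_ref, float)
    X_test = np.asarray(X_test, float)
    if X_ref.shape[1] != X_test.shape[1]:
        raise ValueError("reference and test must share an aligned feature set")
    if X_ref.shape[1] < min_common_features:
        raise ValueError(
            f"only {X_ref.shape[1]} common features; need >= {min_common_features}"
        )
    rng = np.random.default_rng(seed)

    def zscore(X):
        mu = X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    Zr, Zt = zscore(X_ref), zscore(X_test)
    ref_ids = np.unique(labels_ref)
    test_ids = np.unique(labels_test)
    small = [int(c) for c in ref_ids if (labels_ref == c).sum() < 5]
    if small:
        warnings.warn(f"reference clusters with < 5 cells included: {small}")
    y_ref = np.searchsorted(ref_ids, labels_ref)
    y_test = np.searchsorted(test_ids, labels_test)

    clf_ref = _fit_with_retrain(Zr, y_ref, seed, train_frac, max_cells, err_thresh, rng)
    clf_test = _fit_with_retrain(Zt, y_test, seed + 1, train_frac, max_cells, err_thresh, rng)

    top_sets = [s for s in (_top_features(clf_ref, n_top_features),
                            _top_features(clf_test, n_top_features)) if s is not None]
    if top_sets:
        common = set.intersection(*top_sets)
    else:  # both atlases degenerate: keep all features
        common = set(range(Zr.shape[1]))
    if not common:
        raise ValueError("empty intersection of discriminatory feature sets")
    cols = sorted(common)

    if len(ref_ids) == 1:
        assigned = np.zeros(Zt.shape[0], dtype=int)
    else:
        final = _train_xgb(Zr[:, cols], y_ref, len(ref_ids), seed)
        feat_names = [f"f{j}" for j in range(len(cols))]
        prob = final.predict(xgb.DMatrix(Zt[:, cols], feature_names=feat_names))
        assigned = prob.argmax(axis=1)  # argmax ties resolve to the lowest index

    N = np.zeros((len(ref_ids), len(test_ids)))
    for i, j in zip(assigned, y_test):
        N[i, j] += 1
    return ConfusionTable(N=N, ref_ids=ref_ids, test_ids=test_ids)
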