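"""Self-contained recovery benchmarks on synthetic data with planted truth.

Each function simulates a dataset under the package's standard study
conditions, runs the relevant estimators, and returns the measured recovery
statistics. They are used by the test suite, the acceptance script, and the
example scripts, so the measured numbers always come from one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from . import fates as ft
from . import pipeline
from . import synthdata as sd
from . import transport as tp
from .config import RunConfig

#: ages (days) of the standard six-snapshot time course
STANDARD_AGES = (0.0, 1.0, 3.0, 6.0, 11.0, 20.0)
#: denser grid used for specification-time recovery (better temporal support)
DENSE_AGES = (0, 1, 2, 3, 4, 6, 8, 11, 14, 17, 20)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def desk_config(**overrides) -> RunConfig:
    """Pipeline defaults adapted to desk-scale synthetic matrices."""
    base = dict(min_genes_per_cell=50, min_cells_per_gene=3)
    base.update(overrides)
    return RunConfig(**base)


def run_standard_scenario(seed: int, n_cells_per_age: int = 600, n_types: int = 12):
    """Full count-level pipeline on the standard time course.

    Returns ``(truth, results)`` where results is the :func:`pipeline.run_all`
    dict (clusters, diversity, cross-age metrics, transport, fates).
    """
    truth, cm = sd.simulate_dataset(
        n_types=n_types, n_subclasses=4, n_cells_per_age=n_cells_per_age,
        n_genes=800, seed=_sub_seed(seed, 1),
    )
    res = pipeline.run_all(
        cm, desk_config(), seed=_sub_seed(seed, 2),
        subclass_labels=truth.tree.subclass_labels,
    )
    return truth, res


def run_laterality_scenario(seed: int, n_cells_per_age: int = 600, n_types: int = 12):
    """Laterality scenario: sharply determined ipsi lineage, calls propagated.

    The ipsi clade is a small set of early-specifying types (laterality is
    determined at the first sampled age in the real system, so the scenario
    uses strong restriction, sharpness 1.5). Returns ``(truth, results,
    ipsi_mass_fraction)`` where the fraction is the share of propagated
    I-cell mass arriving at the planted ipsi-lineage terminal types.
    """
    truth, cm = sd.simulate_dataset(
        n_types=n_types, n_subclasses=4, n_cells_per_age=n_cells_per_age,
        n_genes=800, sharpness=1.5, with_laterality=True, seed=_sub_seed(seed, 3),
    )
    res = pipeline.run_all(cm, desk_config(), seed=_sub_seed(seed, 4), with_laterality=True)
    frac = ipsi_mass_in_planted_clade(truth, res)
    return truth, res, frac


def ipsi_mass_in_planted_clade(truth, res) -> float:
    """Share of propagated I-cell mass landing in the planted ipsi types."""
    calls = res["laterality"]["calls"]
    ages = sorted(res["partitions"])
    term = ages[-1]
    term_labels = res["partitions"][term].labels
    term_types = truth.cells.loc[truth.cells["age"] == term, "true_type"].to_numpy()
    cluster_to_type = pd.crosstab(term_labels, term_types).idxmax(axis=1)
    push = calls.i_mask.astype(float)
    for a, b in zip(ages[:-1], ages[1:]):
        push = push @ res["maps"][(a, b)].Pi
    mass = (
        pd.Series(push)
        .groupby(term_labels)
        .sum()
        .rename(index=dict(cluster_to_type))
        .groupby(level=0)
        .sum()
    )
    return float(mass.reindex(list(truth.ipsi_types)).fillna(0).sum() / mass.sum())


def specification_recovery(
    seed: int,
    n_types: int = 16,
    n_cells: int = 2000,
    noise: float = 0.5,
    age_grid=DENSE_AGES,
):
    """Estimator-level tau_sp recovery on planted fates with estimator noise.

    Planted fate matrices receive multiplicative log-normal noise; the
    localization + logistic-fit estimator runs against the planted partitions
    (committed cells by type, uncommitted by lineage state x micro-state).
    Returns ``(planted_decouple_times, inferred_tau_sp, spearman_rho)``.
    """
    rng = np.random.default_rng(_sub_seed(seed, 5))
    tree = sd.make_fate_tree(n_types, 4, age_grid, seed=_sub_seed(seed, 6))
    truth = sd.simulate_fates(tree, n_cells, sharpness=0.5, seed=_sub_seed(seed, 7))
    part = truth.planted_partition()
    ages = sorted(truth.cells["age"].unique())
    loc = np.full((len(ages), n_types), np.nan)
    n_series = []
    for i, a in enumerate(ages):
        m = (truth.cells["age"] == a).to_numpy()
        F = truth.fates[m] * np.exp(rng.normal(0, noise, size=(int(m.sum()), n_types)))
        F = F / F.sum(axis=1, keepdims=True)
        labels = part[m]
        n_series.append(len(np.unique(labels)))
        for b in range(n_types):
            loc[i, b] = ft.localization(F, labels, b)
    taus = np.array(
        [ft.specification_time(loc[:, b], n_series, ages).tau_sp for b in range(n_types)]
    )
    planted = np.array([tree.decouple_time_of_type(b) for b in range(n_types)])
    rho = float(scipy.stats.spearmanr(planted, taus).statistic)
    return planted, taus, rho


def subclass_coupling_recovery(seed: int, n_types: int = 16, n_cells: int = 2000, noise: float = 0.5):
    """Within- vs between-subclass coupling contrast on planted early fates."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    tree = sd.make_fate_tree(n_types, 4, STANDARD_AGES, seed=_sub_seed(seed, 9))
    truth = sd.simulate_fates(tree, n_cells, sharpness=0.5, seed=_sub_seed(seed, 10))
    m = (truth.cells["age"] == STANDARD_AGES[0]).to_numpy()
    F = truth.fates[m] * np.exp(rng.normal(0, noise, size=(int(m.sum()), n_types)))
    F = F / F.sum(axis=1, keepdims=True)
    C = ft.coupling_matrix(F)
    return ft.subclass_coupling_test(C, tree.subclass_labels)


def decay_recovery(seed: int, beta0: float = -2.0, beta1: float = 0.5, sigma: float = 0.01):
    """Logistic coupling-decay parameter recovery at stated noise."""
    rng = np.random.default_rng(_sub_seed(seed, 11))
    t_grid = np.array([0.0, 1.0, 3.0, 6.0, 11.0])
    series = 1.0 / (1.0 + np.exp(beta0 + beta1 * t_grid)) + rng.normal(0, sigma, len(t_grid))
    fits = ft.fit_coupling_decay(
        series[:, None], t_grid, include_threshold=0.2, seed=_sub_seed(seed, 12)
    )
    row = fits.iloc[0]
    return {
        "beta0": float(row["beta0"]),
        "beta1": float(row["beta1"]),
        "rel_err_beta0": abs(row["beta0"] - beta0) / abs(beta0),
        "rel_err_beta1": abs(row["beta1"] - beta1) / abs(beta1),
    }


def coupling_null_max(seed: int, n_cells: int = 5000, n_types: int = 45, n_perm: int = 100):
    """Maximum |coupling| under the within-cell randomization null."""
    tree = sd.make_fate_tree(n_types, 8, STANDARD_AGES, seed=_sub_seed(seed, 13))
    truth = sd.simulate_fates(
        tree, n_cells, age_grid=(STANDARD_AGES[0], STANDARD_AGES[-1]),
        sharpness=0.5, seed=_sub_seed(seed, 14),
    )
    m = (truth.cells["age"] == STANDARD_AGES[0]).to_numpy()
    rng = np.random.default_rng(_sub_seed(seed, 15))
    F = truth.fates[m] * np.exp(rng.normal(0, 0.5, size=(int(m.sum()), n_types)))
    F = F / F.sum(axis=1, keepdims=True)
    null = ft.coupling_null(F, n_perm=n_perm, seed=_sub_seed(seed, 16))
    return null


def ot_oracle_gap(seed: int, sizes=(3, 4, 5, 6)):
    """Entropic-vs-exact-LP cost gap on small balanced problems.

    Returns the maximum relative excess of the entropic transport cost over
    the exact linear-program optimum, and the deviation from the
    product-of-marginals coupling in the large-epsilon limit.
    """
    from scipy.optimize import linprog

    rng = np.random.default_rng(_sub_seed(seed, 17))
    worst_gap = 0.0
    for n in sizes:
        C = rng.random((n, n))
        p = np.full(n, 1.0 / n)
        q = np.full(n, 1.0 / n)
        A_eq, b_eq = [], []
        for i in range(n):
            row = np.zeros((n, n))
            row[i] = 1
            A_eq.append(row.ravel())
            b_eq.append(p[i])
        for j in range(n):
            col = np.zeros((n, n))
            col[:, j] = 1
            A_eq.append(col.ravel())
            b_eq.append(q[j])
        lp = linprog(C.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=(0, None))
        Pi, _, _ = tp.sinkhorn(C, p, q, eps=1e-3, max_iter=20000)
        gap = ((Pi * C).sum() - lp.fun) / lp.fun
        worst_gap = max(worst_gap, float(gap))
    # maximum-entropy limit
    C = rng.random((5, 5))
    p = np.full(5, 0.2)
    q = np.full(5, 0.2)
    Pi, _, _ = tp.sinkhorn(C, p, q, eps=1e3 * float(np.median(C)))
    outer_dev = float(np.abs(Pi - np.outer(p, q)).max())
    return worst_gap, outer_dev
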