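"""Fate couplings, randomization null, decay fits, localization, tau_sp."""

import numpy as np
import pytest
import scipy.stats

from rgcfate import fates as ft
from rgcfate import synthdata as sd


class TestCouplingMatrix:
    def test_identical_columns_fully_coupled(self, rng):
        x = rng.random(50)
        F = np.column_stack([x, x, rng.random(50)])
        C = ft.coupling_matrix(F)
        assert C[0, 1] == pytest.approx(1.0)

    def test_complementary_columns_anticorrelated(self, rng):
        x = rng.random(40)
        F = np.column_stack([x, 1.0 - x])
        C = ft.coupling_matrix(F)
        assert C[0, 1] == pytest.approx(-1.0)

    def test_hand_worked_four_cell_pearson(self):
        F = np.array([[0.6, 0.4], [0.5, 0.5], [0.2, 0.8], [0.7, 0.3]])
        C = ft.coupling_matrix(F)
        expected = scipy.stats.pearsonr(F[:, 0], F[:, 1]).statistic
        assert C[0, 1] == pytest.approx(expected)

    def test_zero_variance_reported_missing(self, rng):
        F = np.column_stack([np.full(30, 0.5), rng.random(30)])
        C = ft.coupling_matrix(F)
        assert np.isnan(C[0, 1]) and np.isnan(C[0, 0])
        assert C[1, 1] == 1.0

    def test_invariant_under_cell_permutation(self, rng):
        F = rng.dirichlet(np.ones(6), size=100)
        C1 = ft.coupling_matrix(F)
        C2 = ft.coupling_matrix(F[rng.permutation(100)])
        np.testing.assert_allclose(C1, C2, atol=1e-12)


class TestCouplingNull:
    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.coupling_null(rng.dirichlet(np.ones(5), size=50), n_perm=0)

    def test_reproducible_with_seed(self, rng):
        F = rng.dirichlet(np.ones(8), size=200)
        a = ft.coupling_null(F, n_perm=10, seed=4)
        b = ft.coupling_null(F, n_perm=10, seed=4)
        np.testing.assert_array_equal(a.max_abs_per_perm, b.max_abs_per_perm)

    def test_null_max_stays_small(self, rng):
        # within-cell randomization destroys structure: couplings stay < 0.2
        F = rng.dirichlet(np.ones(20), size=1000)
        null = ft.coupling_null(F, n_perm=20, seed=0)
        assert null.max_abs < 0.2


class TestExportNetwork:
    def test_all_below_threshold_empty(self):
        C = np.full((4, 4), 0.1)
        np.fill_diagonal(C, 1.0)
        edges = ft.export_network(C, threshold=0.2)
        assert len(edges) == 0

    def test_zero_threshold_complete_graph(self, rng):
        n = 5
        C = np.abs(rng.random((n, n))) / 2 + 0.01
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        edges = ft.export_network(C, threshold=0.0)
        assert len(edges) == n * (n - 1) // 2

    def test_written_edge_list_round_trips(self, tmp_path, rng):
        import pandas as pd

        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        path = tmp_path / "net.tsv"
        edges = ft.export_network(C, threshold=0.2, path=path)
        read = pd.read_csv(path, sep="\t")
        assert read["weight"].tolist() == edges["weight"].tolist()

    def test_within_clade_edges_dominate_early(self, small_tree, small_truth):
        t0 = (small_truth.cells["age"] == 0).to_numpy()
        C = ft.coupling_matrix(small_truth.fates[t0])
        edges = ft.export_network(C, threshold=0.2)
        sub = small_tree.subclass_labels
        same = sum(sub[a] == sub[b] for a, b in zip(edges["type_a"], edges["type_b"]))
        assert same > len(edges) - same


class TestFitCouplingDecay:
    def test_parameters_recovered_within_ten_percent(self, rng):
        t_grid = np.array([0.0, 1.0, 3.0, 6.0, 11.0])
        b0, b1 = -2.0, 0.5
        series = 1.0 / (1.0 + np.exp(b0 + b1 * t_grid)) + rng.normal(0, 0.01, 5)
        fits = ft.fit_coupling_decay(series[:, None], t_grid, include_threshold=0.2, seed=0)
        assert len(fits) == 1
        assert abs(fits.iloc[0]["beta0"] - b0) / abs(b0) < 0.10
        assert abs(fits.iloc[0]["beta1"] - b1) / abs(b1) < 0.10

    def test_constant_series_flagged_degenerate(self):
        t_grid = np.array([0.0, 1.0, 3.0, 6.0, 11.0])
        series = np.full(5, 0.5)
        fits = ft.fit_coupling_decay(
            series[:, None], t_grid, terminal_t=1e9, include_threshold=0.2, seed=0
        )
        assert len(fits) == 1 and bool(fits.iloc[0]["degenerate"])

    def test_low_pairs_excluded(self):
        t_grid = np.array([0.0, 1.0, 3.0, 6.0, 11.0])
        series = np.column_stack([np.full(5, 0.1), np.linspace(0.8, 0.05, 5)])
        fits = ft.fit_coupling_decay(series, t_grid, include_threshold=0.2, seed=0)
        assert len(fits) == 1  # only the pair starting above threshold


class TestLocalization:
    def test_fully_localized(self):
        F = np.zeros((20, 3))
        F[:, 1] = 1.0
        labels = np.zeros(20, int)
        labels[:5] = 1  # precursors of type 1 live in cluster 0 of N = 10
        labels = np.repeat(np.arange(10), 2)
        F = np.zeros((20, 3))
        F[:2, 1] = 1.0  # type-1 precursors all in cluster 0
        F[2:, 0] = 1.0
        assert ft.localization(F, labels, 1) == pytest.approx(1 - 1 / 10)

    def test_uniform_spread_zero(self):
        labels = np.repeat(np.arange(10), 3)
        F = np.zeros((30, 2))
        F[:, 1] = 1.0  # every cell argmax type 1, evenly across 10 clusters
        assert ft.localization(F, labels, 1) == pytest.approx(0.0)

    def test_half_half_split(self):
        labels = np.repeat(np.arange(10), 4)
        F = np.zeros((40, 2))
        F[:8, 1] = 1.0  # type-1 precursors split 50/50 over clusters 0 and 1
        F[8:, 0] = 1.0
        assert ft.localization(F, labels, 1) == pytest.approx(1 - 2 / 10)

    def test_empty_precursor_set_missing(self, rng):
        F = rng.dirichlet(np.ones(3), size=20)
        F[:, 2] = 0.0
        F = F / F.sum(1, keepdims=True)
        assert np.isnan(ft.localization(F, np.zeros(20, int), 2))


class TestSpecificationTime:
    def test_already_localized_crosses_immediately(self):
        loc = np.array([0.95, 0.96, 0.97, 0.97, 0.98])
        N = np.full(5, 10)
        fit = ft.specification_time(loc, N, [0, 1, 3, 6, 11])
        assert fit.tau_sp == 0.0 and not fit.censored

    def test_never_crossing_censored_at_end(self):
        loc = np.array([0.01, 0.02, 0.02, 0.03, 0.05])
        N = np.full(5, 10)
        fit = ft.specification_time(loc, N, [0, 1, 3, 6, 11], t_max=36.0)
        assert fit.censored and fit.tau_sp == 36.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ft.specification_time([0.5, np.nan, np.nan, 0.6], [5, 5, 5, 5], [0, 1, 2, 3])

    def test_planted_schedule_recovered(self):
        """Spearman >= 0.8 between planted decouple times and inferred tau_sp."""
        from rgcfate import benchmarks

        _, _, rho = benchmarks.specification_recovery(seed=0)
        assert rho >= 0.8


class TestSubclassCouplingTest:
    def test_type_one_error_controlled(self, rng):
        """Random subclass labels do not produce systematically small p-values."""
        small_p = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            F = r.dirichlet(np.ones(10), size=300)
            C = ft.coupling_matrix(F)
            labels = r.integers(0, 3, size=10)
            if len(np.unique(labels)) < 2:
                continue
            try:
                res = ft.subclass_coupling_test(C, labels)
            except ValueError:
                continue
            small_p += res["p_value"] < 0.05
        assert small_p <= 5

    def test_planted_clades_recovered(self, small_tree, small_truth):
        t0 = (small_truth.cells["age"] == 0).to_numpy()
        rng = np.random.default_rng(0)
        F = small_truth.fates[t0] * np.exp(rng.normal(0, 0.5, size=(int(t0.sum()), 12)))
        F = F / F.sum(1, keepdims=True)
        C = ft.coupling_matrix(F)
        res = ft.subclass_coupling_test(C, small_tree.subclass_labels)
        assert res["within"]["median"] > res["between"]["median"]
        assert res["p_value"] < 0.01

    def test_single_subclass_rejected(self, rng):
        C = ft.coupling_matrix(rng.dirichlet(np.ones(4), size=50))
        with pytest.raises(ValueError):
            ft.subclass_coupling_test(C, np.zeros(4, int))
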