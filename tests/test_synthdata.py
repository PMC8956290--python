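"""Generator tests: planted trees, fates, counts, and laterality signatures."""

import numpy as np
import pandas as pd
import pytest

from rgcfate import preprocess as pp
from rgcfate import synthdata as sd
from rgcfate.laterality import de_ipsi
from rgcfate.transport import potential

AGES = (0, 1, 3, 6, 11, 20)


class TestFateTree:
    def test_minimal_tree_separates_at_first_age(self):
        tree = sd.make_fate_tree(2, 1, (0, 5), decouple_spread=0.0, root_lead=0.0, seed=0)
        assert tree.n_types == 2
        assert tree.nodes[tree.root].decouple_time == 0.0

    def test_binary_tree_internal_node_count(self):
        # a binary tree over n leaves has exactly n - 1 internal nodes
        tree = sd.make_fate_tree(45, 8, AGES, seed=3)
        assert len(tree.internal_nodes) == 44
        assert len([n for n in tree.nodes.values() if n.children is None]) == 45

    def test_subclasses_are_disjoint_clades(self):
        tree = sd.make_fate_tree(45, 8, AGES, seed=3)
        for s in range(8):
            members = set(np.where(tree.subclass_labels == s)[0])
            # some tree node's leaf set equals the subclass exactly
            assert members in [set(n.leaves) for n in tree.nodes.values()]

    def test_same_seed_identical_trees(self):
        t1 = sd.make_fate_tree(12, 4, AGES, seed=7)
        t2 = sd.make_fate_tree(12, 4, AGES, seed=7)
        assert t1.subclass_labels.tolist() == t2.subclass_labels.tolist()
        for nid in t1.nodes:
            assert t1.nodes[nid].decouple_time == t2.nodes[nid].decouple_time
            assert t1.nodes[nid].leaves == t2.nodes[nid].leaves

    def test_decouple_times_nondecreasing_root_to_leaf(self, small_tree):
        for node in small_tree.internal_nodes:
            for child in node.children:
                assert small_tree.nodes[child].decouple_time >= node.decouple_time - 1e-12

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_types": 1, "n_subclasses": 1},
            {"n_types": 4, "n_subclasses": 5},
            {"n_types": 4, "n_subclasses": 0},
        ],
    )
    def test_invalid_configurations(self, kwargs):
        with pytest.raises(ValueError):
            sd.make_fate_tree(age_grid=AGES, seed=0, **kwargs)

    def test_nonincreasing_age_grid_rejected(self):
        with pytest.raises(ValueError):
            sd.make_fate_tree(4, 2, (0, 5, 5), seed=0)


class TestSimulateFates:
    def test_fate_vectors_sum_to_one(self, small_truth):
        np.testing.assert_allclose(small_truth.fates.sum(axis=1), 1.0, atol=1e-12)

    def test_terminal_age_point_masses(self, small_truth):
        terminal = small_truth.cells["age"].max()
        mask = (small_truth.cells["age"] == terminal).to_numpy()
        F = small_truth.fates[mask]
        assert np.all(F.max(axis=1) == 1.0)
        np.testing.assert_allclose(potential(F), 1.0)

    def test_zero_sharpness_limit_is_uniform(self, small_tree):
        truth = sd.simulate_fates(small_tree, 30, sharpness=1e-9, seed=0)
        pre = (truth.cells["age"] < truth.cells["age"].max()).to_numpy()
        np.testing.assert_allclose(truth.fates[pre], 1.0 / 12, atol=1e-6)
        np.testing.assert_allclose(potential(truth.fates[pre]), 12.0, rtol=1e-4)

    def test_mean_potential_monotone_over_replicates(self):
        """Planted restriction increases with age in expectation (20 replicates)."""
        ages = (0, 1, 3, 6, 11)
        means = np.zeros(len(ages))
        for seed in range(20):
            tree = sd.make_fate_tree(10, 3, ages, seed=seed)
            truth = sd.simulate_fates(tree, 60, sharpness=0.5, seed=seed + 100)
            for i, t in enumerate(ages):
                m = (truth.cells["age"] == t).to_numpy()
                means[i] += np.mean(potential(truth.fates[m])) / 20
        assert np.all(np.diff(means) < 0)

    def test_late_decoupling_pairs_more_correlated(self, small_tree, small_truth):
        """Sibling leaves (late ancestor) beat cross-clade pairs in fate correlation."""
        t0 = (small_truth.cells["age"] == 0).to_numpy()
        F = small_truth.fates[t0]
        corr = np.corrcoef(F, rowvar=False)
        leaf_parents = {
            b: small_tree.parent[small_tree.leaf_node_id(b)] for b in range(12)
        }
        sib_pairs = [
            (a, b)
            for a in range(12)
            for b in range(a + 1, 12)
            if leaf_parents[a] == leaf_parents[b]
        ]
        cross = [
            (a, b)
            for a in range(12)
            for b in range(a + 1, 12)
            if small_tree.subclass_labels[a] != small_tree.subclass_labels[b]
        ]
        assert np.mean([corr[p] for p in sib_pairs]) > np.mean([corr[p] for p in cross])

    def test_determinism(self, small_tree):
        a = sd.simulate_fates(small_tree, 40, seed=9)
        b = sd.simulate_fates(small_tree, 40, seed=9)
        np.testing.assert_array_equal(a.fates, b.fates)
        pd.testing.assert_frame_equal(a.cells, b.cells)


class TestSimulateCounts:
    def test_byte_identical_mtx_output(self, tmp_path, small_tree):
        from rgcfate.io import write_10x

        truth = sd.simulate_fates(small_tree, 30, seed=4)
        for sub in ("a", "b"):
            t = sd.simulate_fates(small_tree, 30, seed=4)
            cm = sd.simulate_counts(t, n_genes=400, seed=11)
            write_10x(tmp_path / sub, cm)
        assert (tmp_path / "a/matrix.mtx").read_bytes() == (tmp_path / "b/matrix.mtx").read_bytes()

    def test_library_gamma_shape_recovered(self):
        tree = sd.make_fate_tree(2, 1, (0, 5), seed=0)
        truth = sd.simulate_fates(tree, 1500, seed=1)
        cm = sd.simulate_counts(
            truth, n_genes=300, libsize_shape=20.0, aux_strength=0.0,
            batch_effect_sd=0.0, seed=2,
        )
        alpha = pp.fit_library_gamma(cm)
        assert abs(alpha - 20.0) / 20.0 < 0.10

    def test_too_few_genes_rejected(self, small_truth):
        with pytest.raises(ValueError, match="too small"):
            sd.simulate_counts(small_truth, n_genes=50, programs_per_type=10)

    def test_pure_null_selection_matches_tail_of_rule(self):
        """With no planted programs, selection is only the mean + 0.8 sd tail.

        A mean + z*sd cutoff on a near-symmetric null selects roughly the
        corresponding upper-tail fraction (~20% at z = 0.8) and no gene
        deviates strongly from the Gamma-Poisson null.
        """
        tree = sd.make_fate_tree(2, 1, (0, 5), seed=0)
        truth = sd.simulate_fates(tree, 1200, seed=1)
        cm = sd.simulate_counts(
            truth, n_genes=400, program_strength=0.0, aux_strength=0.0,
            maturation_frac=0.0, seed=3,
        )
        hvg = pp.select_hvgs(cm)
        assert hvg.n_selected / cm.shape[0] < 0.30
        d = hvg.table["d"].to_numpy()
        assert np.nanmax(d[np.isfinite(d)]) < 0.2  # no real overdispersion


class TestPlantLaterality:
    @pytest.fixture(scope="class")
    def planted(self):
        truth, cm = sd.simulate_dataset(
            n_types=12, n_subclasses=4, n_cells_per_age=400, n_genes=600,
            with_laterality=True, seed=13,
        )
        return truth, cm

    def test_ipsi_fraction_near_request(self, planted):
        truth, _ = planted
        early = truth.cells["age"] <= 1
        frac = (truth.cells.loc[early, "laterality"] == "I").mean()
        assert 0.03 < frac < 0.07

    def test_scores_anticorrelated(self, planted):
        from rgcfate.laterality import signature_score

        truth, cm = planted
        em = pp.normalize_log(pp.filter_cells_genes(cm, 50, 3))
        early = (em.obs["age"] <= 1).to_numpy()
        em_early = type(em)(
            X=em.X[:, early], genes=em.genes, cells=em.cells[early],
            target=em.target, obs=em.obs.loc[early],
        )
        si = signature_score(em_early, ("Zic2", "Zic1", "Igfbp5"))
        sc = signature_score(em_early, ("Isl2", "Fgf12", "Igf1"))
        assert np.corrcoef(si, sc)[0, 1] < 0

    def test_no_signal_after_fade(self, planted):
        truth, cm = planted
        em = pp.normalize_log(pp.filter_cells_genes(cm, 50, 3))
        late = (em.obs["age"] == 11).to_numpy()
        em_late = type(em)(
            X=em.X[:, late], genes=em.genes, cells=em.cells[late],
            target=em.target, obs=em.obs.loc[late],
        )
        lineage = em.obs.loc[late, "true_type"].isin(truth.ipsi_types).to_numpy()
        table = de_ipsi(em_late, lineage)
        sig_genes = table.index[table["significant"]]
        markers = {"Zic2", "Zic1", "Igfbp5", "Isl2", "Fgf12", "Igf1"}
        assert len(set(sig_genes) & markers) == 0

    def test_overlapping_gene_sets_rejected(self, small_truth):
        cm = sd.simulate_counts(small_truth, n_genes=400, seed=0)
        with pytest.raises(ValueError, match="disjoint"):
            sd.plant_laterality(small_truth, cm, ipsi_genes=("A", "B"), contra_genes=("B",))

    def test_frac_bounds_rejected(self, small_truth):
        cm = sd.simulate_counts(small_truth, n_genes=400, seed=0)
        with pytest.raises(ValueError, match="frac_ipsi"):
            sd.plant_laterality(small_truth, cm, frac_ipsi=0.6)


def test_planted_partition_labels_types_for_committed(small_truth):
    labels = small_truth.planted_partition()
    pot = 1.0 / (small_truth.fates**2).sum(axis=1)
    committed = pot < 1.5
    destined = small_truth.cells["true_type"].to_numpy()
    assert np.array_equal(labels[committed], destined[committed])
    assert labels[~committed].min() >= small_truth.tree.n_types
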