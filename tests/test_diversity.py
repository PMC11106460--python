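"""Feature table assembly, PCA retention, clustering, gap statistic, stats."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ca1pyr.diversity import (
    FEATURE_NAMES, FeatureTable, assemble_feature_table, dunn_posthoc,
    embed_2d, gap_statistic, group_stats, hierarchical_cluster, pca_retain,
)
from ca1pyr.morphometrics import MORPH_FEATURE_NAMES
from ca1pyr.ephys import EPHYS_FEATURE_NAMES
from ca1pyr.tables import FeatureGenConfig, generate_feature_table


def _split_table(n=31, seed=0):
    tab = generate_feature_table(FeatureGenConfig(n_cells=n, seed=seed))
    morph = tab.data[list(MORPH_FEATURE_NAMES)]
    ephys = tab.data[list(EPHYS_FEATURE_NAMES)]
    return morph, ephys


class TestAssembly:
    def test_complete_31_by_22(self):
        morph, ephys = _split_table()
        tab = assemble_feature_table(morph, ephys)
        assert tab.data.shape == (31, 22)
        assert not tab.data.isna().any().any()
        assert list(tab.data.columns) == list(FEATURE_NAMES)

    def test_input_order_irrelevant(self):
        morph, ephys = _split_table()
        shuffled = morph.sample(frac=1.0, random_state=1)
        a = assemble_feature_table(morph, ephys).data
        b = assemble_feature_table(shuffled, ephys).data
        pd.testing.assert_frame_equal(a, b)

    def test_unmatched_cells_dropped_with_warning(self):
        morph, ephys = _split_table()
        with pytest.warns(UserWarning, match="unmatched"):
            tab = assemble_feature_table(morph.iloc[:-2], ephys)
        assert tab.n_cells == 29

    def test_duplicate_ids_rejected(self):
        morph, ephys = _split_table()
        dup = pd.concat([morph, morph.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_table(dup, ephys)

    def test_missing_entry_masked_row_retained(self):
        morph, ephys = _split_table()
        morph = morph.copy()
        morph.iloc[0, morph.columns.get_loc("soma_depth_fraction")] = np.nan
        tab = assemble_feature_table(morph, ephys)
        assert tab.n_cells == 31
        assert tab.mask.loc[tab.data.index[0], "soma_depth_fraction"]
        assert not tab.imputed().isna().any().any()


class TestPCARetention:
    def test_rank_one_table_keeps_single_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        tab = FeatureTable(pd.DataFrame({"a": x, "b": 2.0 * x}))
        pc = pca_retain(tab)
        assert pc.n_retained == 1
        assert pc.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_normalized_coefficients_peak_at_one(self):
        tab = generate_feature_table(FeatureGenConfig(n_cells=31, seed=1))
        pc = pca_retain(tab)
        for col in pc.coefficients.columns:
            assert pc.coefficients[col].abs().max() == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_spectrum_handled(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 22)), columns=list(FEATURE_NAMES))
        pc = pca_retain(FeatureTable(df))
        # each direction holds ~1/22 = 4.5% of variance; retention is driven
        # by sampling noise and must stay small without crashing
        assert 1 <= pc.n_retained < 11
        assert pc.explained_variance[0] < 0.10

    def test_explained_variance_sorted_and_bounded(self):
        tab = generate_feature_table(FeatureGenConfig(n_cells=31, seed=3))
        pc = pca_retain(tab)
        assert np.all(np.diff(pc.explained_variance) <= 1e-12)
        assert pc.explained_variance.sum() <= 1.0 + 1e-9
        assert np.all(pc.explained_variance > 0.05)

    def test_single_cell_rejected(self):
        tab = FeatureTable(pd.DataFrame({"a": [1.0], "b": [2.0]}))
        with pytest.raises(ValueError):
            pca_retain(tab)


def _blobs(n_per=15, centers=(0.0, 6.0, 12.0), dim=5, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(c, 0.4, size=(n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestHierarchicalClustering:
    def test_separated_blobs_recovered_exactly(self):
        pts, labels = _blobs()
        res = hierarchical_cluster(pts, n_branches=3)
        assert adjusted_rand_score(labels, res.branches) == 1.0

    def test_identical_points_collapse_to_one_branch(self):
        pts = np.ones((10, 3))
        res = hierarchical_cluster(pts, n_branches=3)
        assert len(np.unique(res.branches)) == 1

    def test_permutation_invariant_partition(self):
        pts, _ = _blobs(seed=4)
        perm = np.random.default_rng(1).permutation(len(pts))
        a = hierarchical_cluster(pts, 3).branches
        b = hierarchical_cluster(pts[perm], 3).branches
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_too_many_branches_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.ones((3, 2)), n_branches=5)


class TestGapStatistic:
    def test_three_blobs_estimated(self):
        pts, _ = _blobs()
        res = gap_statistic(pts, k_max=8, n_refs=100, seed=0)
        assert res.estimated_k == 3

    def test_seeded_curve_reproducible(self):
        pts, _ = _blobs(seed=2)
        a = gap_statistic(pts, k_max=6, n_refs=50, seed=9)
        b = gap_statistic(pts, k_max=6, n_refs=50, seed=9)
        assert np.array_equal(a.gap_curve, b.gap_curve)

    def test_degenerate_data_gives_one_cluster(self):
        res = gap_statistic(np.zeros((12, 3)), k_max=5, n_refs=10, seed=0)
        assert res.estimated_k == 1

    def test_single_population_gives_one_cluster(self):
        tab = generate_feature_table(FeatureGenConfig(n_cells=31, seed=5))
        pc = pca_retain(tab)
        res = gap_statistic(pc.scores, k_max=10, n_refs=200, seed=5)
        assert res.estimated_k == 1

    def test_single_population_recovery_rate(self):
        """k = 1 recovered in >= 90% of 20 seeded single-Gaussian cohorts."""
        hits = 0
        for seed in range(20):
            tab = generate_feature_table(FeatureGenConfig(n_cells=31, seed=seed))
            pc = pca_retain(tab)
            res = gap_statistic(pc.scores, k_max=10, n_refs=100, seed=seed)
            hits += res.estimated_k == 1
        assert hits >= 18


class TestGroupStats:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"f": np.tile(rng.normal(size=10), 3)})
        tab = FeatureTable(df)
        branches = np.repeat([1, 2, 3], 10)
        rep = group_stats(tab, branches)
        assert rep["features"]["f"]["kruskal_h"] == pytest.approx(0.0, abs=1e-9)
        assert rep["features"]["f"]["kruskal_p"] > 0.99

    def test_shifted_groups_detected_reliably(self):
        """3 SD shift, n = 15 per group: Mann-Whitney p < 0.001 in >= 95%
        of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)])
            tab = FeatureTable(pd.DataFrame({"f": vals}))
            rep = group_stats(tab, np.repeat([1, 2], 15))
            hits += rep["features"]["f"]["mannwhitney_p"] < 0.001
        assert hits >= 95

    def test_small_branch_skipped_and_flagged(self):
        rng = np.random.default_rng(1)
        tab = FeatureTable(pd.DataFrame({"f": rng.normal(size=11)}))
        branches = np.array([1] * 5 + [2] * 5 + [3])
        rep = group_stats(tab, branches)
        assert rep["skipped_branches"] == [3]
        assert "mannwhitney_p" in rep["features"]["f"]

    def test_duplicated_feature_perfectly_correlated(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        tab = FeatureTable(pd.DataFrame({"f1": x, "f2": x.copy(),
                                         "f3": rng.normal(size=30)}))
        rep = group_stats(tab, np.repeat([1, 2], 15))
        pair = next(r for r in rep["spearman"]
                    if {r["feature_a"], r["feature_b"]} == {"f1", "f2"})
        assert pair["rho"] == pytest.approx(1.0)
        assert pair["significant"]

    def test_tdl_basal_pair_excluded(self):
        rng = np.random.default_rng(3)
        cols = {"tdl_total": rng.normal(size=20), "tdl_basal": rng.normal(size=20),
                "sag_ratio": rng.normal(size=20)}
        tab = FeatureTable(pd.DataFrame(cols))
        rep = group_stats(tab, np.repeat([1, 2], 10),
                          dominant_features=list(cols))
        pairs = [{r["feature_a"], r["feature_b"]} for r in rep["spearman"]]
        assert {"tdl_total", "tdl_basal"} not in pairs

    def test_dunn_pairs_cover_all_contrasts(self):
        rng = np.random.default_rng(4)
        out = dunn_posthoc(rng.normal(size=30), np.repeat([1, 2, 3], 10))
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()


class TestEmbedding:
    def test_seeded_reproducibility(self):
        pts, _ = _blobs(n_per=10, dim=4)
        a = embed_2d(pts, seed=3, perplexity=8)
        b = embed_2d(pts, seed=3, perplexity=8)
        assert np.array_equal(a, b)

    def test_blob_structure_preserved(self):
        pts, labels = _blobs(n_per=10, dim=4)
        emb = embed_2d(pts, seed=0, perplexity=8)
        intra, inter = [], []
        for i in range(len(emb)):
            for j in range(i + 1, len(emb)):
                d = np.linalg.norm(emb[i] - emb[j])
                (intra if labels[i] == labels[j] else inter).append(d)
        assert np.mean(inter) > np.mean(intra)

    def test_perplexity_bound(self):
        pts, _ = _blobs(n_per=4, dim=3)
        with pytest.raises(ValueError):
            embed_2d(pts, perplexity=20)
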