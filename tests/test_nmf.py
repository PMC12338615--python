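import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import laminax as lx


class TestNMFFit:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, 50)
        h = rng.uniform(0.5, 2.0, 40)
        X = np.outer(w, h)
        model = lx.nmf_fit(X, k=1, seed=0, max_iter=300)
        rel = np.linalg.norm(X - model.W @ model.H) / np.linalg.norm(X)
        assert rel < 1e-4

    def test_seed_determinism(self):
        X = np.abs(np.random.default_rng(1).normal(1, 0.5, (30, 25)))
        m1 = lx.nmf_fit(X, k=3, seed=5, max_iter=100)
        m2 = lx.nmf_fit(X, k=3, seed=5, max_iter=100)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_loss_monotone_nonincreasing(self):
        X = np.abs(np.random.default_rng(2).normal(1, 0.5, (60, 50)))
        model = lx.nmf_fit(X, k=4, seed=0, max_iter=200)
        diffs = np.diff(model.objective_trace)
        assert (diffs <= 1e-9 * max(model.objective_trace[0], 1.0)).all()

    def test_planted_block_factors_recovered(self):
        X, W_true, _ = lx.simulate_low_rank(200, 150, rank=4, noise_sd=0.1, seed=3)
        model = lx.nmf_fit(X, k=4, seed=1, max_iter=500)
        # cosine similarity under the best permutation (Hungarian matching)
        Wn = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
        Tn = W_true / np.linalg.norm(W_true, axis=0, keepdims=True)
        sim = Tn.T @ Wn
        rows, cols = linear_sum_assignment(-sim)
        assert sim[rows, cols].mean() >= 0.9

    def test_nonnegativity_and_unit_loadings(self):
        X = np.abs(np.random.default_rng(4).normal(1, 0.5, (40, 30)))
        model = lx.nmf_fit(X, k=3, seed=0)
        assert model.W.min() >= 0 and model.H.min() >= 0
        norms = np.linalg.norm(model.W, axis=0)
        np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-9)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            lx.nmf_fit(np.ones((5, 4)), k=4)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lx.nmf_fit(np.array([[1.0, -0.1], [0.2, 0.3], [0.1, 0.1]]), k=1)

    def test_sparse_variant_concentrates_loadings(self):
        X, W_true, _ = lx.simulate_low_rank(200, 150, rank=3, noise_sd=0.3, seed=5)
        plain = lx.nmf_fit(X, k=3, seed=1, max_iter=300)
        sparse = lx.nmf_fit(X, k=3, seed=1, max_iter=300, l1_w=0.01)
        assert (sparse.W == 0).mean() > (plain.W == 0).mean()


class TestCrossValidateRank:
    def test_planted_rank_selected(self):
        X, _, _ = lx.simulate_low_rank(150, 120, rank=3, noise_sd=0.5, seed=0)
        table, selected = lx.cross_validate_rank(X, ranks=range(1, 6), seed=0,
                                                 n_reps=2, max_iter=150)
        assert selected == 3

    def test_error_curve_deterministic(self):
        X, _, _ = lx.simulate_low_rank(80, 60, rank=2, noise_sd=0.3, seed=1)
        t1, s1 = lx.cross_validate_rank(X, [1, 2, 3], seed=7, n_reps=2, max_iter=100)
        t2, s2 = lx.cross_validate_rank(X, [1, 2, 3], seed=7, n_reps=2, max_iter=100)
        pd.testing.assert_frame_equal(t1, t2)
        assert s1 == s2

    def test_rank_one_heldout_error_near_noise_floor(self):
        X, W, H = lx.simulate_low_rank(100, 80, rank=1, noise_sd=0.2, seed=2)
        table, _ = lx.cross_validate_rank(X, [1], seed=0, n_reps=3, max_iter=200)
        err = table["heldout_mse"].iloc[0]
        # clipping at zero and fit bias leave the held-out MSE near sigma^2
        assert err == pytest.approx(0.04, rel=0.5)

    def test_empty_ranks_error(self):
        with pytest.raises(ValueError):
            lx.cross_validate_rank(np.ones((10, 10)), [])


class TestTechnicalFilter:
    def _model_with_H(self, H):
        k, n = H.shape
        return lx.NMFModel(np.ones((5, k)), H, k, np.zeros(1), 0)

    def test_library_size_pattern_flagged(self):
        rng = np.random.default_rng(0)
        lib = rng.lognormal(8, 0.5, 200)
        H = np.vstack([lib, rng.normal(5, 1, 200)])
        model = self._model_with_H(np.abs(H))
        flags = lx.technical_filter(model, pd.DataFrame({"sum": lib}))
        assert flags["NMF1"] and not flags["NMF2"]

    def test_categorical_dummies(self):
        rng = np.random.default_rng(1)
        donor = np.repeat(["d1", "d2"], 100)
        H = np.vstack([(donor == "d1").astype(float) * 3 + 0.1,
                       rng.uniform(0, 1, 200)])
        model = self._model_with_H(H)
        flags = lx.technical_filter(model, pd.DataFrame({"donor": donor}))
        assert flags["NMF1"] and not flags["NMF2"]

    def test_zero_variance_pattern_not_flagged(self):
        H = np.vstack([np.full(50, 2.0), np.random.default_rng(2).uniform(0, 1, 50)])
        model = self._model_with_H(H)
        flags = lx.technical_filter(model, pd.DataFrame({"sum": np.arange(50.0)}))
        assert not flags["NMF1"]

    def test_planted_technical_factor_flagged_in_simulation(self, small_sim):
        _, _, nuclei, truth = small_sim
        model = lx.nmf_fit(lx.log_normalize(nuclei), k=truth.planted_rank + 4,
                           seed=1, max_iter=400)
        qc = lx.compute_qc(nuclei)
        cov = pd.DataFrame(
            {"sum": qc.sum, "detected": qc.detected, "mito_pct": qc.mito_pct,
             "donor": nuclei.obs_meta["donor"].to_numpy(),
             "sex": nuclei.obs_meta["sex"].to_numpy()}
        )
        flags = lx.technical_filter(model, cov)
        # the planted library-size program must surface as a flagged pattern
        assert flags.any()


class TestAnnotatePatterns:
    def test_indicator_pattern_assignment(self):
        labels = np.array(["a"] * 30 + ["b"] * 30)
        H = np.vstack([(labels == "a").astype(float), (labels == "b").astype(float)])
        model = lx.NMFModel(np.eye(4)[:, :2], H, 2, np.zeros(1), 0,
                            gene_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object))
        meta = lx.annotate_patterns(model, labels)
        assert model.top_pattern_by_type["a"] == "NMF1"
        assert model.top_pattern_by_type["b"] == "NMF2"
        assert model.mean_by_type.loc["NMF1", "a"] == 1.0
        assert model.mean_by_type.loc["NMF1", "b"] == 0.0

    def test_tie_broken_by_lower_index_and_recorded(self):
        labels = np.array(["a"] * 20)
        H = np.vstack([np.ones(20), np.ones(20)])
        model = lx.NMFModel(np.ones((3, 2)), H, 2, np.zeros(1), 0)
        lx.annotate_patterns(model, labels)
        assert model.top_pattern_by_type["a"] == "NMF1"

    def test_technical_patterns_excluded(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        H = np.vstack([np.full(20, 5.0), (labels == "a").astype(float)])
        model = lx.NMFModel(np.ones((3, 2)), H, 2, np.zeros(1), 0)
        model.technical = np.array([True, False])
        lx.annotate_patterns(model, labels)
        assert model.top_pattern_by_type["a"] == "NMF2"

    def test_top_genes_recorded(self):
        W = np.zeros((6, 1))
        W[[2, 4], 0] = [1.0, 0.5]
        model = lx.NMFModel(W, np.ones((1, 4)), 1, np.zeros(1), 0,
                            gene_ids=np.array([f"g{i}" for i in range(6)], dtype=object))
        meta = lx.annotate_patterns(model, np.array(["a"] * 4), n_top_genes=2)
        assert meta.loc["NMF1", "top_genes"].split(",") == ["g2", "g4"]


class TestProjection:
    def _fitted(self, seed=0):
        X, _, _ = lx.simulate_low_rank(120, 100, rank=3, noise_sd=0.1, seed=seed)
        gene_ids = np.array([f"g{i}" for i in range(120)], dtype=object)
        ln = lx.LogNormMatrix(X, gene_ids, np.array([f"s{j}" for j in range(100)], dtype=object))
        return lx.nmf_fit(ln, k=3, seed=1, max_iter=300), X, gene_ids

    def test_self_projection_reproduces_weights(self):
        model, X, gids = self._fitted()
        res = lx.project_patterns(model, X, gene_ids_new=gids)
        for j in range(3):
            r = np.corrcoef(res.H_new[j], model.H[j])[0, 1]
            assert r >= 0.95

    def test_pure_column_recovers_unit_weight(self):
        model, X, gids = self._fitted()
        x = 2.5 * model.W[:, 1]
        res = lx.project_patterns(model, x[:, None], gene_ids_new=gids)
        expected = np.zeros(3)
        expected[1] = 2.5
        np.testing.assert_allclose(res.H_new[:, 0], expected, atol=1e-8)

    def test_zero_vector_gives_zero_weights(self):
        model, X, gids = self._fitted()
        res = lx.project_patterns(model, np.zeros((120, 1)), gene_ids_new=gids)
        np.testing.assert_array_equal(res.H_new, 0)

    def test_gene_permutation_equivariance(self):
        model, X, gids = self._fitted()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(gids))
        res1 = lx.project_patterns(model, X, gene_ids_new=gids)
        res2 = lx.project_patterns(model, X[perm], gene_ids_new=gids[perm])
        np.testing.assert_allclose(res1.H_new, res2.H_new, atol=1e-10)

    def test_partial_overlap_reported(self):
        model, X, gids = self._fitted()
        res = lx.project_patterns(model, X[:80], gene_ids_new=gids[:80])
        assert res.dropped_genes["model_only"] == 40
        assert len(res.genes_used) == 80

    def test_empty_intersection_is_error(self):
        model, X, gids = self._fitted()
        with pytest.raises(ValueError, match="intersection"):
            lx.project_patterns(model, X, gene_ids_new=np.array([f"z{i}" for i in range(120)]))


class TestNMFPositiveDE:
    def _assay(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(20.0, (30, n))
        counts[0, : n // 2] *= 6   # marker of class A spots
        obs_meta = pd.DataFrame(
            {"sample": np.tile(["s1", "s2"], n // 2), "donor": np.tile(["d1", "d2"], n // 2)},
            index=pd.Index([f"o{j}" for j in range(n)], name="obs_id"),
        )
        return lx.CountAssay(counts, [f"g{i}" for i in range(30)],
                             [f"o{j}" for j in range(n)], obs_meta=obs_meta)

    def test_disjoint_supports_no_exclusions(self):
        assay = self._assay()
        h_a = np.zeros(60)
        h_a[:30] = 1.0
        h_b = np.zeros(60)
        h_b[30:] = 1.0
        stats, report = lx.nmf_positive_de(assay, h_a, h_b, min_obs=2)
        assert report["n_double_positive"] == 0
        assert report["n_a"] == 30 and report["n_b"] == 30

    def test_all_double_positive_is_error(self):
        assay = self._assay()
        with pytest.raises(ValueError):
            lx.nmf_positive_de(assay, np.ones(60), np.ones(60), min_obs=2)

    def test_marker_gene_tops_t_ranking(self):
        assay = self._assay()
        h_a = np.zeros(60)
        h_a[:30] = 1.0
        h_b = np.zeros(60)
        h_b[30:] = 1.0
        stats, _ = lx.nmf_positive_de(assay, h_a, h_b, min_obs=2)
        top = stats.table.sort_values("t", ascending=False).iloc[0]
        assert top["gene_id"] == "g0"

    def test_double_positives_excluded_and_counted(self):
        assay = self._assay()
        h_a = np.zeros(60)
        h_a[:35] = 1.0
        h_b = np.zeros(60)
        h_b[30:] = 1.0
        stats, report = lx.nmf_positive_de(assay, h_a, h_b, min_obs=2)
        assert report["n_double_positive"] == 5
        assert report["n_a"] == 30 and report["n_b"] == 25


class TestGroupSummaries:
    def test_fraction_nonzero_arithmetic(self):
        h = np.array([0.0, 1.0, 2.0, 0.0, 0.0, 0.0, 3.0, 0.0, 0.0, 0.0])
        groups = ["L5"] * 10
        samples = ["s1"] * 10
        tab = lx.fraction_nonzero_by_group(h, groups, samples)
        assert tab.loc["s1", "L5"] == pytest.approx(0.3)

    def test_extremes(self):
        groups = ["a", "a", "b", "b"]
        samples = ["s"] * 4
        assert (lx.fraction_nonzero_by_group(np.zeros(4), groups, samples) == 0).all().all()
        assert (lx.fraction_nonzero_by_group(np.ones(4), groups, samples) == 1).all().all()

    def test_empty_group_missing_not_zero(self):
        h = np.array([1.0, 1.0])
        tab = lx.fraction_nonzero_by_group(h, ["a", "a"], ["s1", "s1"])
        assert "b" not in tab.columns
        tab2 = lx.fraction_nonzero_by_group(
            np.array([1.0, 0.5, 0.0]), ["a", "a", "b"], ["s1", "s1", "s2"]
        )
        assert np.isnan(tab2.loc["s1", "b"])

    def test_mean_weight_by_group(self):
        h = np.array([1.0, 3.0, 10.0])
        tab = lx.mean_weight_by_group(h, ["a", "a", "b"], ["s1", "s1", "s1"])
        assert tab.loc["s1", "a"] == pytest.approx(2.0)
        assert tab.loc["s1", "b"] == pytest.approx(10.0)
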