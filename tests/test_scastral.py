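"""Contrastive classifier: normalization closed forms, pair construction,
loss identities, training behaviour, prediction thresholds, serialization and
permutation feature importance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sclineage import scastral as sc

FAST = sc.TrainConfig(seed=0, max_epochs=60, patience=10)


@pytest.fixture(scope="module")
def trained(separable_counts):
    counts, gene_ids, labels, panel = separable_counts
    model = sc.train(counts, gene_ids, labels, panel,
                     cfg=sc.TrainConfig(seed=0, max_epochs=100, patience=15))
    return model


class TestNormalization:
    def test_cpm_row_shares(self):
        cpm = sc.cpm_normalize(np.array([[1.0], [1.0], [2.0]]))
        assert np.allclose(cpm[:, 0], [250_000, 250_000, 500_000])
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_cpm_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            sc.cpm_normalize(np.array([[0.0], [0.0]]))

    def test_idf_closed_forms(self):
        # gene 0 in every cell, gene 1 in 1 of 100 cells
        counts = np.zeros((2, 100))
        counts[0] = 1.0
        counts[1, 0] = 1.0
        idf = sc.idf_weights(counts)
        assert idf[0] == pytest.approx(np.log(100 / 101))
        assert idf[1] == pytest.approx(np.log(50))
        assert idf[0] < 0  # ubiquitous genes are down-weighted to ~0

    def test_tf_sums_to_one_per_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, (20, 5)).astype(float)
        tf = sc.tf_vector(counts)
        assert np.allclose(tf.sum(axis=0), 1.0)

    def test_all_zero_cell_maps_to_zero_vector(self):
        counts = np.zeros((4, 2))
        counts[:, 0] = [1, 2, 3, 4]
        out = sc.tfidf_rescale(counts)
        assert np.allclose(out[:, 1], 0.0)

    def test_missing_panel_genes_imputed_with_warning(self):
        counts = np.ones((2, 3))
        with pytest.warns(UserWarning):
            out = sc.cut_to_panel(counts, pd.Index(["A", "B"]), ["A", "MISSING"])
        assert np.allclose(out[1], 0.0)


class TestPairs:
    def test_exactly_two_pairs_per_cell_with_correct_classes(self):
        labels = np.array(["t"] * 6 + ["s"] * 4)
        i1, i2, y = sc.build_pairs(labels, np.random.default_rng(0))
        assert len(y) == 20
        pos = y > 0
        assert (labels[i1[pos]] == labels[i2[pos]]).all()
        assert (labels[i1[~pos]] != labels[i2[~pos]]).all()
        assert not np.any(i1[pos] == i2[pos])  # self excluded when possible

    def test_deterministic_in_seed(self):
        labels = np.array(["t", "t", "s", "s", "s"])
        a = sc.build_pairs(labels, np.random.default_rng(5))
        b = sc.build_pairs(labels, np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sc.build_pairs(np.array(["t", "t"]), np.random.default_rng(0))


class TestLoss:
    def test_identical_positive_pair_with_perfect_reconstruction_is_zero(self):
        z = np.array([[1.0, 2.0]])
        x = np.array([[1.0, 0.0]])
        cfg = sc.TrainConfig(w_lat=0.0)
        assert sc.contrastive_loss(z, z, np.array([1]), x, x, cfg) == pytest.approx(0.0)

    def test_orthogonal_negative_pair_costs_nothing(self):
        z1, z2 = np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])
        loss = sc.cosine_embedding_loss(z1, z2, np.array([-1]), margin=0.0)
        assert loss[0] == pytest.approx(0.0)

    def test_identical_negative_pair_costs_one(self):
        z = np.array([[1.0, 1.0]])
        loss = sc.cosine_embedding_loss(z, z, np.array([-1]), margin=0.0)
        assert loss[0] == pytest.approx(1.0)

    def test_zero_norm_vector_contributes_zero(self):
        z0 = np.zeros((1, 2))
        z1 = np.ones((1, 2))
        assert sc.cosine_embedding_loss(z0, z1, np.array([1]))[0] == 0.0

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        ae = sc.ContrastiveAutoencoder(6, sc.EncoderConfig(hidden=5, latent=3), rng)
        X = rng.normal(0, 1, (8, 6))
        i1, i2, y = sc.build_pairs(np.array(["a"] * 4 + ["b"] * 4), rng)
        cfg = sc.TrainConfig()
        _, grads = ae.loss_and_grads(X, i1, i2, y, cfg)
        eps = 1e-6
        for key in ("W1", "W4", "b2"):
            w = ae.params[key]
            idx = tuple(0 for _ in w.shape)
            w[idx] += eps
            up, _ = ae.loss_and_grads(X, i1, i2, y, cfg)
            w[idx] -= 2 * eps
            dn, _ = ae.loss_and_grads(X, i1, i2, y, cfg)
            w[idx] += eps
            assert grads[key][idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-3, abs=1e-8)


class TestTraining:
    def test_separable_fixture_reaches_high_accuracy(self, trained):
        assert trained.selection_accuracy >= 0.9

    def test_training_is_deterministic(self, separable_counts, trained):
        counts, gene_ids, labels, panel = separable_counts
        again = sc.train(counts, gene_ids, labels, panel,
                         cfg=sc.TrainConfig(seed=0, max_epochs=100, patience=15))
        p1 = sc.predict(trained, counts, gene_ids).cells["p_tolerant"]
        p2 = sc.predict(again, counts, gene_ids).cells["p_tolerant"]
        assert np.allclose(p1, p2)

    def test_missing_class_rejected(self, separable_counts):
        counts, gene_ids, labels, panel = separable_counts
        with pytest.raises(ValueError):
            sc.train(counts, gene_ids, np.array(["tolerant"] * counts.shape[1]),
                     panel, cfg=FAST)

    def test_embedding_separates_classes_in_cosine_distance(self, separable_counts, trained):
        from sklearn.metrics.pairwise import cosine_distances

        counts, gene_ids, labels, _ = separable_counts
        emb = trained.embed_counts(counts, gene_ids)
        D = cosine_distances(emb)
        tol = labels == "tolerant"
        intra = (D[np.ix_(tol, tol)].mean() + D[np.ix_(~tol, ~tol)].mean()) / 2
        inter = D[np.ix_(tol, ~tol)].mean()
        assert intra < inter


class TestPrediction:
    def test_threshold_rule_and_fraction_arithmetic(self, separable_counts, trained):
        counts, gene_ids, _, _ = separable_counts
        pred = sc.predict(trained, counts, gene_ids)
        cells = pred.cells
        undet = cells["class"] == "undetermined"
        assert (cells.loc[undet, "probability"] <= 0.75).all()
        assert (cells.loc[~undet, "probability"] > 0.75).all()
        assert pred.fractions.sum() == pytest.approx(1.0)
        assert pred.fractions["tolerant"] == pytest.approx(
            (cells["class"] == "tolerant").mean())

    def test_pseudobulk_of_identical_cells_matches_single_cell(self, separable_counts, trained):
        counts, gene_ids, _, _ = separable_counts
        one = counts[:, [0]]
        stack = np.repeat(one, 10, axis=1)  # 10 identical cells
        single = sc.predict(trained, one, gene_ids)
        bulk = sc.predict_pseudobulk(trained, stack, gene_ids)
        # summing identical cells rescales the profile; tf-idf is scale-free
        assert np.allclose(bulk.cells["p_tolerant"], single.cells["p_tolerant"], atol=1e-9)

    def test_empty_pseudobulk_rejected(self, trained, separable_counts):
        _, gene_ids, _, _ = separable_counts
        with pytest.raises(ValueError):
            sc.predict_pseudobulk(trained, np.zeros((300, 0)), gene_ids)

    def test_save_load_roundtrip_identical_probabilities(self, separable_counts, trained, tmp_path):
        counts, gene_ids, _, _ = separable_counts
        trained.save(tmp_path / "model.joblib")
        loaded = sc.FittedScastral.load(tmp_path / "model.joblib")
        p1 = sc.predict(trained, counts, gene_ids).cells["p_tolerant"]
        p2 = sc.predict(loaded, counts, gene_ids).cells["p_tolerant"]
        assert np.allclose(p1, p2, atol=1e-6)


class TestPFI:
    def test_constant_gene_has_exactly_zero_importance(self, separable_counts, trained):
        counts, gene_ids, labels, panel = separable_counts
        # an all-zero panel gene has a constant (zero) tf-idf column, so
        # every permutation of it is the identity
        counts = counts.copy()
        counts[gene_ids.get_loc(panel[10])] = 0
        imp = sc.pfi(trained, counts, gene_ids, labels, n_rep=3, seed=0)
        assert imp.loc[panel[10]] == 0.0

    def test_informative_gene_dominates_one_signal_fixture(self):
        rng = np.random.default_rng(11)
        n = 400
        gene_ids = pd.Index([f"G{i}" for i in range(40)])
        labels = np.array(["tolerant"] * (n // 2) + ["sensitive"] * (n // 2))
        mean = np.full((40, n), 20.0)
        mean[0, : n // 2] *= 6.0  # the single informative gene
        counts = rng.poisson(mean)
        panel = list(gene_ids[:20])
        model = sc.train(counts, gene_ids, labels, panel, cfg=FAST)
        imp = sc.pfi(model, counts, gene_ids, labels, n_rep=10, seed=1)
        assert imp.idxmax() == "G0"
        assert imp.loc["G0"] > 0

    def test_single_class_rejected(self, separable_counts, trained):
        counts, gene_ids, _, _ = separable_counts
        with pytest.raises(ValueError):
            sc.pfi(trained, counts, gene_ids,
                   np.array(["tolerant"] * counts.shape[1]), n_rep=2)
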