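"""Joint embedding, label transfer and the cluster classifier."""

import numpy as np
import pandas as pd
import pytest

from spotmap import transfer as T


def _rank1(n=30, g=15, seed=0):
    rng = np.random.default_rng(seed)
    return np.outer(rng.uniform(1, 2, g), rng.uniform(1, 2, n))


class TestIntegrate:
    def test_self_integration_coincides(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(0, 5, (20, 15))
        emb = T.integrate(mat, mat, [f"c{i}" for i in range(15)],
                          [f"s{i}" for i in range(15)], d=5)
        gaps = np.linalg.norm(emb.cell_shared - emb.spot_shared, axis=1)
        assert gaps.max() < 1e-8

    def test_constant_gene_shift_removed(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 5, (30, 40))
        shifted = base + rng.uniform(1, 3, (30, 1))  # per-gene batch offset
        emb = T.integrate(base, shifted, range(40), range(40), d=10)
        paired = np.linalg.norm(emb.cell_shared - emb.spot_shared, axis=1)
        rng_idx = rng.permutation(40)
        crossed = np.linalg.norm(
            emb.cell_shared - emb.spot_shared[rng_idx], axis=1
        )
        assert np.median(paired) < 0.1 * np.median(crossed[rng_idx != np.arange(40)])

    def test_rank1_single_direction(self):
        mat = _rank1()
        emb = T.integrate(mat, mat, range(mat.shape[1]), range(mat.shape[1]), d=1)
        assert emb.d_cca == 1
        # all L2-normalised 1-d vectors collapse to +-1
        assert set(np.round(np.abs(emb.cell_shared[:, 0]), 6)) == {1.0}

    def test_too_few_genes_rejected(self):
        mat = np.ones((4, 5))
        with pytest.raises(ValueError, match="4 shared feature genes"):
            T.integrate(mat, mat, range(5), range(5))


class TestEmbed2D:
    @pytest.fixture(scope="class")
    def populations(self):
        rng = np.random.default_rng(2)
        centers = np.eye(3) * 8
        pts = np.vstack([rng.normal(centers[i], 0.3, (40, 3)) for i in range(3)])
        labels = np.repeat([0, 1, 2], 40)
        emb = T.JointEmbedding(
            cell_ids=np.array([f"c{i}" for i in range(100)], dtype=object),
            spot_ids=np.array([f"s{i}" for i in range(20)], dtype=object),
            cell_shared=pts[:100],
            spot_shared=pts[100:],
            d_cca=3,
        )
        return emb, labels

    def test_determinism(self, populations):
        emb, _ = populations
        a = T.embed_2d(emb, seed=5, n_neighbors=10)
        c1 = a.cell_coords.copy()
        b = T.embed_2d(emb, seed=5, n_neighbors=10)
        np.testing.assert_array_equal(c1, b.cell_coords)

    def test_separated_populations_stay_separated(self, populations):
        from sklearn.metrics import silhouette_score

        emb, labels = populations
        T.embed_2d(emb, seed=5, n_neighbors=10)
        coords = np.vstack([emb.cell_coords, emb.spot_coords])
        assert silhouette_score(coords, labels) > 0

    def test_small_input_reduces_neighbors(self):
        rng = np.random.default_rng(3)
        emb = T.JointEmbedding(
            cell_ids=np.array(["a", "b", "c"], dtype=object),
            spot_ids=np.array(["s"], dtype=object),
            cell_shared=rng.normal(size=(3, 2)),
            spot_shared=rng.normal(size=(1, 2)),
            d_cca=2,
        )
        with pytest.warns(UserWarning, match="reduced"):
            T.embed_2d(emb, seed=0, n_neighbors=30)


def _embedding(cell_pts, spot_pts):
    cells = np.asarray(cell_pts, dtype=float)
    spots = np.asarray(spot_pts, dtype=float)
    emb = T.JointEmbedding(
        cell_ids=np.array([f"c{i}" for i in range(len(cells))], dtype=object),
        spot_ids=np.array([f"s{i}" for i in range(len(spots))], dtype=object),
        cell_shared=cells,
        spot_shared=spots,
        d_cca=cells.shape[1],
    )
    return T.use_shared_space(emb)


class TestTransferLabels:
    def test_nearest_cell_labelled(self):
        emb = _embedding([[1.0, 0.0], [2.0, 0.0]], [[0.0, 0.0]])
        pairs = T.transfer_labels(emb, pd.Series({"s0": 7}), k=1)
        assert len(pairs) == 1
        assert pairs.loc[0, "cell_id"] == "c0" and pairs.loc[0, "label"] == 7

    def test_equidistant_tie_goes_to_first_spot_id(self):
        emb = _embedding([[0.0, 0.0]], [[1.0, 0.0], [-1.0, 0.0]])
        pairs = T.transfer_labels(emb, pd.Series({"s0": 1, "s1": 2}), k=1)
        assert pairs.loc[0, "spot_id"] == "s0" and pairs.loc[0, "label"] == 1

    def test_conflict_resolved_by_nearest_spot(self):
        emb = _embedding([[0.0, 0.0]], [[0.5, 0.0], [2.0, 0.0]])
        pairs = T.transfer_labels(emb, pd.Series({"s0": 1, "s1": 2}), k=1)
        assert list(pairs["label"]) == [1]

    def test_cardinality_bounds(self):
        rng = np.random.default_rng(4)
        emb = _embedding(rng.normal(size=(12, 2)), rng.normal(size=(5, 2)))
        pairs = T.transfer_labels(
            emb, pd.Series(0, index=emb.spot_ids), k=3
        )
        assert len(pairs) <= min(5 * 3, 12)

    def test_k_exceeding_cells_rejected(self):
        emb = _embedding([[0.0, 0.0]], [[1.0, 0.0]])
        with pytest.raises(ValueError, match="exceeds"):
            T.transfer_labels(emb, pd.Series({"s0": 0}), k=2)


class TestRandomForest:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(5)
        n = 120
        X = np.vstack([
            np.column_stack([rng.uniform(3, 5, n // 2), rng.uniform(0, 1, n // 2)]),
            np.column_stack([rng.uniform(0, 1, n // 2), rng.uniform(3, 5, n // 2)]),
        ])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_separable_training_accuracy_one(self, separable):
        X, y = separable
        model = T.train_rf(X, y, ["g1", "g2"], n_trees=50, seed=0)
        assert model.training_accuracy == 1.0

    def test_more_trees_do_not_hurt_heldout(self, separable):
        X, y = separable
        rng = np.random.default_rng(6)
        noisy = X + rng.normal(0, 1.5, X.shape)
        hold = noisy[::3]
        yh = y[::3]
        mask = np.ones(len(y), bool)
        mask[::3] = False
        accs = {}
        for n_trees in (1, 1000):
            m = T.train_rf(noisy[mask], y[mask], ["g1", "g2"], n_trees=n_trees, seed=0)
            accs[n_trees] = (m.clf.predict(hold) == yh).mean()
        assert accs[1000] >= accs[1]

    def test_same_seed_identical_predictions(self, separable):
        X, y = separable
        p1 = T.train_rf(X, y, ["g1", "g2"], n_trees=20, seed=3).clf.predict(X)
        p2 = T.train_rf(X, y, ["g1", "g2"], n_trees=20, seed=3).clf.predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_label_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="single cluster"):
            model = T.train_rf(np.ones((5, 2)), np.zeros(5), ["g1", "g2"])
        pred = T.predict_clusters(model, np.zeros((3, 2)), ["a", "b", "c"], ["g1", "g2"])
        assert set(pred) == {0}

    def test_prediction_labels_subset_of_training(self, separable):
        X, y = separable
        model = T.train_rf(X, y, ["g1", "g2"], n_trees=20, seed=0)
        rng = np.random.default_rng(7)
        pred = T.predict_clusters(
            model, rng.uniform(-5, 10, (50, 2)), range(50), ["g1", "g2"]
        )
        assert set(pred) <= set(model.classes)

    def test_gene_mismatch_rejected(self, separable):
        X, y = separable
        model = T.train_rf(X, y, ["g1", "g2"], n_trees=5, seed=0)
        with pytest.raises(ValueError, match="feature genes"):
            T.predict_clusters(model, X, range(len(X)), ["g1", "gX"])

    def test_all_zero_cell_gets_some_label(self, separable):
        X, y = separable
        model = T.train_rf(X, y, ["g1", "g2"], n_trees=5, seed=0)
        pred = T.predict_clusters(model, np.zeros((1, 2)), ["z"], ["g1", "g2"])
        assert pred.iloc[0] in set(model.classes)
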