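"""MLP training, embedding extraction, MCC scoring, and APD-point assembly."""

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from apdkit.model_bench import (
    APDPoint,
    EmbeddingSet,
    MLPConfig,
    aggregate_apd,
    build_apd_point,
    envelope_violation_fraction,
    extract_embeddings,
    mcc,
    train_mlp,
    train_test_apd_point,
)
from apdkit.synthetic_data import gen_blobs

FAST = MLPConfig(epochs=30, seed=0)


class TestMCC:
    def test_perfect_prediction(self):
        assert mcc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_inverted_prediction(self):
        assert mcc([0, 1, 0, 1], [1, 0, 1, 0]) == -1.0

    def test_hand_evaluated_confusion(self):
        # TP=2, TN=2, FP=1, FN=1 -> (4-1)/sqrt(3^4) = 1/3
        y_true = [1, 1, 1, 0, 0, 0]
        y_pred = [1, 1, 0, 0, 0, 1]
        assert mcc(y_true, y_pred) == pytest.approx(1.0 / 3.0)

    def test_zero_denominator_convention(self):
        assert mcc([0, 0, 0], [0, 0, 0]) == 0.0

    def test_simultaneous_label_flip_symmetry(self, rng):
        y_true = rng.integers(0, 2, 30)
        y_pred = rng.integers(0, 2, 30)
        assert mcc(y_true, y_pred) == pytest.approx(mcc(1 - y_true, 1 - y_pred))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcc([0, 1], [0, 1, 0])


class TestTrainMLP:
    def test_separable_blobs_reach_high_mcc(self):
        X, y = gen_blobs(seed=0)
        itr, ite = train_test_split(np.arange(len(y)), test_size=0.2,
                                    stratify=y, random_state=0)
        model = train_mlp(X[itr], y[itr], FAST)
        assert mcc(y[ite], model.predict(X[ite])) >= 0.9

    def test_seed_determinism_bit_identical(self):
        X, y = gen_blobs(n=500, separation=3.0, seed=1)
        a = train_mlp(X, y, MLPConfig(seed=5)).predict(X)
        b = train_mlp(X, y, MLPConfig(seed=5)).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_labels_rejected(self):
        X, _ = gen_blobs(n=100, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_mlp(X, np.zeros(100, dtype=int), FAST)

    def test_binary_features_skip_scaling(self, rng):
        X = rng.integers(0, 2, (100, 8)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        model = train_mlp(X, y, FAST)
        assert model.scaler is None


class TestExtractEmbeddings:
    def test_shape_and_nonnegativity(self):
        X, y = gen_blobs(n=300, seed=2)
        model = train_mlp(X, y, FAST)
        emb = extract_embeddings(model, X)
        assert emb.matrix.shape == (300, FAST.hidden_dim)
        assert np.all(emb.matrix >= 0.0)  # post-ReLU

    def test_identical_rows_give_identical_embeddings(self):
        X, y = gen_blobs(n=200, seed=3)
        model = train_mlp(X, y, FAST)
        Xdup = np.vstack([X[:1], X[:1], X[1:]])
        emb = extract_embeddings(model, Xdup)
        np.testing.assert_array_equal(emb.matrix[0], emb.matrix[1])

    def test_matches_layerwise_forward_oracle(self):
        X, y = gen_blobs(n=200, seed=4)
        model = train_mlp(X, y, MLPConfig(seed=4, scale_features=False))
        emb = extract_embeddings(model, X)
        est = model.estimator
        # independent layer-by-layer replay
        h = np.maximum(X @ est.coefs_[0] + est.intercepts_[0], 0.0)
        h = np.maximum(h @ est.coefs_[1] + est.intercepts_[1], 0.0)
        np.testing.assert_allclose(emb.matrix, h, atol=1e-12)

    def test_width_mismatch(self):
        X, y = gen_blobs(n=100, seed=5)
        model = train_mlp(X, y, FAST)
        with pytest.raises(ValueError, match="width"):
            extract_embeddings(model, np.ones((5, 7)))


class TestAPDPoints:
    def make_embedding(self, rng, tag, values=None):
        values = rng.standard_normal((20, 6)) if values is None else values
        return EmbeddingSet(matrix=values, sample_ids=tuple(range(20)),
                            representation_tag=tag)

    def test_equal_mcc_gives_zero_gap(self, rng):
        p = build_apd_point("d", self.make_embedding(rng, "A"),
                            self.make_embedding(rng, "B"), 0.5, 0.5)
        assert p.perf_diff == 0.0

    def test_identical_embeddings_align_to_one(self, rng):
        vals = rng.standard_normal((20, 6))
        p = build_apd_point("d", self.make_embedding(rng, "A", vals),
                            self.make_embedding(rng, "B", vals.copy()), 0.2, 0.7)
        assert p.alignment == pytest.approx(1.0, abs=1e-10)
        assert p.perf_diff == pytest.approx(0.5)

    def test_alignment_matches_hsic_oracle(self, rng):
        from test_repr_align import hsic_cka_oracle

        ea = self.make_embedding(rng, "A")
        eb = self.make_embedding(rng, "B")
        p = build_apd_point("d", ea, eb, 0.1, 0.2)
        Xc = ea.matrix - ea.matrix.mean(axis=0)
        Zc = eb.matrix - eb.matrix.mean(axis=0)
        assert p.alignment == pytest.approx(hsic_cka_oracle(Xc, Zc), abs=1e-10)

    def test_sample_mismatch_errors(self, rng):
        ea = self.make_embedding(rng, "A")
        eb = EmbeddingSet(matrix=rng.standard_normal((20, 6)),
                          sample_ids=tuple(range(1, 21)), representation_tag="B")
        with pytest.raises(ValueError, match="same samples"):
            build_apd_point("d", ea, eb, 0.1, 0.2)


class TestAggregateAPD:
    @staticmethod
    def point(ds, align, diff):
        return APDPoint(dataset_id=ds, pair=("A", "B"), alignment=align,
                        perf_diff=diff, mcc_a=diff / 2, mcc_b=-diff / 2)

    def test_single_point_convention(self):
        out = aggregate_apd([self.point("d1", 0.4, 0.1)])
        row = out.iloc[0]
        assert row.alignment_mean == 0.4 and row.alignment_std == 0.0
        assert row.n_pairs == 1

    def test_two_point_mean(self):
        out = aggregate_apd([self.point("d", 0.2, 0.1), self.point("d", 0.4, 0.3)])
        assert out.iloc[0].alignment_mean == pytest.approx(0.3)
        assert out.iloc[0].perf_diff_mean == pytest.approx(0.2)

    def test_matches_groupby_oracle_on_many_points(self, rng):
        pts = [self.point(f"d{rng.integers(0, 12)}", rng.random(), rng.random())
               for _ in range(253)]
        out = aggregate_apd(pts).set_index("dataset_id")
        # brute-force recomputation
        by_ds = {}
        for p in pts:
            by_ds.setdefault(p.dataset_id, []).append(p)
        for ds, group in by_ds.items():
            a = np.array([p.alignment for p in group])
            assert out.loc[ds].alignment_mean == pytest.approx(a.mean())
            expected_std = a.std(ddof=1) if len(a) > 1 else 0.0
            assert out.loc[ds].alignment_std == pytest.approx(expected_std)

    def test_envelope_fraction_matches_brute_force(self, rng):
        pts = [self.point("d", rng.random(), rng.random()) for _ in range(100)]
        frac = envelope_violation_fraction(pts)
        brute = sum(p.perf_diff > 1 - p.alignment for p in pts) / 100
        assert frac == pytest.approx(brute)


class TestEndToEndAPD:
    def test_two_noisy_views_give_valid_point(self):
        from apdkit.synthetic_data import ReprGenConfig, gen_representations

        reps, labels = gen_representations(
            ReprGenConfig(n_samples=400, latent_dim=4, output_dims=(6, 6),
                          noise_scales=(0.1, 0.1), seed=0)
        )
        p = train_test_apd_point("synth", reps[0].values, reps[1].values, labels,
                                 config=MLPConfig(seed=0))
        assert 0.0 <= p.alignment <= 1.0
        assert p.perf_diff == pytest.approx(abs(p.mcc_a - p.mcc_b))
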