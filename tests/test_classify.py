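"""GP classification: kernel/inference correctness, LOO evaluation,
permutation significance, weight maps."""

import numpy as np
import pytest

from conntrace import (SyntheticConfig, make_cohort, random_connected_edges,
                       devectorize, gpc_fit, loo_cv, permutation_significance,
                       threshold_weights, vectorize, weight_map)
from conntrace.classify import LinearGPC, _confusion_and_scores


@pytest.fixture(scope="module")
def separable_cohort():
    planted = random_connected_edges(15, 60, np.random.default_rng(7))
    cfg = SyntheticConfig(n_regions=60, n_subjects_a=18, n_subjects_b=18,
                          planted_edges=planted, effect_ratio=8.0,
                          edge_density=0.3, seed=21)
    return make_cohort(cfg)


class TestVectorize:
    def test_three_node_convention(self):
        from conntrace import Cohort
        M = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        c = Cohort(matrices=np.stack([M, M]), groups=np.array(["A", "B"]))
        feats = vectorize(c)
        assert feats.X[0].tolist() == [1, 2, 3]
        assert feats.edge_index == [(0, 1), (0, 2), (1, 2)]

    def test_devectorize_roundtrip(self):
        rng = np.random.default_rng(0)
        n = 7
        M = rng.integers(0, 9, size=(n, n))
        M = np.triu(M, 1)
        M = M + M.T
        iu = np.triu_indices(n, 1)
        assert np.array_equal(devectorize(M[iu], n), M)

    def test_column_edge_map_roundtrips(self, separable_cohort):
        cohort, _ = separable_cohort
        feats = vectorize(cohort)
        rng = np.random.default_rng(1)
        for j in rng.integers(0, len(feats.edge_index), size=10):
            i, k = feats.edge_index[j]
            assert np.array_equal(feats.X[:, j], cohort.matrices[:, i, k])


class TestGPCFit:
    def test_contradictory_duplicate_near_half(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        X = np.vstack([X, X[0]])  # same point, both labels
        y = np.array(["A"] * 5 + ["B"] * 5 + ["B"])
        y[0] = "A"
        m = gpc_fit(X, y, optimize=False)
        p = m.predict_proba(X[:1])
        assert abs(p[0] - 0.5) < 0.2

    def test_label_swap_flips_probabilities(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        y = np.array(["A", "B"] * 6)
        m1 = gpc_fit(X, y, optimize=False)
        y_sw = np.where(y == "A", "B", "A")
        m2 = gpc_fit(X, y_sw, optimize=False)
        p1 = m1.predict_proba(X)
        p2 = m2.predict_proba(X)
        assert np.allclose(p1, 1 - p2, atol=1e-8)

    def test_separable_training_confidence(self, separable_cohort):
        cohort, _ = separable_cohort
        feats = vectorize(cohort)
        m = gpc_fit(feats, cohort.groups, optimize=True)
        is_b = cohort.groups == "B"
        # plugin (MAP) probabilities are sharp on separable data
        p_plug = m.predict_proba(feats.X, method="plugin")
        assert np.all(p_plug[is_b] > 0.9)
        assert np.all(p_plug[~is_b] < 0.1)
        # the averaged predictive is moderated but classifies identically
        p_avg = m.predict_proba(feats.X)
        assert np.all((p_avg > 0.5) == (p_plug > 0.5))
        assert np.all(p_avg[is_b] > 0.8)
        assert np.all(p_avg[~is_b] < 0.2)

    def test_single_class_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError, match="2 classes"):
            gpc_fit(X, np.array(["A"] * 4))


class TestRepresenterIdentity:
    def test_latent_equals_primal_on_every_fold(self, separable_cohort):
        """f(x) - bias-term = w . x for the linear kernel, per LOO fold."""
        cohort, _ = separable_cohort
        feats = vectorize(cohort)
        X, y = feats.X, cohort.groups
        rng = np.random.default_rng(4)
        for i in rng.choice(len(y), size=6, replace=False):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            m = LinearGPC(optimize=False).fit(X[mask], y[mask])
            w, b = m.primal_weights()
            f, _ = m.latent(X[i:i + 1])
            assert abs(f[0] - b - w @ (X[i] - m.mean_)) < 1e-6

    def test_zero_feature_column_zero_weight(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        X[:, 2] = 0.0
        y = np.array(["A", "B"] * 5)
        m = gpc_fit(X, y, optimize=False, center=False)
        w, _ = m.primal_weights()
        assert w[2] == 0.0


class TestLooCV:
    def test_confusion_arithmetic(self):
        """Pooled confusion [[17,1],[4,14]] (rows = predicted class):
        accuracy 31/36, predictive values 17/18 and 14/18."""
        labels, preds = [], []
        for true_c, pred_c, k in (("A", "A", 17), ("B", "A", 1),
                                  ("A", "B", 4), ("B", "B", 14)):
            labels += [true_c] * k
            preds += [pred_c] * k
        conf, acc, pv = _confusion_and_scores(labels, preds, ["A", "B"])
        assert acc == pytest.approx(31 / 36)
        assert pv["A"] == pytest.approx(17 / 18)   # 94.4%
        assert pv["B"] == pytest.approx(14 / 18)   # 77.8%

    def test_perfect_prediction_metrics(self, separable_cohort):
        cohort, _ = separable_cohort
        feats = vectorize(cohort)
        res = loo_cv(feats, cohort.groups, optimize=False)
        assert res.accuracy >= 0.9
        if res.accuracy == 1.0:
            assert res.predictive_value["A"] == 1.0
            assert res.predictive_value["B"] == 1.0
        assert res.confusion.sum() == cohort.n_subjects
        # accuracy is the mean of per-fold correctness
        assert res.accuracy == pytest.approx(
            np.mean([p == t for p, t in zip(res.predictions, res.labels)]))

    def test_minimum_size_enforced(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError, match="n >= 4"):
            loo_cv(X, np.array(["A", "A", "B"]))

    def test_single_class_fold_flagged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 3))
        y = np.array(["A"] * 5 + ["B"])  # the lone B's fold trains single-class
        with pytest.raises(ValueError, match="single-class; fold flagged"):
            loo_cv(X, y, optimize=False)

    def test_feature_scaling_invariance_with_refit(self, separable_cohort):
        """Scaling all features by a positive constant must not change
        LOO predictions when the kernel scale is refit."""
        cohort, _ = separable_cohort
        feats = vectorize(cohort)
        r1 = loo_cv(feats.X, cohort.groups, optimize=True, compute_weights=False)
        r2 = loo_cv(feats.X * 7.5, cohort.groups, optimize=True,
                    compute_weights=False)
        assert list(r1.predictions) == list(r2.predictions)


class TestPermutationSignificance:
    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 4))
        y = np.array(["A", "B"] * 4)
        p1 = permutation_significance(X, y, "accuracy", n_perm=20, seed=11,
                                      optimize=False)
        p2 = permutation_significance(X, y, "accuracy", n_perm=20, seed=11,
                                      optimize=False)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_separable_data_significant(self, separable_cohort):
        cohort, _ = separable_cohort
        feats = vectorize(cohort)
        p = permutation_significance(feats, cohort.groups, "accuracy",
                                     n_perm=39, seed=1, optimize=False)
        assert p <= 1 / 40 + 1e-12  # observed beats every permutation

    def test_null_pvalues_roughly_uniform(self):
        """On null cohorts the permutation p-value should be ~Uniform(0,1]
        (coarse check: mean in the middle, no pile-up at the bottom)."""
        rng = np.random.default_rng(13)
        ps = []
        for r in range(12):
            X = rng.normal(size=(8, 10))
            y = np.array(["A"] * 4 + ["B"] * 4)
            ps.append(permutation_significance(X, y, "accuracy", n_perm=19,
                                               seed=100 + r, optimize=False))
        assert 0.25 < np.mean(ps) < 0.85
        assert np.mean(np.array(ps) <= 0.1) < 0.5

    def test_nperm_validation(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(np.zeros((4, 2)),
                                     np.array(["A", "A", "B", "B"]),
                                     "accuracy", n_perm=0)


class TestWeights:
    def test_planted_edges_carry_more_weight(self, separable_cohort):
        cohort, truth = separable_cohort
        feats = vectorize(cohort)
        m = gpc_fit(feats, cohort.groups, optimize=False)
        W = weight_map(m, feats)
        assert np.allclose(W, W.T)
        planted = np.array([abs(W[i, j]) for i, j in truth.planted_edges])
        iu = np.triu_indices(60, 1)
        assert planted.mean() > 3 * np.abs(W[iu]).mean()

    def test_threshold_weights_arithmetic(self):
        W = devectorize(np.array([4., 3., 2., 1., 0., 0.]), 4)
        edges, frac = threshold_weights(W, 0.25)  # top 1 of 4 nonzero
        assert len(edges) == 1
        assert edges[0][2] == 4.0
        assert frac == pytest.approx(0.4)

    def test_keep_all_returns_everything(self):
        W = devectorize(np.array([4., 3., 2., 1., 0., 0.]), 4)
        edges, frac = threshold_weights(W, 1.0)
        assert len(edges) == 4
        assert frac == pytest.approx(1.0)

    def test_retained_fraction_monotone(self):
        rng = np.random.default_rng(8)
        W = devectorize(rng.normal(size=45), 10)
        fracs = [threshold_weights(W, kf)[1]
                 for kf in (0.1, 0.3, 0.5, 0.8, 1.0)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_keep_fraction_validated(self):
        with pytest.raises(ValueError, match="keep_fraction"):
            threshold_weights(np.zeros((3, 3)), 0.0)
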