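import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from memdecode import classify as cl
from memdecode._cnn import CNNConfig, CompactCNN


class TestFolds:
    def test_even_partition(self):
        f = cl.make_folds(100, 5, seed=1)
        sizes = np.bincount(f)
        assert list(sizes) == [20] * 5

    def test_remainder_rule(self):
        f = cl.make_folds(101, 5, seed=1)
        assert sorted(np.bincount(f), reverse=True) == [21, 20, 20, 20, 20]

    def test_deterministic_and_covering(self):
        a = cl.make_folds(57, 5, seed=7)
        b = cl.make_folds(57, 5, seed=7)
        assert np.array_equal(a, b)
        assert set(a) == set(range(5))


class TestSMOTE:
    def test_synthetic_points_on_segment(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 0.0], [6.0, 1.0], [7.0, 0.0], [8.0, 1.0]])
        y = np.array([0, 0, 1, 1, 1, 1])
        Xb, yb = cl.smote(X, y, k_neighbors=1, seed=0)
        synth = Xb[len(X):]
        assert len(synth) == 2
        # minority pair (0,0)-(1,1): every synthetic point has equal coords in [0,1]
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0) & (synth <= 1))

    def test_upsamples_to_majority_count(self, rng):
        X = rng.standard_normal((140, 6))
        y = np.array([0] * 40 + [1] * 100)
        Xb, yb = cl.smote(X, y, seed=3)
        counts = np.bincount(yb)
        assert counts[0] == counts[1] == 100
        assert np.array_equal(Xb[:140], X)  # originals untouched

    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0] * 10 + [1] * 10)
        Xb, yb = cl.smote(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_small_minority_reduces_k_with_warning(self, rng):
        X = rng.standard_normal((13, 4))
        y = np.array([0] * 3 + [1] * 10)
        with pytest.warns(UserWarning, match="k="):
            Xb, yb = cl.smote(X, y, k_neighbors=5, seed=0)
        assert np.bincount(yb)[0] == 10


class TestShrinkageFormula:
    def test_diagonal_example(self):
        sigma = np.diag([2.0, 4.0])
        out = cl.shrink_covariance(sigma, 0.5)
        assert np.allclose(out, np.diag([2.5, 3.5]))  # v = 3

    def test_eigendecomposition_identity_random_psd(self, rng):
        """Σ(γ) = V((1−γ)D + γvI)Vᵀ on random PSD matrices to 1e-8."""
        for _ in range(100):
            d = rng.integers(2, 8)
            A = rng.standard_normal((d, d + 2))
            sigma = A @ A.T
            gamma = rng.random()
            direct = cl.shrink_covariance(sigma, gamma)
            w, V = np.linalg.eigh(sigma)
            v = np.trace(sigma) / d
            eig_form = V @ np.diag((1 - gamma) * w + gamma * v) @ V.T
            assert np.allclose(direct, eig_form, atol=1e-8)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            cl.shrink_covariance(np.eye(2), 1.5)


class TestShrinkageLDA:
    def _toy(self, rng, n=200, d=6, sep=3.0):
        X0 = rng.standard_normal((n // 2, d))
        X1 = rng.standard_normal((n // 2, d)) + sep / np.sqrt(d)
        X = np.vstack([X0, X1])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_gamma0_matches_sklearn_lda(self, rng):
        X, y = self._toy(rng)
        ours = cl.ShrinkageLDA(gamma=0.0).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.0).fit(X, y)
        assert np.array_equal(ours.predict(X), ref.predict(X))

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_matches_sklearn_shrunk_decision(self, rng, gamma):
        # sklearn's 'lsqr' + shrinkage implements the same shrunk-covariance
        # discriminant; decisions must agree on a well-conditioned problem
        X, y = self._toy(rng)
        ours = cl.ShrinkageLDA(gamma=gamma).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=gamma).fit(X, y)
        assert np.mean(ours.predict(X) == ref.predict(X)) == 1.0

    def test_gamma1_direction_parallel_to_mean_difference(self, rng):
        X, y = self._toy(rng)
        model = cl.ShrinkageLDA(gamma=1.0).fit(X, y)
        delta = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        cos = model.w @ delta / (np.linalg.norm(model.w) * np.linalg.norm(delta))
        assert cos > 1.0 - 1e-10

    def test_woodbury_path_matches_direct_solve(self, rng):
        """Wide problem (d >> n): the Gram-matrix solve must reproduce the
        explicit d × d shrunk-covariance solve to high precision."""
        n, d = 40, 500
        X = rng.standard_normal((n, d))
        y = np.array([0] * 15 + [1] * 25)
        X[y == 1] += 0.3
        gamma = 0.3
        model = cl.ShrinkageLDA(gamma=gamma).fit(X, y)  # takes Woodbury branch
        mu = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
        Xc = X.copy()
        for i, c in enumerate((0, 1)):
            Xc[y == c] -= mu[i]
        sigma = Xc.T @ Xc / n
        w_direct = np.linalg.solve(cl.shrink_covariance(sigma, gamma), mu[1] - mu[0])
        scores_direct = X @ w_direct - 0.5 * w_direct @ (mu[0] + mu[1]) + np.log(25 / 15)
        assert np.allclose(model.decision_scores(X), scores_direct, rtol=1e-8, atol=1e-8)


class TestEvaluate:
    def test_perfect_and_constant_scores(self):
        y = np.array([0, 0, 1, 1])
        assert cl.evaluate(np.array([0.1, 0.2, 0.8, 0.9]), y)["auc_pct"] == 100.0
        assert cl.evaluate(np.zeros(4), y)["auc_pct"] == 50.0  # midrank ties

    def test_brute_force_pairwise_auc(self, rng):
        scores = rng.standard_normal(30)
        y = (rng.random(30) < 0.4).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        brute = wins / (len(pos) * len(neg)) * 100.0
        assert np.isclose(cl.evaluate(scores, y)["auc_pct"], brute)

    def test_swap_example(self):
        y = np.array([0, 0, 1, 1])
        assert cl.evaluate(np.array([0.6, 0.7, 0.8, 0.9]), y)["auc_pct"] == 100.0
        assert cl.evaluate(np.array([0.6, 0.8, 0.7, 0.9]), y)["auc_pct"] == 75.0

    def test_confusion_rows_normalized(self):
        y = np.array([0, 0, 1, 1, 1])
        out = cl.evaluate(np.array([-1.0, 1.0, 1.0, 1.0, -1.0]), y)
        assert np.allclose(out["confusion"].sum(axis=1), 1.0)
        assert np.isclose(out["confusion"][1, 1], 2 / 3)


class TestCNN:
    def test_separable_classes_high_auc(self, rng):
        n, C, T = 160, 8, 20
        y = np.array([0, 1] * (n // 2))
        X = rng.standard_normal((n, C, T))
        X[y == 1] += 5.0 / np.sqrt(C * T) * 4
        cfg = CNNConfig(n_filters=4, epochs=30, seed=0)
        idx = rng.permutation(n)
        tr, te = idx[:120], idx[120:]
        model = CompactCNN(cfg).fit(X[tr], y[tr])
        auc = roc_auc_score(y[te], model.decision_scores(X[te]))
        assert auc > 0.99

    def test_shuffled_labels_near_chance(self, rng):
        n, C, T = 400, 6, 16
        X = rng.standard_normal((n, C, T))
        y = (rng.random(n) < 0.5).astype(int)
        cfg = CNNConfig(n_filters=2, epochs=10, seed=1)
        model = CompactCNN(cfg).fit(X[:300], y[:300])
        auc = roc_auc_score(y[300:], model.decision_scores(X[300:]))
        assert 0.4 <= auc <= 0.6

    def test_same_seed_identical_weights(self, rng):
        X = rng.standard_normal((60, 5, 12))
        y = (rng.random(60) < 0.5).astype(int)
        cfg = CNNConfig(n_filters=3, epochs=5, seed=9)
        h1 = CompactCNN(cfg).fit(X, y).weights_hash()
        h2 = CompactCNN(cfg).fit(X, y).weights_hash()
        assert h1 == h2


class TestCrossValidation:
    def test_no_leakage_smote_confined_to_training_folds(self, rng):
        """Held-out scores must be produced for exactly the original trials
        and the fold partition must cover them disjointly."""
        n = 60
        X = rng.standard_normal((n, 4, 10))
        y = np.array([0] * 15 + [1] * 45)
        folds = cl.make_folds(n, 5, seed=0)
        rep = cl.cross_validate_cell(X, y, "rlda", folds, seed=0)
        assert rep.scores.shape == (n,)
        assert set(folds) == set(range(5))

    def test_fold_reuse_across_models(self, rng):
        n = 50
        X = rng.standard_normal((n, 3, 12))
        y = np.array([0] * 20 + [1] * 30)
        folds = cl.make_folds(n, 5, seed=4)
        r1 = cl.cross_validate_cell(X, y, "rlda", folds, seed=4)
        r2 = cl.cross_validate_cell(X, y, "cnn", folds, seed=4, cnn_config=CNNConfig(n_filters=2, epochs=3))
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)

    def test_mean_coded_signal_recovered(self, rng):
        n = 80
        y = np.array([0] * 25 + [1] * 55)
        X = rng.standard_normal((n, 4, 10))
        X[y == 1] += 0.8
        folds = cl.make_folds(n, 5, seed=2)
        rep = cl.cross_validate_cell(X, y, "rlda", folds, seed=2)
        assert rep.pooled_auc_pct > 85.0


class TestPermutationNull:
    def test_null_centered_at_chance(self, rng):
        scores = [rng.standard_normal(60) for _ in range(5)]
        labels = [(rng.random(60) < 0.7).astype(int) for _ in range(5)]
        folds = [cl.make_folds(60, 5, seed=i) for i in range(5)]
        null = cl.permutation_null_mean_auc(scores, labels, folds, 400, seed=0)
        assert abs(np.mean(null) - 50.0) < 1.5
        assert np.percentile(null, 95) < 60.0

    def test_null_band_covers_null_cv_statistic(self, rng):
        """A classifier trained on pure noise should land inside the
        permutation band ~95% of the time (fold-matched statistic)."""
        hits = 0
        for rep_i in range(12):
            n = 50
            X = rng.standard_normal((n, 3, 10))
            y = (rng.random(n) < 0.75).astype(int)
            if len(np.unique(y)) < 2 or min(np.bincount(y)) < 6:
                y[:6] = 0
            folds = cl.make_folds(n, 5, seed=rep_i)
            rep = cl.cross_validate_cell(X, y, "rlda", folds, seed=rep_i)
            null = cl.permutation_null_mean_auc([rep.scores], [y], [folds], 100, seed=rep_i)
            lo, hi = np.nanpercentile(null, [2.5, 97.5])
            hits += lo <= rep.auc_pct <= hi
        assert hits >= 9  # ~95% coverage, binomial slack


class TestShrinkageProperties:
    from hypothesis import given, settings, strategies as hst

    @given(hst.integers(min_value=2, max_value=10), hst.floats(min_value=0.0, max_value=1.0),
           hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_shrunk_covariance_psd_and_trace_preserving(self, d, gamma, seed):
        rng2 = np.random.default_rng(seed)
        A = rng2.standard_normal((d, d + 1))
        sigma = A @ A.T
        out = cl.shrink_covariance(sigma, gamma)
        assert np.allclose(out, out.T)
        assert np.linalg.eigvalsh(out).min() > -1e-9 * max(1.0, np.trace(sigma))
        assert np.isclose(np.trace(out), np.trace(sigma))  # trace invariant

    @given(hst.integers(min_value=10, max_value=200), hst.integers(min_value=2, max_value=9),
           hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_folds_partition_trials(self, n, k, seed):
        if n < k:
            n = k
        f = cl.make_folds(n, k, seed)
        sizes = np.bincount(f, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
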