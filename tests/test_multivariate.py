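"""Statistics layer: Pearson matrices, correlation PCA, discriminant model."""

import numpy as np
import pandas as pd
import pytest

import halophen as hp
from conftest import FEATURES


def brute_force_pearson(x, y):
    """Two-pass covariance / (sx·sy) oracle."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = (sum((a - mx) ** 2 for a in x) / (n - 1)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / (n - 1)) ** 0.5
    return cov / (sx * sy)


class TestPearson:
    def test_self_and_anticorrelation(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 5, 8], "y": [-1.0, -2, -3, -5, -8]})
        r, p, sig = hp.pearson_matrix(t, ["x", "y"])
        assert r.loc["x", "x"] == pytest.approx(1.0)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert sig.loc["x", "y"]

    def test_hand_table_matches_brute_force(self):
        t = pd.DataFrame({"u": [2.0, 4, 1, 7, 5], "v": [3.0, 1, 4, 9, 6]})
        r, p, _ = hp.pearson_matrix(t, ["u", "v"])
        assert r.loc["u", "v"] == pytest.approx(brute_force_pearson(t["u"], t["v"]), abs=1e-12)
        # p-value from the t distribution with n-2 df
        from scipy import stats

        rv = r.loc["u", "v"]
        tt = rv * np.sqrt(3 / (1 - rv**2))
        assert p.loc["u", "v"] == pytest.approx(2 * stats.t.sf(abs(tt), 3), abs=1e-12)

    def test_random_table_matches_brute_force(self, rng):
        t = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        r, _, _ = hp.pearson_matrix(t, list("abcd"))
        for i in "abcd":
            for j in "abcd":
                assert r.loc[i, j] == pytest.approx(
                    brute_force_pearson(t[i], t[j]), abs=1e-12
                )

    def test_zero_variance_column_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="zero-variance"):
            hp.pearson_matrix(t, ["x", "c"])

    def test_too_few_rows_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2], "y": [2.0, 1]})
        with pytest.raises(ValueError):
            hp.pearson_matrix(t, ["x", "y"])


class TestCorrelationPCA:
    def test_two_variable_closed_form(self, rng):
        # for a 2x2 correlation matrix the eigenvalues are 1 ± r
        z = rng.normal(size=200)
        t = pd.DataFrame({"x": z + rng.normal(size=200), "y": z - rng.normal(size=200)})
        r = np.corrcoef(t["x"], t["y"])[0, 1]
        result = hp.pca(t, ["x", "y"])
        np.testing.assert_allclose(
            result.eigenvalues_, sorted([1 + abs(r), 1 - abs(r)], reverse=True), atol=1e-12
        )

    def test_trace_and_contribution_conservation(self, trial):
        result = hp.pca(trial, FEATURES)
        assert result.eigenvalues_.sum() == pytest.approx(len(FEATURES), abs=1e-9)
        np.testing.assert_allclose(result.contributions_.sum(axis=0), 100.0, atol=1e-9)
        np.testing.assert_allclose(
            (result.loadings_**2).sum(axis=0), result.eigenvalues_, atol=1e-9
        )

    def test_loadings_reconstruct_correlation(self, trial):
        result = hp.pca(trial, FEATURES)
        L = result.loadings_.to_numpy()
        np.testing.assert_allclose(
            L @ L.T, np.corrcoef(trial[FEATURES].to_numpy(), rowvar=False), atol=1e-9
        )

    def test_constant_column_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            hp.pca(t, ["x", "c"])

    def test_more_variables_than_rows_rejected(self, rng):
        t = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            hp.pca(t, list("abcd"))


def brute_force_scores(X, means, cov, priors):
    """Shared-covariance Gaussian discriminant score, computed longhand."""
    prec = np.linalg.inv(cov)
    out = []
    for x in X:
        row = []
        for mu, pi in zip(means, priors):
            row.append(x @ prec @ mu - 0.5 * mu @ prec @ mu + np.log(pi))
        out.append(row)
    return np.array(out)


class TestDiscriminant:
    def test_separated_classes_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 1, (30, 3))])
        y = np.array(["lo"] * 30 + ["hi"] * 30)
        model = hp.PooledCovarianceLDA().fit(X, y)
        assert model.score(X, y) == 1.0

    def test_class_means_assigned_to_own_class(self, trial):
        model = hp.lda_fit(trial, FEATURES, "class")
        pred = model.predict(model.means_)
        np.testing.assert_array_equal(pred, model.classes_)

    def test_posteriors_match_brute_force_oracle(self, rng):
        X = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(3, 1, (5, 2)), rng.normal(6, 1, (4, 2))])
        y = np.repeat(["a", "b", "c"], [5, 5, 4])
        model = hp.PooledCovarianceLDA().fit(X, y)
        scores = brute_force_scores(X, model.means_, model.covariance_, model.priors_)
        expd = np.exp(scores - scores.max(axis=1, keepdims=True))
        np.testing.assert_allclose(
            model.predict_proba(X), expd / expd.sum(axis=1, keepdims=True), atol=1e-10
        )

    def test_two_class_equal_priors_reduce_to_projection_sign(self, rng):
        # with 2 equal-prior classes the decision reduces to the sign of the
        # (whitened) projection onto the mean difference
        mu = np.array([2.0, -1.0, 0.5])
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(0, 1, (40, 3)) + mu])
        y = np.array([0] * 40 + [1] * 40)
        model = hp.PooledCovarianceLDA().fit(X, y)
        m0, m1 = model.means_
        prec = np.linalg.inv(model.covariance_)
        projection = (X - (m0 + m1) / 2) @ prec @ (m1 - m0)
        np.testing.assert_array_equal(
            model.predict(X), model.classes_[(projection > 0).astype(int)]
        )

    def test_matches_sklearn_reference(self, trial):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = trial[FEATURES].to_numpy(float)
        y = trial["class"].to_numpy()
        mine = hp.PooledCovarianceLDA().fit(X, y)
        ref = LinearDiscriminantAnalysis().fit(X, y)
        np.testing.assert_array_equal(mine.predict(X), ref.predict(X))
        np.testing.assert_allclose(mine.predict_proba(X), ref.predict_proba(X), atol=1e-8)

    def test_posteriors_sum_to_one_and_order_invariant(self, trial):
        model = hp.lda_fit(trial, FEATURES, "class")
        pred, post = hp.lda_classify(model, trial)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        permuted = list(reversed(FEATURES))
        model2 = hp.lda_fit(trial, permuted, "class")
        pred2, _ = hp.lda_classify(model2, trial)
        np.testing.assert_array_equal(pred, pred2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hp.PooledCovarianceLDA().fit(np.ones((5, 2)), np.zeros(5))

    def test_singular_covariance_ridge_warns(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.hstack([X, X[:, :1]])  # duplicated feature -> singular pooled cov
        y = np.array([0] * 10 + [1] * 10)
        with pytest.warns(RuntimeWarning, match="ridge"):
            model = hp.PooledCovarianceLDA().fit(X, y)
        assert np.all(np.isfinite(model.coef_))


class TestCrossValidation:
    def test_separable_classes_give_diagonal_matrix(self, rng):
        X = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(12, 1, (12, 2))])
        t = pd.DataFrame(X, columns=["f1", "f2"])
        t["g"] = ["a"] * 12 + ["b"] * 12
        cm = hp.loo_cross_validate(t, ["f1", "f2"], "g")
        np.testing.assert_array_equal(cm.counts, np.diag([12, 12]))

    def test_singleton_class_fold_rejected(self):
        t = pd.DataFrame({"f": [0.0, 1.0], "g": ["a", "b"]})
        with pytest.raises(ValueError):
            hp.loo_cross_validate(t, ["f"], "g")

    def test_row_order_invariance(self, rng):
        X = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(5, 1, (8, 2))])
        t = pd.DataFrame(X, columns=["f1", "f2"])
        t["g"] = ["a"] * 8 + ["b"] * 8
        cm1 = hp.loo_cross_validate(t, ["f1", "f2"], "g")
        shuffled = t.sample(frac=1, random_state=0).reset_index(drop=True)
        cm2 = hp.loo_cross_validate(shuffled, ["f1", "f2"], "g")
        np.testing.assert_array_equal(cm1.counts, cm2.counts)


class TestAccuracy:
    def test_identity_matrix_is_all_correct(self):
        cm = hp.ConfusionMatrix(np.eye(3, dtype=int) * 7, ("a", "b", "c"))
        overall, per_class = hp.accuracy_from_matrix(cm)
        assert overall == 100.0
        assert all(v == 100.0 for v in per_class.values())

    def test_rounding_is_half_up_to_two_decimals(self):
        cm = hp.ConfusionMatrix(np.array([[95, 1], [0, 0]]), ("x", "y"))
        overall, per_class = hp.accuracy_from_matrix(cm)
        assert overall == 98.96  # 95/96 = 98.9583...
        assert np.isnan(per_class["y"])  # empty row undefined
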