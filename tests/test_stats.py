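import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from g4therm.phylo import parse_newick
from g4therm.simulate import simulate_bm, yule_tree
from g4therm.stats import (
    PGLS,
    anova_oneway,
    bm_covariance,
    lambda_transform,
    normality_check,
    pearson,
)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_orthogonal_hand_example(self):
        r, _ = pearson([1, 0, -1, 0], [0, 1, 0, -1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0, p0 = pearson(x, y)
        r1, p1 = pearson(3 * x + 7, 0.5 * y - 2)
        assert r1 == pytest.approx(r0) and p1 == pytest.approx(p0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


def rooted(newick):
    t = parse_newick(newick)
    t.is_rooted = True
    return t


class TestBmCovariance:
    def test_path_sum_example(self):
        V = bm_covariance(rooted("((A:1,B:1):1,C:2);"))
        assert V.loc["A", "A"] == 2 and V.loc["C", "C"] == 2
        assert V.loc["A", "B"] == 1
        assert V.loc["A", "C"] == 0 and V.loc["B", "C"] == 0

    def test_near_star_tree_nearly_diagonal(self):
        V = bm_covariance(rooted("((A:1,B:1):0,C:1);"))
        off = V.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0) and np.allclose(np.diag(V.values), 1.0)

    def test_polytomy_at_root_rejected(self):
        with pytest.raises(ValueError, match="root"):
            bm_covariance(rooted("(A:1,B:1,C:1);"))

    def test_unrooted_rejected(self):
        with pytest.raises(ValueError, match="root"):
            bm_covariance(parse_newick("((A:1,B:1):1,C:2);"))

    def test_ultrametric_constant_diagonal(self):
        tree = yule_tree(12, seed=3, depth=1.0)
        V = bm_covariance(tree)
        assert np.allclose(np.diag(V.values), 1.0)
        assert np.all(V.values >= -1e-12)


class TestLambdaTransform:
    def setup_method(self):
        self.V = pd.DataFrame(
            [[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )

    def test_lambda_one_identity(self):
        assert lambda_transform(self.V, 1.0).equals(self.V)

    def test_lambda_zero_diagonal(self):
        out = lambda_transform(self.V, 0.0)
        assert np.allclose(out.values, np.diag([2.0, 2.0, 2.0]))

    def test_lambda_half(self):
        out = lambda_transform(self.V, 0.5)
        assert out.loc["A", "B"] == 0.5 and out.loc["A", "A"] == 2.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lambda_transform(self.V, 1.5)


def ols_reference(y, X):
    """Textbook OLS: coefficients, SEs and t statistics from first
    principles (independent of the PGLS code path)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    s2 = resid @ resid / (n - p)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, beta / se


class TestPGLS:
    def test_lambda_zero_ultrametric_reduces_to_ols(self, rng):
        tree = yule_tree(20, seed=5, depth=1.0)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        x = rng.normal(size=20)
        y = 1.0 + 0.3 * x + rng.normal(size=20)
        X = np.column_stack([np.ones(20), x])
        fit = PGLS(y, X, tree=tree, labels=labels).fit(
            lambda_mode="fixed", lambda_fixed=0.0
        )
        beta, se, t = ols_reference(y, X)
        assert np.allclose(fit.params.values, beta, atol=1e-8)
        assert np.allclose(fit.bse.values, se, atol=1e-8)
        assert np.allclose(fit.tvalues.values, t, atol=1e-8)

    def test_exact_linear_response(self, rng):
        tree = yule_tree(12, seed=2, depth=1.0)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        x = rng.normal(size=12)
        y = 2.0 + 0.5 * x
        X = np.column_stack([np.ones(12), x])
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = PGLS(y, X, tree=tree, labels=labels).fit(
                lambda_mode="fixed", lambda_fixed=1.0
            )
        assert np.allclose(fit.resid, 0.0, atol=1e-10)
        assert fit.pvalues.iloc[1] < 1e-12

    def test_ml_lambda_matches_dense_grid(self, rng):
        tree = yule_tree(40, seed=9, depth=1.0)
        x = simulate_bm(tree, 4.0, 0.0, lambda_true=1.0, seed=10)
        noise = simulate_bm(tree, 1.0, 0.0, lambda_true=0.5, seed=11)
        y = 0.5 * x + noise
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        model = PGLS(y, X, tree=tree, labels=list(x.index))
        fit = model.fit(lambda_mode="ml")
        grid = np.linspace(0, 1, 10001)
        lls = np.array([model.profile_loglik(g) for g in grid])
        assert fit.llf >= lls.max() - 1e-6
        assert abs(fit.lambda_ - grid[np.argmax(lls)]) <= 2e-4 or (
            fit.llf >= lls.max()
        )

    def test_lambda_bounds_respected(self, rng):
        tree = yule_tree(10, seed=1, depth=1.0)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        y = rng.normal(size=10)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        model = PGLS(y, X, tree=tree, labels=labels)
        with pytest.raises(ValueError):
            model.fit(lambda_mode="fixed", lambda_fixed=1.2)
        fit = model.fit()
        assert 0.0 <= fit.lambda_ <= 1.0

    def test_singular_design_errors(self):
        tree = yule_tree(10, seed=1, depth=1.0)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        X = np.ones((10, 2))  # duplicated intercept
        with pytest.raises(ValueError):
            PGLS(np.arange(10.0), X, tree=tree, labels=labels).fit(
                lambda_mode="fixed", lambda_fixed=1.0
            )

    def test_summary_mentions_lambda(self, rng):
        tree = yule_tree(10, seed=4, depth=1.0)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        x = rng.normal(size=10)
        X = pd.DataFrame({"intercept": np.ones(10), "x": x})
        fit = PGLS(x + rng.normal(size=10), X, tree=tree, labels=labels).fit()
        s = fit.summary()
        assert "lambda" in s and "x" in s


class TestNormalityCheck:
    def test_normal_sample(self, rng):
        x = rng.normal(size=500)
        assert normality_check(x).classification == "normal"

    def test_lognormal_sample(self, rng):
        x = np.exp(rng.normal(size=500))
        assert normality_check(x).classification == "lognormal"

    def test_bimodal_neither(self, rng):
        mixed = np.concatenate([rng.normal(-4, 0.3, 250), rng.normal(4, 0.3, 250)])
        assert normality_check(mixed).classification == "neither"

    def test_nonpositive_skips_lognormal(self, rng):
        x = np.concatenate([rng.normal(-4, 0.3, 100), rng.normal(4, 0.3, 100)])
        res = normality_check(x)
        assert res.classification == "neither" and res.p_log is None

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0, 3.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(0.5, 1.0, size=15)
        res = anova_oneway([a, b])
        t, _ = sps.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.F == pytest.approx(t**2)
        assert res.df_between == 1 and res.df_within == 25

    def test_strong_separation(self, rng):
        groups = [rng.normal(loc, 0.1, 10) for loc in (0, 100, 200)]
        res = anova_oneway(groups)
        assert res.p < 1e-12
        assert (res.pairwise.adjusted_p < 1e-6).all()

    def test_tukey_adjusted_at_least_pairwise_p(self, rng):
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.4, 0.8)]
        res = anova_oneway(groups)
        for _, row in res.pairwise.iterrows():
            i = ["g0", "g1", "g2"].index(row.group_i)
            j = ["g0", "g1", "g2"].index(row.group_j)
            _, p_raw = sps.ttest_ind(groups[i], groups[j])
            assert row.adjusted_p >= p_raw - 1e-12

    def test_log10_transform(self, rng):
        groups = [np.exp(rng.normal(m, 0.5, 15)) for m in (0.0, 1.0)]
        res = anova_oneway(groups, transform="log10")
        assert res.transform == "log10" and res.p < 0.01

    def test_log10_requires_positive(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, -1.0, 2.0], [1.0, 2.0, 3.0]], transform="log10")

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])
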