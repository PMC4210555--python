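import numpy as np
import pytest
from scipy import stats

from ecmlm import (
    GroupAssignment,
    group_kinship,
    marker_ftest,
    neg2_reml_loglik,
    reml_fit,
)
from ecmlm.mlm import REMLWorkspace, neg2_reml_loglik_dense
from oracles import gls_marker_ftest_dense, reml_neg2ll_dense


def _instance(rng, n=None, q=2):
    n = n or int(rng.integers(8, 21))
    s = int(rng.integers(2, n))
    A = rng.normal(size=(s, s))
    Kg = A @ A.T / s
    labels = np.concatenate([np.arange(s), rng.integers(0, s, size=n - s)])
    Z = np.zeros((n, s))
    Z[np.arange(n), labels] = 1.0
    X = np.column_stack([np.ones(n), rng.normal(size=(n, q - 1))])
    y = rng.normal(size=n)
    return y, X, Z, Kg


class TestLikelihood:
    def test_matches_dense_formula(self, rng):
        for _ in range(25):
            y, X, Z, Kg = _instance(rng)
            lam = float(10 ** rng.uniform(-3, 3))
            spectral = neg2_reml_loglik(y, X, Z, Kg, lam)
            dense = neg2_reml_loglik_dense(y, X, Z, Kg, lam)
            assert spectral == pytest.approx(dense, abs=1e-8)

    def test_lambda_zero_is_ols_reml(self, rng):
        y, X, Z, Kg = _instance(rng, n=18)
        n, q = X.shape
        val = neg2_reml_loglik(y, X, Z, Kg, 0.0)
        # closed form at lam=0: V = I
        expected = reml_neg2ll_dense(y, X, np.eye(n))
        assert val == pytest.approx(expected, abs=1e-10)

    def test_translation_invariance(self, rng):
        y, X, Z, Kg = _instance(rng, n=15)
        c = rng.normal(size=X.shape[1])
        a = neg2_reml_loglik(y, X, Z, Kg, 1.3)
        b = neg2_reml_loglik(y + X @ c, X, Z, Kg, 1.3)
        assert a == pytest.approx(b, abs=1e-8)

    def test_kinship_scale_absorption(self, rng):
        # replacing (K, lam) by (cK, lam/c) leaves the likelihood unchanged
        y, X, Z, Kg = _instance(rng, n=16)
        c = 3.7
        a = neg2_reml_loglik(y, X, Z, Kg, 0.8)
        b = neg2_reml_loglik(y, X, Z, c * Kg, 0.8 / c)
        assert a == pytest.approx(b, abs=1e-8)

    def test_singular_v_returns_inf(self, rng):
        y, X, Z, Kg = _instance(rng, n=10)
        assert neg2_reml_loglik(y, X, Z, Kg, np.inf) == np.inf


class TestREMLFit:
    def test_null_heritability_boundary(self, rng):
        # no genetic signal: lambda-hat follows the boundary mixture — a
        # point mass at zero (about half the replicates) plus small positive
        # estimates; the median is at the boundary and no replicate finds a
        # large genetic component
        n = 100
        A = rng.normal(size=(n, n))
        Kg = A @ A.T / n
        Z = np.eye(n)
        X = np.ones((n, 1))
        reps = 60
        lams = np.array(
            [reml_fit(rng.normal(size=n), X, Z, Kg).vc.lam for _ in range(reps)]
        )
        assert np.mean(lams <= 1e-6) >= 0.45
        assert np.median(lams) <= 1e-6
        assert np.all(lams < 1.0)

    def test_fit_is_optimum_of_likelihood(self, rng):
        y, X, Z, Kg = _instance(rng, n=20)
        fit = reml_fit(y, X, Z, Kg)
        lam = fit.vc.lam
        for other in [lam * 0.5, lam * 2.0, 1e-9, 1e3]:
            assert fit.vc.neg2LL <= neg2_reml_loglik(y, X, Z, Kg, other) + 1e-8

    def test_blue_reduces_to_ols_at_lambda_zero(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(size=n) * 0.1
        # a kinship of zeros forces lambda to be irrelevant: V = I
        Z = np.eye(n)
        fit = reml_fit(y, X, Z, np.zeros((n, n)))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta_hat, ols, atol=1e-8)

    def test_nonfinite_phenotype_fatal(self, rng):
        y, X, Z, Kg = _instance(rng, n=10)
        y[0] = np.nan
        with pytest.raises(ValueError, match="phenotype"):
            reml_fit(y, X, Z, Kg)


class TestMarkerFtest:
    def _vc(self, y, X, Z, Kg):
        return reml_fit(y, X, Z, Kg).vc

    def test_matches_dense_whitening_oracle(self, rng):
        for _ in range(10):
            y, X, Z, Kg = _instance(rng, n=18)
            marker = rng.binomial(2, 0.4, size=18).astype(float)
            if len(np.unique(marker)) < 2:
                continue
            vc = self._vc(y, X, Z, Kg)
            res = marker_ftest(y, X, marker, Z, Kg, vc)
            V = 2 * vc.lam * (Z @ Kg @ Z.T) + np.eye(18)
            F, p = gls_marker_ftest_dense(y, X, marker, V)
            assert res.F == pytest.approx(F, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-10)
            assert res.df1 == 1 and res.df2 == 18 - X.shape[1] - 1

    def test_lambda_zero_equals_plain_regression(self, rng):
        n = 30
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        marker = rng.binomial(2, 0.3, size=n).astype(float)
        Z = np.eye(n)
        from ecmlm import VarianceComponents

        vc = VarianceComponents(0.0, 1.0, 0.0)  # lam = 0
        res = marker_ftest(y, X, marker, Z, np.eye(n), vc)
        F, p = gls_marker_ftest_dense(y, X, marker, np.eye(n))
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_monomorphic_marker_untestable(self, rng):
        y, X, Z, Kg = _instance(rng, n=12)
        vc = self._vc(y, X, Z, Kg)
        res = marker_ftest(y, X, np.ones(12), Z, Kg, vc)
        assert not res.testable
        assert res.p_value == 1.0

    def test_missing_individuals_dropped(self, rng):
        y, X, Z, Kg = _instance(rng, n=15)
        vc = self._vc(y, X, Z, Kg)
        marker = rng.binomial(2, 0.4, size=15).astype(float)
        marker[3] = np.nan
        res = marker_ftest(y, X, marker, Z, Kg, vc)
        keep = np.isfinite(marker)
        V = 2 * vc.lam * (Z[keep] @ Kg @ Z[keep].T) + np.eye(int(keep.sum()))
        F, p = gls_marker_ftest_dense(y[keep], X[keep], marker[keep], V)
        assert res.F == pytest.approx(F, abs=1e-8)
        assert res.df2 == int(keep.sum()) - X.shape[1] - 1

    def test_null_pvalues_uniform(self, family_panel, family_kinship):
        # permuted dosages are independent of y: p-values should be uniform
        g, _, y = family_panel
        K = family_kinship
        n = g.n_individuals
        rng = np.random.default_rng(11)
        Z = np.eye(n)
        X = np.ones((n, 1))
        fit = reml_fit(y.y, X, Z, K.values)
        from ecmlm.scan import gram_ftests, whiten

        M = g.imputed().copy()
        for j in range(M.shape[1]):
            M[:, j] = rng.permutation(M[:, j])
        yw, Xw, Mw = whiten(y.y, X, M, Z, K.values, fit.vc.lam)
        _, _, p, _, ok = gram_ftests(yw, Xw, Mw)
        ks = stats.kstest(p[ok], "uniform").statistic
        # 1% critical value of the KS statistic, n markers
        crit = 1.63 / np.sqrt(ok.sum())
        assert ks < crit


class TestEquivalences:
    def test_compression_level_one_equals_standard_mlm(self, family_panel, family_kinship):
        g, _, y = family_panel
        K = family_kinship
        n = g.n_individuals
        X = np.ones((n, 1))
        base = reml_fit(y.y, X, np.eye(n), K.values)
        a = GroupAssignment(np.arange(n), n)
        for phi in ("average", "median", "maximum"):
            gm = group_kinship(K, a, phi)
            fit = reml_fit(y.y, X, gm.Z, gm.K_group)
            assert fit.vc.neg2LL == pytest.approx(base.vc.neg2LL, abs=1e-6)

    def test_single_group_marker_test_equals_glm(self, family_panel, family_kinship):
        g, _, y = family_panel
        K = family_kinship
        n = g.n_individuals
        X = np.ones((n, 1))
        a = GroupAssignment(np.zeros(n, dtype=int), 1)
        gm = group_kinship(K, a, "average")
        fit = reml_fit(y.y, X, gm.Z, gm.K_group)
        marker = g.values[:, 17]
        res = marker_ftest(y.y, X, marker, gm.Z, gm.K_group, fit.vc)
        F, p = gls_marker_ftest_dense(y.y, X, marker, np.eye(n))
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_p3d_consistent_with_full_reml(self, rng):
        # per-marker p-values with fixed variance components track the
        # exact per-marker REML p-values almost perfectly
        from ecmlm import PanelSpec, simulate_panel, simulate_phenotype

        spec = PanelSpec(n_families=10, sibship=5, n_subpops=2, m=200, seed=21)
        g, K_true = simulate_panel(spec)
        y = simulate_phenotype(g, K_true, h2=0.5, seed=21)
        from ecmlm import loiselle_kinship

        K = loiselle_kinship(g)
        n = g.n_individuals
        X = np.ones((n, 1))
        Z = np.eye(n)
        fit = reml_fit(y.y, X, Z, K.values)
        p3d = np.array(
            [
                marker_ftest(y.y, X, g.values[:, j], Z, K.values, fit.vc).p_value
                for j in range(g.n_markers)
            ]
        )
        full = np.empty(g.n_markers)
        for j in range(g.n_markers):
            Xj = np.column_stack([X, g.values[:, j]])
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                full[j] = 1.0
                continue
            fj = reml_fit(y.y, Xj, Z, K.values)
            full[j] = marker_ftest(
                y.y, X, g.values[:, j], Z, K.values, fj.vc
            ).p_value
        rho = stats.spearmanr(p3d, full).statistic
        assert rho > 0.99
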