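import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from phylomorph.errors import ValidationError
from phylomorph.models import (
    ecology_design,
    fit_gls_terms,
    fit_pgls_rrpp,
    ppls_integration,
)
from phylomorph.phylo_engine import bm_covariance, simulate_multivariate_bm
from phylomorph.synthetic_data import simulate_tree


def _one_way_F(y, labels):
    groups = [y[labels == g] for g in np.unique(labels)]
    return stats.f_oneway(*groups).statistic


class TestPglsRrpp:
    def test_identity_C_matches_classical_anova_F(self, rng):
        n = 16
        labels = np.array(["a"] * 8 + ["b"] * 8, dtype=object)
        y = rng.standard_normal(n)
        tab = fit_pgls_rrpp(y, [("grp", labels)], None, n_perm=99, seed=0)
        F_expected = _one_way_F(y, labels)
        assert tab.terms["F"][0] == pytest.approx(F_expected, rel=1e-10)

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        # n=7: all 5040 permutations enumerable for the exact p-value
        n = 7
        labels = np.array(["a", "a", "a", "b", "b", "b", "b"], dtype=object)
        y = rng.standard_normal(n)
        F_obs = _one_way_F(y, labels)
        exact = np.mean(
            [
                _one_way_F(y[list(p)], labels) >= F_obs - 1e-12
                for p in itertools.permutations(range(n))
            ]
        )
        tab = fit_pgls_rrpp(y, [("grp", labels)], None, n_perm=1999, seed=1)
        p = tab.p("grp")
        # binomial error of the sampled permutation p around the exact value
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(p - exact) < 4 * se + 1e-3

    def test_duplicated_response_columns(self, rng):
        n = 20
        labels = np.array(list("ab") * 10, dtype=object)
        Y = rng.standard_normal((n, 3))
        t1 = fit_pgls_rrpp(Y, [("grp", labels)], None, n_perm=49, seed=5)
        t2 = fit_pgls_rrpp(np.hstack([Y, Y]), [("grp", labels)], None, n_perm=49, seed=5)
        assert t2.terms["F"][0] == pytest.approx(t1.terms["F"][0], rel=1e-10)
        assert t2.p("grp") == t1.p("grp")
        assert t2.terms["SS"][0] == pytest.approx(2 * t1.terms["SS"][0], rel=1e-10)

    def test_sequential_ss_identity(self, matched, rng):
        from phylomorph.gpa import generalized_procrustes

        aln = generalized_procrustes(matched.landmarks)
        C = bm_covariance(matched.phylogeny, matched.taxa)
        terms = ecology_design(matched.ecology, aln.log_centroid_size)
        tab = fit_pgls_rrpp(aln.flatten(), terms, C, n_perm=49, seed=3)
        assert (tab.terms["SS"] >= 0).all()
        assert tab.terms["SS"].sum() + tab.SS_residual == pytest.approx(
            tab.SS_total, rel=1e-8
        )
        assert ((tab.terms["p"] > 0) & (tab.terms["p"] <= 1)).all()

    def test_min_p_is_one_over_nperm_plus_one(self, rng):
        # overwhelming group separation: p pinned at 1/(n_perm+1)
        n = 20
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        y = np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 0.01, n)
        tab = fit_pgls_rrpp(y, [("grp", labels)], None, n_perm=199, seed=0)
        assert tab.p("grp") == pytest.approx(1 / 200)

    def test_seeded_determinism(self, rng):
        n = 15
        labels = np.array(list("abc") * 5, dtype=object)
        Y = rng.standard_normal((n, 4))
        t1 = fit_pgls_rrpp(Y, [("grp", labels)], None, n_perm=99, seed=42)
        t2 = fit_pgls_rrpp(Y, [("grp", labels)], None, n_perm=99, seed=42)
        assert t1.terms.equals(t2.terms)

    def test_single_level_factor_rejected(self, rng):
        labels = np.array(["same"] * 10, dtype=object)
        with pytest.raises(ValidationError, match="grp"):
            fit_pgls_rrpp(rng.standard_normal(10), [("grp", labels)], None)

    def test_null_calibration(self):
        # BM response + random labels: p approximately uniform
        phy = simulate_tree(20, seed=1)
        C = bm_covariance(phy)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            Y = simulate_multivariate_bm(C, np.eye(3), seed=rng)
            labels = rng.choice(["a", "b", "c"], size=20).astype(object)
            size = rng.standard_normal(20)
            tab = fit_pgls_rrpp(
                Y, [("grp", labels), ("size", size)], C, n_perm=99, seed=rng
            )
            ps.append(tab.p("grp"))
        ps = np.array(ps)
        assert stats.kstest(ps, "uniform").pvalue > 0.001
        assert 0.01 <= (ps <= 0.05).mean() <= 0.10


class TestGlsTerms:
    def test_identity_C_matches_ols_oracle(self):
        rng = np.random.default_rng(7)
        n = 25
        x = rng.standard_normal(n)
        g = rng.choice(["u", "v", "w"], size=n).astype(object)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        fit = fit_gls_terms(y, [("grp", g), ("x", x)], None)
        # statsmodels OLS with the same treatment coding
        dummies = np.column_stack([(g == "v").astype(float), (g == "w").astype(float)])
        X = sm.add_constant(np.column_stack([dummies, x]))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ols.params, atol=1e-8)
        # Wald chi-square for the x term
        w = ols.wald_test(np.array([[0.0, 0.0, 0.0, 1.0]]), use_f=False, scalar=True)
        assert fit.term_tests.set_index("term").loc["x", "chisq"] == pytest.approx(
            float(w.statistic), rel=1e-6
        )
        assert fit.p("x") == pytest.approx(float(w.pvalue), abs=1e-6)

    def test_known_size_effect(self):
        rng = np.random.default_rng(3)
        phy = simulate_tree(40, seed=2)
        C = bm_covariance(phy)
        group_ps = []
        for _ in range(50):
            size = rng.standard_normal(40)
            g = rng.choice(["a", "b"], size=40).astype(object)
            # strong linear size effect, no group effect, mild BM noise
            y = 2.0 * size + 0.3 * simulate_multivariate_bm(C, np.eye(1), seed=rng).ravel()
            fit = fit_gls_terms(y, [("grp", g), ("size", size)], C)
            assert fit.p("size") < 1e-6
            group_ps.append(fit.p("grp"))
        assert np.mean(group_ps) > 0.35

    def test_taxon_permutation_invariance(self, rng):
        phy = simulate_tree(12, seed=4)
        C = bm_covariance(phy)
        y = rng.standard_normal(12)
        g = rng.choice(["a", "b"], size=12).astype(object)
        x = rng.standard_normal(12)
        fit1 = fit_gls_terms(y, [("grp", g), ("x", x)], C)
        perm = rng.permutation(12)
        C2 = C.subset([C.taxa[i] for i in perm])
        fit2 = fit_gls_terms(y[perm], [("grp", g[perm]), ("x", x[perm])], C2)
        np.testing.assert_allclose(
            fit1.coef.to_numpy(), fit2.coef.to_numpy(), atol=1e-10
        )


class TestPpls:
    def test_identical_blocks_r_is_one(self, rng):
        Y = rng.standard_normal((15, 4))
        res = ppls_integration(Y, Y, None, n_perm=49, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-10)

    def test_null_calibration(self, rng):
        ps = []
        for _ in range(300):
            Y1 = rng.standard_normal((12, 3))
            Y2 = rng.standard_normal((12, 2))
            ps.append(ppls_integration(Y1, Y2, None, n_perm=49, seed=rng).p)
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.001

    def test_latent_factor_monotonicity(self):
        rng = np.random.default_rng(5)
        mean_r = []
        for strength in [0.0, 0.5, 1.0, 2.0, 4.0]:
            rs = []
            for _ in range(30):
                latent = rng.standard_normal(25)
                Y1 = rng.standard_normal((25, 2)) + strength * latent[:, None]
                Y2 = rng.standard_normal((25, 2)) + strength * latent[:, None]
                rs.append(ppls_integration(Y1, Y2, None, n_perm=9, seed=rng).r_pls)
            mean_r.append(np.mean(rs))
        assert all(np.diff(mean_r) > 0)

    def test_constant_block_rejected(self, rng):
        with pytest.raises(ValidationError, match="constant"):
            ppls_integration(rng.standard_normal((10, 2)), np.ones((10, 2)), None)

    def test_p_never_zero(self, rng):
        latent = rng.standard_normal(20)
        Y1 = latent[:, None] + rng.normal(0, 0.01, (20, 2))
        Y2 = latent[:, None] + rng.normal(0, 0.01, (20, 2))
        res = ppls_integration(Y1, Y2, None, n_perm=99, seed=1)
        assert res.p >= 1 / 100


class TestStarPhylogenyReduction:
    def test_pgls_with_identity_equals_C_none(self, rng):
        n = 18
        Y = rng.standard_normal((n, 3))
        labels = rng.choice(["a", "b", "c"], size=n).astype(object)
        x = rng.standard_normal(n)
        terms = [("grp", labels), ("x", x)]
        t1 = fit_pgls_rrpp(Y, terms, None, n_perm=49, seed=9)
        t2 = fit_pgls_rrpp(Y, terms, np.eye(n), n_perm=49, seed=9)
        np.testing.assert_allclose(
            t1.terms[["SS", "F"]].to_numpy(), t2.terms[["SS", "F"]].to_numpy(), atol=1e-8
        )
        assert (t1.terms["p"] == t2.terms["p"]).all()

    def test_gls_and_ppls_identity_reduction(self, rng):
        n = 14
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        f1 = fit_gls_terms(y, [("x", x)], None)
        f2 = fit_gls_terms(y, [("x", x)], np.eye(n))
        np.testing.assert_allclose(f1.coef.to_numpy(), f2.coef.to_numpy(), atol=1e-8)
        Y1, Y2 = rng.standard_normal((n, 3)), rng.standard_normal((n, 2))
        r1 = ppls_integration(Y1, Y2, None, n_perm=19, seed=3)
        r2 = ppls_integration(Y1, Y2, np.eye(n), n_perm=19, seed=3)
        assert r1.r_pls == pytest.approx(r2.r_pls, abs=1e-8)
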