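"""Prediction models: REML engines, Bayesian LASSO, RKHS, masked prediction."""

import numpy as np
import pandas as pd
import pytest

from pavcall.containers import PavcallError, PhenotypeTable
from pavcall.grm import epistatic_grm, vanraden_grm
from pavcall.models import (
    FixedDesign,
    build_fixed_design,
    fit_bayesian_lasso,
    fit_egblup,
    fit_gblup,
    fit_rkhs,
    fit_variance_components,
    gaussian_kernels,
    predict_masked,
)
from pavcall.models import KernelSet


def _pheno(levels, trait=None):
    n = len(levels)
    df = pd.DataFrame(
        {"y": trait if trait is not None else np.zeros(n), "fam": levels},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    return PhenotypeTable(df, trait_names=["y"], covariate_names=["fam"])


class TestFixedDesign:
    def test_two_mothers_four_samples(self):
        X = build_fixed_design(_pheno(["m1", "m1", "m2", "m2"]), "intercept+factor", "fam")
        assert X.X.shape == (4, 2)
        assert list(X.X[:, 1]) == [0.0, 0.0, 1.0, 1.0]

    def test_intercept_only(self):
        X = build_fixed_design(_pheno(["a"] * 5), "intercept_only")
        assert np.array_equal(X.X, np.ones((5, 1)))

    def test_three_families_full_rank(self):
        X = build_fixed_design(_pheno(list("aabbcc")), "intercept+factor", "fam")
        assert X.X.shape == (6, 3)
        assert np.linalg.matrix_rank(X.X) == 3

    def test_rank_deficient_rejected(self):
        with pytest.raises(PavcallError):
            FixedDesign(np.ones((4, 2)), "bad")


def _gblup_data(rng, n=50, m=200, h2=0.5):
    M = rng.integers(0, 3, size=(n, m)).astype(float)
    g = vanraden_grm(M)
    a = rng.normal(0, 1, m)
    gv = (M - M.mean(axis=0)) @ a
    gv *= np.sqrt(h2) / gv.std()
    y = 3.0 + gv + rng.normal(0, np.sqrt(1 - h2), n)
    return M, g, y


class TestGBLUP:
    def test_rrblup_equivalence(self, rng):
        """GBLUP fitted values equal ridge marker-effect predictions when
        G = ZZ'/c and the ridge penalty is c * sigma_e^2 / sigma_a^2."""
        M, g, y = _gblup_data(rng)
        n, m = M.shape
        X = np.ones((n, 1))
        fit = fit_gblup(y, X, g)
        lam = g.denominator * fit.sigma2["residual"] / fit.sigma2["additive"]
        Z = g.Z
        mme = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(m)]])
        sol = np.linalg.solve(mme, np.concatenate([X.T @ y, Z.T @ y]))
        pred_rr = X @ sol[:1] + Z @ sol[1:]
        pred_g = X @ fit.beta_hat + fit.u_hat["additive"]
        assert np.abs(pred_g - pred_rr).max() < 1e-6

    def test_no_signal_shrinks_to_fixed_means(self, rng):
        n = 200
        M = rng.integers(0, 3, size=(n, 100)).astype(float)
        g = vanraden_grm(M)
        y = 1.5 + rng.normal(0, 1, n)  # no genetic signal
        fit = fit_gblup(y, np.ones((n, 1)), g)
        ratio = fit.sigma2["additive"] / fit.sigma2["residual"]
        assert ratio < 0.15
        assert np.abs(fit.u_hat["additive"]).max() < 0.5

    def test_sample_order_invariance(self, rng):
        M, g, y = _gblup_data(rng, n=40, m=80)
        X = np.ones((40, 1))
        fit = fit_gblup(y, X, g)
        perm = rng.permutation(40)
        fit_p = fit_gblup(y[perm], X, g.G[np.ix_(perm, perm)])
        assert fit.sigma2["additive"] == pytest.approx(
            fit_p.sigma2["additive"], rel=1e-5
        )
        assert np.allclose(fit.u_hat["additive"][perm], fit_p.u_hat["additive"], atol=1e-6)


class TestEGBLUP:
    def test_nested_loglik_and_null_epistasis(self, rng):
        M, g, y = _gblup_data(rng, n=80, m=150)
        gaa = epistatic_grm(g)
        X = np.ones((80, 1))
        fit_a = fit_gblup(y, X, g)
        fit_e = fit_egblup(y, X, g, gaa)
        assert fit_e.loglik >= fit_a.loglik - 1e-4
        for v in fit_e.sigma2.values():
            assert v >= 0

    def test_additive_trait_gives_similar_predictions(self):
        rng = np.random.default_rng(202)
        n = 150
        M, g, y = _gblup_data(rng, n=n, m=150)
        gaa = epistatic_grm(g)
        X = np.ones((n, 1))
        tr, te = np.arange(100), np.arange(100, n)
        fa = fit_gblup(y[tr], X[tr], g.G[np.ix_(tr, tr)])
        fe = fit_egblup(y[tr], X[tr], g.G[np.ix_(tr, tr)], gaa.G[np.ix_(tr, tr)])
        pa = predict_masked(fa, {"additive": g.G}, tr, te, X)
        pe = predict_masked(fe, {"additive": g.G, "epistasis": gaa.G}, tr, te, X)
        ra = np.corrcoef(y[te], pa)[0, 1]
        re = np.corrcoef(y[te], pe)[0, 1]
        assert abs(ra - re) < 0.1


class TestPredictMasked:
    def test_duplicate_sample_interpolates_exactly(self, rng):
        M, g, y = _gblup_data(rng, n=40, m=100)
        G = g.G.copy()
        # make sample 39 a genomic copy of sample 0
        G[39] = G[0]
        G[:, 39] = G[:, 0]
        G[39, 39] = G[0, 0]
        tr = np.arange(39)
        fit = fit_gblup(y[tr], np.ones((39, 1)), G[np.ix_(tr, tr)])
        pred = predict_masked(fit, {"additive": G}, tr, [39], np.ones((40, 1)))
        expected = fit.beta_hat[0] + fit.u_hat["additive"][0]
        assert pred[0] == pytest.approx(expected, abs=1e-6)

    def test_unrelated_sample_gets_fixed_part(self, rng):
        M, g, y = _gblup_data(rng, n=30, m=60)
        G = np.eye(31)
        G[:30, :30] = g.G + 0.05 * np.eye(30)  # test sample fully unrelated
        tr = np.arange(30)
        fit = fit_gblup(y, np.ones((30, 1)), G[np.ix_(tr, tr)])
        pred = predict_masked(fit, {"additive": G}, tr, [30], np.ones((31, 1)))
        assert pred[0] == pytest.approx(fit.beta_hat[0], abs=1e-10)

    def test_matches_full_mixed_model_solve(self, rng):
        """Masked prediction equals the all-sample mixed-model equations with
        the validation phenotypes absent, at fixed variance components."""
        n = 60
        M, g, y = _gblup_data(rng, n=n, m=120)
        X = np.ones((n, 1))
        tr, te = np.arange(45), np.arange(45, n)
        fit = fit_gblup(y[tr], X[tr], g.G[np.ix_(tr, tr)] + 1e-8 * np.eye(45))
        pred = predict_masked(fit, {"additive": g.G + 1e-8 * np.eye(n)}, tr, te, X)
        # oracle: Henderson MME on training data, then u_test via conditional mean
        s2a, s2e = fit.sigma2["additive"], fit.sigma2["residual"]
        Gtt = g.G[np.ix_(tr, tr)] + 1e-8 * np.eye(45)
        Ginv = np.linalg.inv(Gtt)
        A = np.block(
            [[X[tr].T @ X[tr] / s2e, X[tr].T / s2e],
             [X[tr] / s2e, np.eye(45) / s2e + Ginv / s2a]]
        )
        rhs = np.concatenate([X[tr].T @ y[tr] / s2e, y[tr] / s2e])
        sol = np.linalg.solve(A, rhs)
        beta, u_tr = sol[:1], sol[1:]
        u_te = g.G[np.ix_(te, tr)] @ Ginv @ u_tr
        assert np.abs(pred - (X[te] @ beta + u_te)).max() < 1e-6


class TestBayesianLasso:
    def test_zero_markers_recovers_mean(self, rng):
        y = 4.0 + rng.normal(0, 1, 100)
        fit = fit_bayesian_lasso(y, np.ones((100, 1)), np.empty((100, 0)),
                                 iters=600, burn_in=100, seed=0)
        assert fit.beta_mean[0] == pytest.approx(y.mean(), abs=0.3)

    def test_planted_marker_recovered(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            M = rng.integers(0, 3, (300, 100)).astype(float)
            g = M[:, 17] * 1.0
            y = g + rng.normal(0, g.std(), 300)  # marker explains 50%
            fit = fit_bayesian_lasso(y, np.ones((300, 1)), M,
                                     iters=1500, burn_in=300, thin=3, seed=seed)
            j = int(np.argmax(np.abs(fit.effect_mean)))
            if j == 17 and fit.effect_mean[17] > 0:
                hits += 1
        assert hits == n_seeds

    def test_deterministic_under_seed(self, rng):
        M = rng.integers(0, 3, (80, 40)).astype(float)
        y = rng.normal(size=80)
        a = fit_bayesian_lasso(y, np.ones((80, 1)), M, iters=400, burn_in=100, seed=7)
        b = fit_bayesian_lasso(y, np.ones((80, 1)), M, iters=400, burn_in=100, seed=7)
        assert np.array_equal(a.effect_mean, b.effect_mean)
        assert a.sigma2_e_mean == b.sigma2_e_mean

    def test_iters_must_exceed_burnin(self):
        with pytest.raises(PavcallError):
            fit_bayesian_lasso(np.zeros(10), np.ones((10, 1)), np.empty((10, 0)),
                               iters=100, burn_in=100)


class TestKernels:
    def test_diagonal_one_and_bandwidth_monotonicity(self, rng):
        m = rng.normal(size=(20, 30))
        ks = gaussian_kernels(m)
        prev = None
        for K in ks.kernels:
            assert np.allclose(np.diag(K), 1.0)
            if prev is not None:
                off = ~np.eye(20, dtype=bool)
                assert (K[off] <= prev[off] + 1e-12).all()
            prev = K
        tiny = gaussian_kernels(m, bandwidths=(1e-9,)).kernels[0]
        assert np.allclose(tiny, 1.0, atol=1e-6)

    def test_identical_samples_rejected(self):
        with pytest.raises(PavcallError):
            gaussian_kernels(np.ones((5, 3)))


class TestRKHS:
    def test_single_kernel_reduces_to_gblup(self, rng):
        M, g, y = _gblup_data(rng, n=60, m=120)
        X = np.ones((60, 1))
        tr, te = np.arange(45), np.arange(45, 60)
        fit_g = fit_gblup(y[tr], X[tr], g.G[np.ix_(tr, tr)])
        ks = KernelSet([g.G[np.ix_(tr, tr)]], (1.0,), np.zeros((45, 45)))
        fit_k = fit_rkhs(y[tr], X[tr], ks)
        pg = predict_masked(fit_g, {"additive": g.G}, tr, te, X)
        pk = predict_masked(fit_k, {"kernel_h1": g.G}, tr, te, X)
        assert np.abs(pg - pk).max() < 1e-4

    def test_pure_noise_attributes_no_covariance(self):
        """Null trait: the fitted kernels contribute ~no between-sample
        covariance.  (Raw kernel variances are not individually identifiable
        because the sharpest kernel is nearly an identity matrix and trades
        freely against the residual.)"""
        rng = np.random.default_rng(303)
        m = rng.integers(0, 3, size=(100, 60)).astype(float)
        y = rng.normal(size=100)
        ks = gaussian_kernels(m)
        fit = fit_rkhs(y, np.ones((100, 1)), ks)
        vy = np.var(y)
        n = 100
        cov = sum(fit.sigma2[name] * K for name, K in ks.as_dict().items())
        # remove the constant (intercept-confounded) direction, which REML
        # cannot see: H C H with H the centering matrix
        h = np.eye(n) - np.ones((n, n)) / n
        cov_c = h @ cov @ h
        off = ~np.eye(n, dtype=bool)
        assert np.abs(cov_c[off]).mean() < 0.05 * vy
        assert np.abs(cov_c[off]).max() < 0.3 * vy

    def test_kernel_order_invariance(self, rng):
        m = rng.integers(0, 3, size=(60, 50)).astype(float)
        y = rng.normal(size=60) + m[:, 0]
        ks = gaussian_kernels(m)
        f1 = fit_variance_components(y, np.ones((60, 1)), ks.as_dict())
        rev = dict(reversed(list(ks.as_dict().items())))
        f2 = fit_variance_components(y, np.ones((60, 1)), rev)
        tot1 = sum(v for k, v in f1.sigma2.items() if k != "residual")
        tot2 = sum(v for k, v in f2.sigma2.items() if k != "residual")
        assert tot1 == pytest.approx(tot2, rel=1e-3, abs=1e-8)
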