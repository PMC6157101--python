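import numpy as np
import pytest
from scipy.linalg import null_space

from jcar.car_test import (CovariateMatrix, KinshipMatrix, inverse_sqrt,
                           jcar_test, residual_basis, score_statistic_layer)
from jcar.kernels import build_similarity_pair


def equal_similarity_pair(n, off=0.5, gamma=0.0):
    S_raw = np.full((n, n), off)
    np.fill_diagonal(S_raw, 1.0)
    return build_similarity_pair(S_raw, gamma)


class TestInverseSqrt:
    def test_identity(self):
        kin = KinshipMatrix.identity(["a", "b"])
        assert np.allclose(inverse_sqrt(kin), np.eye(2))

    def test_diagonal_closed_form(self):
        kin = KinshipMatrix(np.diag([4.0, 1.0]), ["a", "b"])
        assert np.allclose(inverse_sqrt(kin), np.diag([0.5, 1.0]))

    def test_reconstruction(self, spd_factory):
        V = spd_factory(5)
        kin = KinshipMatrix(V, [str(i) for i in range(5)])
        M = inverse_sqrt(kin)
        assert np.allclose(M, M.T)
        assert np.max(np.abs(M @ V @ M - np.eye(5))) < 1e-8

    def test_singular_rejected(self):
        V = np.ones((3, 3))  # rank 1
        kin = KinshipMatrix(V, list("abc"))
        with pytest.raises(ValueError, match="eigenvalue"):
            inverse_sqrt(kin)


class TestResidualBasis:
    def test_intercept_only_annihilates_ones(self):
        kin = KinshipMatrix.identity(list("abc"))
        X = CovariateMatrix.intercept_only(3)
        rb = residual_basis(kin, X, np.array([1.0, 2.0, 3.0]))
        assert rb.A.shape == (2, 3)
        assert np.max(np.abs(rb.A @ np.ones(3))) < 1e-10
        assert np.allclose(rb.A @ rb.A.T, np.eye(2), atol=1e-10)

    def test_fitted_phenotype_gives_zero_ystar(self, rng):
        n = 8
        kin = KinshipMatrix.identity([str(i) for i in range(n)])
        Xv = np.column_stack([np.ones(n), rng.standard_normal(n)])
        X = CovariateMatrix(Xv, ["intercept", "x"])
        y = Xv @ np.array([2.0, -1.0])  # in the covariate span
        rb = residual_basis(kin, X, y)
        assert np.max(np.abs(rb.y_star)) < 1e-10

    def test_projection_contracts_random(self, spd_factory, rng):
        for n, p in [(10, 2), (25, 4)]:
            V = spd_factory(n)
            kin = KinshipMatrix(V, [str(i) for i in range(n)])
            Xv = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            X = CovariateMatrix(Xv, [f"c{j}" for j in range(p)])
            rb = residual_basis(kin, X, rng.standard_normal(n))
            assert np.max(np.abs(rb.A @ rb.K_inv_sqrt @ Xv)) < 1e-10
            assert np.max(np.abs(rb.A @ rb.A.T - np.eye(rb.df))) < 1e-10

    def test_rotation_invariance_of_ratio(self, rng):
        # two valid bases give identical y*'My*/y*'y* for any symmetric M
        n = 9
        kin = KinshipMatrix.identity([str(i) for i in range(n)])
        X = CovariateMatrix.intercept_only(n)
        y = rng.standard_normal(n)
        rb1 = residual_basis(kin, X, y, method="svd")
        rb2 = residual_basis(kin, X, y, method="qr")
        M = rng.standard_normal((n, n))
        M = M + M.T
        for rb in (rb1, rb2):
            Mp = rb.A @ M @ rb.A.T
            r = (rb.y_star @ Mp @ rb.y_star) / (rb.y_star @ rb.y_star)
            if rb is rb1:
                r1 = r
        assert r == pytest.approx(r1, abs=1e-10)


class TestScoreStatistic:
    def test_hand_evaluated_equal_similarity(self):
        # n=3, K=I, intercept-only X, equal similarity off-diag 0.5, gamma=0,
        # y=(1,0,-1): independent dense evaluation of both displayed terms
        kin = KinshipMatrix.identity(list("abc"))
        X = CovariateMatrix.intercept_only(3)
        y = np.array([1.0, 0.0, -1.0])
        rb = residual_basis(kin, X, y)
        pair = equal_similarity_pair(3, off=0.5, gamma=0.0)

        # oracle: explicit matrices, no shared code path
        A = null_space(np.ones((1, 3))).T
        ystar = A @ y
        P = np.diag([1.0, 1.0, 1.0])  # D - 0*S, row sums = 1
        Q = A @ np.linalg.inv(P) @ A.T
        expected = (2 / 2) * (ystar @ Q @ ystar) / (ystar @ ystar) \
            - 0.5 * np.trace(np.linalg.inv(P))
        assert expected == pytest.approx(-0.5)

        assert score_statistic_layer(rb, pair) == pytest.approx(expected,
                                                                abs=1e-10)

    def test_terms_cancel_when_ratio_equals_trace_over_df(self, rng):
        # when (y*'Q y*)/(y*'y*) = tr(K^{-1/2}P^{-1}K^{-1/2})/df the two
        # displayed terms of S_l cancel exactly; construct such a y by
        # mixing extreme eigenvectors of Q to hit the target ratio
        n = 20
        kin = KinshipMatrix.identity([str(i) for i in range(n)])
        X = CovariateMatrix.intercept_only(n)
        S_raw = rng.uniform(0.2, 0.9, (n, n))
        S_raw = (S_raw + S_raw.T) / 2
        np.fill_diagonal(S_raw, 1.0)
        pair = build_similarity_pair(S_raw, gamma=0.3)
        rb0 = residual_basis(kin, X, rng.standard_normal(n))
        Pinv = np.linalg.inv(pair.precision())
        Q = rb0.A @ Pinv @ rb0.A.T
        w, V = np.linalg.eigh(Q)
        t = np.trace(Pinv) / rb0.df
        frac = (t - w[0]) / (w[-1] - w[0])
        assert 0.0 < frac < 1.0  # target ratio is attainable
        ystar = np.sqrt(frac) * V[:, -1] + np.sqrt(1 - frac) * V[:, 0]
        rb = residual_basis(kin, X, rb0.A.T @ ystar)
        assert score_statistic_layer(rb, pair) == pytest.approx(0.0,
                                                                abs=1e-9)

    def test_affine_invariance(self, rng):
        n = 12
        kin = KinshipMatrix.identity([str(i) for i in range(n)])
        Xv = np.column_stack([np.ones(n), rng.standard_normal(n)])
        X = CovariateMatrix(Xv, ["intercept", "x"])
        y = rng.standard_normal(n)
        pair = equal_similarity_pair(n, off=0.4, gamma=0.3)
        s0 = score_statistic_layer(residual_basis(kin, X, y), pair)
        y2 = -2.5 * y + Xv @ np.array([3.0, 1.0])
        s1 = score_statistic_layer(residual_basis(kin, X, y2), pair)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_degenerate_phenotype_rejected(self):
        kin = KinshipMatrix.identity(list("abc"))
        X = CovariateMatrix.intercept_only(3)
        rb = residual_basis(kin, X, np.full(3, 2.0))
        pair = equal_similarity_pair(3)
        with pytest.raises(ValueError, match="degenerate"):
            score_statistic_layer(rb, pair)


def _random_problem(rng, n=20, gamma1=0.2, gamma2=0.1):
    from jcar.simulate import SimScenario, simulate_dataset
    from jcar import kernels

    sc = SimScenario(n_subjects=n, family_structure="unrelated",
                     seed=int(rng.integers(2**31)))
    d = simulate_dataset(sc)
    gen = kernels.build_similarity_pair(
        kernels.ibs_similarity(d.genotypes), gamma1)
    meth = kernels.build_similarity_pair(
        kernels.gaussian_similarity(
            d.methylation, kernels.default_bandwidth(d.methylation)), gamma2)
    return d, gen, meth


class TestJcarTest:
    def test_observed_threshold_identity(self, rng):
        # y*'By* = 0 by construction of the threshold constant
        d, gen, meth = _random_problem(rng)
        rb = residual_basis(d.kinship, d.covariates, d.phenotype)
        for layers in [dict(genetic=gen, methylation=meth),
                       dict(genetic=gen), dict(methylation=meth)]:
            res = jcar_test(rb, **layers)
            M = np.zeros((rb.df, rb.df))
            for pair in layers.values():
                R = rb.K_inv_sqrt @ np.linalg.inv(pair.precision()) @ rb.K_inv_sqrt
                M += rb.A @ R @ rb.A.T
            c = res.diagnostics["threshold_constant"]
            B = M - c * np.eye(rb.df)
            q_obs = rb.y_star @ B @ rb.y_star
            assert abs(q_obs) < 1e-8 * max(1.0, rb.y_star @ rb.y_star)

    def test_joint_combines_statistics(self, rng):
        d, gen, meth = _random_problem(rng)
        rb = residual_basis(d.kinship, d.covariates, d.phenotype)
        res = jcar_test(rb, genetic=gen, methylation=meth)
        assert res.mode == "joint"
        assert res.S == pytest.approx((res.S1 + res.S2) / 2)
        assert 0.0 <= res.p_value <= 1.0

    def test_single_layer_modes(self, rng):
        d, gen, meth = _random_problem(rng)
        rb = residual_basis(d.kinship, d.covariates, d.phenotype)
        res_g = jcar_test(rb, genetic=gen)
        res_m = jcar_test(rb, methylation=meth)
        assert res_g.mode == "genetic" and res_g.S2 is None
        assert res_m.mode == "methylation" and res_m.S1 is None
        assert res_g.S == pytest.approx(
            score_statistic_layer(rb, gen), abs=1e-10)

    def test_requires_a_layer(self, rng):
        d, _, _ = _random_problem(rng)
        rb = residual_basis(d.kinship, d.covariates, d.phenotype)
        with pytest.raises(ValueError):
            jcar_test(rb)

    def test_affine_invariance_of_p_value(self, rng):
        d, gen, meth = _random_problem(rng)
        rb0 = residual_basis(d.kinship, d.covariates, d.phenotype)
        p0 = jcar_test(rb0, genetic=gen, methylation=meth).p_value
        y2 = 3.0 * d.phenotype + d.covariates.values @ np.array([1.0, -2.0, 0.5])
        rb1 = residual_basis(d.kinship, d.covariates, y2)
        p1 = jcar_test(rb1, genetic=gen, methylation=meth).p_value
        assert p1 == pytest.approx(p0, abs=1e-8)

    def test_basis_invariance_of_p_value(self, rng):
        d, gen, meth = _random_problem(rng)
        p = {}
        for method in ("svd", "qr"):
            rb = residual_basis(d.kinship, d.covariates, d.phenotype,
                                method=method)
            p[method] = jcar_test(rb, genetic=gen, methylation=meth).p_value
        assert p["svd"] == pytest.approx(p["qr"], abs=1e-8)

    def test_subject_permutation_equivariance(self, rng):
        from jcar.car_test import CovariateMatrix
        from jcar.kernels import SimilarityPair

        d, gen, meth = _random_problem(rng, n=15)
        rb = residual_basis(d.kinship, d.covariates, d.phenotype)
        res0 = jcar_test(rb, genetic=gen, methylation=meth)

        perm = rng.permutation(15)
        kin_p = KinshipMatrix(d.kinship.values[np.ix_(perm, perm)],
                              [d.kinship.subject_ids[i] for i in perm])
        X_p = CovariateMatrix(d.covariates.values[perm], d.covariates.names)
        pairs_p = []
        for pair in (gen, meth):
            pairs_p.append(SimilarityPair(
                S=pair.S[np.ix_(perm, perm)],
                D=np.diag(np.diag(pair.D)[perm]), gamma=pair.gamma))
        rb_p = residual_basis(kin_p, X_p, d.phenotype[perm])
        res_p = jcar_test(rb_p, genetic=pairs_p[0], methylation=pairs_p[1])
        assert res_p.S1 == pytest.approx(res0.S1, abs=1e-8)
        assert res_p.S2 == pytest.approx(res0.S2, abs=1e-8)
        assert res_p.p_value == pytest.approx(res0.p_value, abs=1e-8)
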