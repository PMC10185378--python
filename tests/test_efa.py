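import numpy as np
import pytest
from scipy import optimize

import actionspace as a
from actionspace.efa import reduced_eigenvalues
from actionspace.errors import ValidationError
from conftest import make_cluster_loadings


def paf_oracle(R, k, tol=1e-3, max_iter=100):
    """Independent principal-axis recursion written with explicit steps."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    for _ in range(max_iter):
        Rr = R.copy()
        for i in range(p):
            Rr[i, i] = h2[i]
        w, v = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1]
        lam = np.zeros((p, k))
        for j in range(k):
            lam[:, j] = v[:, order[j]] * np.sqrt(max(w[order[j]], 0.0))
        h2_new = np.minimum((lam ** 2).sum(axis=1), 1.0)
        if np.abs(h2_new - h2).max() < tol:
            return lam, h2_new
        h2 = h2_new
    return lam, h2


def quartimin_oracle(A, seed=0):
    """Direct-quartimin rotation by a generic optimizer over the oblique
    manifold (columns of T normalised), independent of gradient projection."""
    p, k = A.shape

    def criterion(tflat):
        T = tflat.reshape(k, k)
        T = T / np.sqrt((T ** 2).sum(axis=0))
        try:
            L = A @ np.linalg.inv(T).T
        except np.linalg.LinAlgError:
            return 1e6
        L2 = L ** 2
        total = 0.0
        for i in range(k):
            for j in range(k):
                if i != j:
                    total += (L2[:, i] * L2[:, j]).sum()
        return total / 4.0

    rng = np.random.default_rng(seed)
    best = None
    for start in range(8):
        x0 = np.eye(k).ravel() if start == 0 else rng.standard_normal(k * k)
        res = optimize.minimize(criterion, x0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    T = best.x.reshape(k, k)
    T /= np.sqrt((T ** 2).sum(axis=0))
    L = A @ np.linalg.inv(T).T
    return L, T.T @ T, best.fun


def align(got, want):
    """Permute/sign-align columns of `got` onto `want`."""
    k = want.shape[1]
    C = got.T @ want
    out = np.zeros_like(want)
    used = set()
    for j in range(k):
        order = np.argsort(-np.abs(C[:, j]))
        src = next(s for s in order if s not in used)
        used.add(src)
        out[:, j] = np.sign(C[src, j]) * got[:, src]
    return out


class TestScree:
    def test_identity_eigenvalues_all_one(self):
        np.testing.assert_allclose(a.scree(np.eye(20)), 1.0)

    def test_rank_one_equicorrelation(self):
        p = 6
        R = np.ones((p, p))
        ev = a.scree(R)
        np.testing.assert_allclose(ev, [p] + [0] * (p - 1), atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_eigenvalues_sum_to_p(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(50, 8))
        R = np.corrcoef(x, rowvar=False)
        assert a.scree(R).sum() == pytest.approx(8.0, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        R = np.eye(3)
        R[0, 1] = 0.5
        with pytest.raises(ValidationError):
            a.scree(R)


class TestParallelAnalysis:
    def test_noise_retains_nothing_under_q95(self):
        rng = np.random.default_rng(1)
        R = np.corrcoef(rng.standard_normal((240, 20)), rowvar=False)
        res = a.parallel_analysis(R, n=240, p=20, reps=200, criterion="q95",
                                  seed=2)
        assert res.n_factors_pa == 0

    def test_strong_four_factor_data_retains_four(self):
        lam = make_cluster_loadings(p=20, k=4, value=0.7)
        rng = np.random.default_rng(3)
        eta = rng.standard_normal((240, 4))
        x = eta @ lam.T + rng.standard_normal((240, 20)) * np.sqrt(1 - 0.49)
        R = np.corrcoef(x, rowvar=False)
        for method in ("fa", "pc"):
            res = a.parallel_analysis(R, n=240, p=20, reps=200, seed=4,
                                      method=method)
            assert res.n_factors_pa == 4, method

    def test_reps_floor_enforced(self):
        with pytest.raises(ValidationError):
            a.parallel_analysis(np.eye(4), n=50, p=4, reps=10)


class TestPaf:
    def test_exact_one_factor_structure_recovered(self):
        lam = np.array([.8, .7, .6, .5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        loadings, h2, converged, _ = a.paf_extract(R, k=1, tol=1e-8)
        assert converged
        np.testing.assert_allclose(np.abs(loadings[:, 0]), lam, atol=1e-6)
        np.testing.assert_allclose(h2, lam ** 2, atol=1e-6)

    def test_matches_independent_recursion(self):
        lam = np.array([[.8, 0], [.7, .2], [.6, 0], [.1, .7], [0, .6]])
        R = lam @ lam.T + np.diag(1 - (lam ** 2).sum(axis=1))
        got, h2, converged, _ = a.paf_extract(R, k=2)
        want, h2_want = paf_oracle(R, k=2)
        np.testing.assert_allclose(np.abs(got), np.abs(want), atol=1e-10)
        np.testing.assert_allclose(h2, h2_want, atol=1e-10)

    def test_k_bounds_validated(self):
        with pytest.raises(ValidationError):
            a.paf_extract(np.eye(4), k=4)


class TestOblimin:
    def test_simple_structure_is_fixed_point(self):
        lam = make_cluster_loadings(p=6, k=2, value=0.8)
        pattern, structure, phi = a.oblimin_rotate(lam, seed=0)
        aligned = align(pattern, lam)
        np.testing.assert_allclose(aligned, lam, atol=1e-5)
        np.testing.assert_allclose(phi, np.eye(2), atol=1e-4)

    def test_matches_independent_optimizer(self):
        rng = np.random.default_rng(12)
        lam = np.array([[.75, .05], [.68, -.1], [.8, .12],
                        [.1, .7], [-.05, .66], [.08, .72]])
        R = lam @ lam.T + np.diag(1 - (lam ** 2).sum(axis=1))
        A, _, _, _ = a.paf_extract(R, k=2, tol=1e-8)
        pattern, structure, phi = a.oblimin_rotate(A, seed=1)
        L_o, phi_o, f_o = quartimin_oracle(A, seed=2)
        from actionspace.efa import _oblimin_criterion
        f_ours = _oblimin_criterion(pattern, 0.0)[0]
        assert f_ours == pytest.approx(f_o, abs=1e-5)
        aligned = align(L_o, pattern)
        np.testing.assert_allclose(aligned, pattern, atol=1e-3)

    def test_rotation_preserves_common_factor_covariance(self, default_matrix):
        R = a.pearson_corr(default_matrix)
        A, h2, _, _ = a.paf_extract(R.to_numpy(), k=4)
        pattern, structure, phi = a.oblimin_rotate(A, seed=0)
        np.testing.assert_allclose(pattern @ phi @ pattern.T, A @ A.T,
                                   atol=1e-8)
        # communalities unchanged by rotation
        np.testing.assert_allclose(np.diag(pattern @ phi @ pattern.T), h2,
                                   atol=1e-8)
        # structure = pattern @ phi by construction
        np.testing.assert_allclose(structure, pattern @ phi, atol=1e-12)

    def test_single_factor_passthrough(self):
        lam = np.array([[.8], [.6], [.4]])
        pattern, structure, phi = a.oblimin_rotate(lam)
        np.testing.assert_allclose(pattern, lam)
        np.testing.assert_allclose(phi, [[1.0]])


class TestInterpret:
    @pytest.mark.parametrize("row,expected", [
        ((.789, -.108, .067, .19), 0),      # clean primary loading
        ((.544, .381, -.012, .094), None),  # cross-loading >= .3
        ((.49, .0, .0, .0), None),          # primary below .5
        ((-.651, .1, .0, .2), 0),           # negative primary counts
    ])
    def test_substantial_rule(self, row, expected):
        s = np.array([row])
        interp = a.interpret(s, items=["x"])
        assignment = interp.assignments[0]
        if expected is None:
            assert not assignment.is_substantial
            assert assignment.primary_factor is None
        else:
            assert assignment.is_substantial
            assert assignment.primary_factor == expected

    def test_per_factor_lists(self):
        s = np.array([[.8, .0], [.7, .1], [.1, .9], [.4, .4]])
        interp = a.interpret(s, items=list("abcd"))
        assert interp.substantial_items(0) == ["a", "b"]
        assert interp.substantial_items(1) == ["c"]
        assert interp.loading_sign("a") == 1.0


class TestVarianceExplained:
    def test_orthogonal_case_is_column_sum_of_squares(self):
        lam = make_cluster_loadings(p=8, k=2, value=0.8)
        per, total = a.variance_explained(lam, lam, np.eye(2), p=8)
        np.testing.assert_allclose(per, 100 * (lam ** 2).sum(axis=0) / 8)
        assert total == pytest.approx(per.sum())

    def test_oblique_per_factor_sums_to_total(self, default_matrix):
        model = a.fit_efa(default_matrix, k=4, seed=0)
        assert model.var_explained_pct.sum() == pytest.approx(
            model.total_var_pct, abs=1e-9)
        assert model.total_var_pct == pytest.approx(
            100 * model.communalities.sum() / 20, abs=1e-6)


class TestFactorScores:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(6)
        lam = make_cluster_loadings(p=10, k=2, value=0.9)
        eta = rng.standard_normal((300, 2))
        import pandas as pd
        x = pd.DataFrame(eta @ lam.T + rng.standard_normal((300, 10)) * 0.01)
        x.columns = [str(c) for c in x.columns]
        model = a.fit_efa(x, k=2, seed=0)
        scores = a.factor_scores(x, model)
        corr = np.corrcoef(scores.to_numpy().T, eta.T)[:2, 2:]
        assert np.abs(corr).max(axis=1).min() > 0.99

    def test_matches_matrix_product_oracle(self, default_matrix):
        model = a.fit_efa(default_matrix, k=4, seed=0)
        scores = a.factor_scores(default_matrix, model)
        df = default_matrix.values
        z = (df - df.mean()) / df.std(ddof=1)
        expected = z.to_numpy() @ np.linalg.inv(model.corr.to_numpy()) @ model.structure
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-10)
        # standardised input => zero-mean scores
        np.testing.assert_allclose(scores.mean().to_numpy(), 0.0, atol=1e-10)


class TestCentrality:
    def test_identical_groups_give_null_t(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        base = rng.standard_normal((100, 4))
        scores = pd.DataFrame(np.vstack([base, base]))
        groups = np.array([0] * 100 + [1] * 100)
        t, df, p = a.centrality_test(scores, groups)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 198

    def test_known_shift_matches_formula_oracle(self):
        import pandas as pd
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(rng.standard_normal((240, 4)))
        scores.iloc[:120] *= 1.8          # first group further from centre
        groups = np.array([0] * 120 + [1] * 120)
        t, df, p = a.centrality_test(scores, groups)
        assert df == 238
        d = np.sqrt((scores.to_numpy() ** 2).sum(axis=1))
        a_, b_ = d[:120], d[120:]
        sp = np.sqrt(((len(a_) - 1) * a_.var(ddof=1)
                      + (len(b_) - 1) * b_.var(ddof=1)) / (len(d) - 2))
        t_expect = (a_.mean() - b_.mean()) / (sp * np.sqrt(1 / len(a_) + 1 / len(b_)))
        assert t == pytest.approx(t_expect, abs=1e-10)


class TestReducedEigenvalues:
    def test_reduced_below_unreduced_leading_eigenvalue(self, default_matrix):
        R = a.pearson_corr(default_matrix).to_numpy()
        red = reduced_eigenvalues(R)
        full = a.scree(R)
        assert red[0] < full[0]
        assert red.sum() < full.sum()
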