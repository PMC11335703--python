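"""CCA solver: oracle equivalence, invariances, loadings and redundancy."""

import numpy as np
import pytest

from nvucca.cca import (
    CanonicalCorrelation,
    canonical_loadings,
    redundancy,
    shared_variance,
    variance_extracted,
)
from nvucca.prep import build_matrices, invert_scores
from nvucca.simulate import LatentStructureSpec, generate_cohort

from conftest import random_pair


def eigen_oracle(X, Y):
    """Independent brute-force oracle: r^2 as eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx via a generic (non-symmetric) eigen-solver."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.linalg.eigvals(M)
    ev = np.sort(np.real(ev))[::-1]
    return np.clip(ev[: min(X.shape[1], Y.shape[1])], 0.0, 1.0)


class TestFitAgainstOracles:
    def test_mode_count_is_min_p_q(self, standard_pair):
        res = CanonicalCorrelation(standard_pair.X, standard_pair.Y).fit()
        assert res.n_modes == 5
        assert res.Lx.shape == (5, 5)
        assert res.Ly.shape == (13, 5)

    def test_self_correlation_is_unity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        res = CanonicalCorrelation(X, X.copy()).fit()
        np.testing.assert_allclose(res.r, 1.0, atol=1e-10)

    def test_two_by_two_closed_form(self):
        rng = np.random.default_rng(1)
        X, Y = random_pair(rng, 300, 2, 2, rho1=0.6)
        res = CanonicalCorrelation(X, Y).fit()
        np.testing.assert_allclose(res.r**2, eigen_oracle(X, Y), atol=1e-8)

    def test_fifty_random_instances_match_eigen_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.integers(1, 5)
            q = rng.integers(1, 5)
            X, Y = random_pair(rng, 200, int(p), int(q), rho1=float(rng.uniform(0, 0.7)))
            res = CanonicalCorrelation(X, Y).fit()
            np.testing.assert_allclose(res.r**2, eigen_oracle(X, Y), atol=1e-8)

    def test_matches_sklearn_first_mode(self, standard_pair):
        """Cross-check against scikit-learn's iterative CCA on the first pair."""
        from sklearn.cross_decomposition import CCA as SkCCA

        X, Y = standard_pair.X, standard_pair.Y
        sk = SkCCA(n_components=1).fit(X, Y)
        u, v = sk.transform(X, Y)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        res = CanonicalCorrelation(X, Y).fit()
        assert res.r[0] == pytest.approx(r_sk, abs=1e-6)


@pytest.fixture(scope="module")
def fitted(standard_pair):
    return CanonicalCorrelation(standard_pair.X, standard_pair.Y).fit()


class TestResultInvariants:
    def test_correlations_sorted_in_unit_interval(self, fitted):
        assert np.all(np.diff(fitted.r) <= 1e-12)
        assert np.all((fitted.r >= 0) & (fitted.r <= 1))

    def test_variates_unit_variance_and_within_set_orthogonal(self, fitted):
        for M in (fitted.U, fitted.V):
            np.testing.assert_allclose(M.std(axis=0, ddof=1), 1.0, atol=1e-8)
            C = np.corrcoef(M.T)
            np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)

    def test_paired_variates_correlate_at_r(self, fitted):
        for k in range(fitted.n_modes):
            c = np.corrcoef(fitted.U[:, k], fitted.V[:, k])[0, 1]
            assert c == pytest.approx(fitted.r[k], abs=1e-8)

    def test_loadings_bounded(self, fitted):
        assert np.all(np.abs(fitted.Lx) <= 1 + 1e-10)
        assert np.all(np.abs(fitted.Ly) <= 1 + 1e-10)

    def test_affine_invariance(self, standard_pair):
        rng = np.random.default_rng(3)
        X, Y = standard_pair.X, standard_pair.Y
        r0 = CanonicalCorrelation(X, Y).fit().r
        A = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        B = rng.standard_normal((13, 13)) + 3 * np.eye(13)
        r1 = CanonicalCorrelation(X @ A, Y @ B).fit().r
        np.testing.assert_allclose(r1, r0, atol=1e-8)

    def test_first_mode_maximality(self, fitted, standard_pair):
        rng = np.random.default_rng(4)
        X, Y = standard_pair.X, standard_pair.Y
        best = fitted.r[0]
        for _ in range(1000):
            a = rng.standard_normal(5)
            b = rng.standard_normal(13)
            c = abs(np.corrcoef(X @ a, Y @ b)[0, 1])
            assert c <= best + 1e-10

    def test_variance_extracted_completeness_smaller_set(self, fitted):
        """Per-variable squared X-loadings sum to 1 across all K modes."""
        np.testing.assert_allclose(np.sum(fitted.Lx**2, axis=1), 1.0, atol=1e-8)
        assert fitted.var_extracted_x.sum() == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_deterministic(self, standard_pair):
        X, Y = standard_pair.X, standard_pair.Y
        r1 = CanonicalCorrelation(X, Y).fit()
        r2 = CanonicalCorrelation(X, Y).fit()
        np.testing.assert_array_equal(r1.Lx, r2.Lx)
        for k in range(r1.n_modes):
            j = np.argmax(np.abs(r1.Lx[:, k]))
            assert r1.Lx[j, k] > 0

    def test_single_variable_set_loading_is_unit(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 1))
        Y = rng.standard_normal((100, 3))
        res = CanonicalCorrelation(X, Y).fit()
        assert abs(res.Lx[0, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_orthonormal_columns_loadings_equal_weights(self):
        """For orthonormal X columns, loadings equal weights up to scaling."""
        rng = np.random.default_rng(6)
        X0 = rng.standard_normal((400, 3))
        # orthonormalise columns exactly (sample covariance = I)
        Xc = X0 - X0.mean(axis=0)
        Q, _ = np.linalg.qr(Xc)
        X = Q * np.sqrt(400 - 1)
        Y = X @ rng.standard_normal((3, 4)) + 0.5 * rng.standard_normal((400, 4))
        res = CanonicalCorrelation(X, Y).fit()
        for k in range(res.n_modes):
            w = res.Wx[:, k]
            np.testing.assert_allclose(res.Lx[:, k], w / np.linalg.norm(w), atol=1e-8)


class TestInterpretationQuantities:
    def test_shared_variance_values(self):
        assert round(100 * shared_variance(0.73), 1) == 53.3
        assert shared_variance(0.0) == 0.0
        assert shared_variance(1.0) == 1.0
        with pytest.raises(ValueError):
            shared_variance(1.2)

    def test_variance_extracted_values(self):
        assert variance_extracted(np.array([1.0, 1.0, 1.0])) == 1.0
        assert variance_extracted(np.array([0.0, 0.0])) == 0.0
        L = np.sqrt(np.array([0.3, 0.18, 0.24]))  # squares average to 0.24
        assert variance_extracted(L) == pytest.approx(0.240)
        with pytest.raises(ValueError):
            variance_extracted(np.array([]))

    def test_redundancy_reproduces_reported_identities(self):
        assert round(100 * redundancy(0.240, 0.73), 1) == 12.8
        assert round(100 * redundancy(0.231, 0.73), 1) == 12.3
        assert redundancy(0.5, 0.0) == 0.0
        with pytest.raises(ValueError):
            redundancy(1.4, 0.5)

    def test_canonical_loadings_function(self, standard_pair):
        res = CanonicalCorrelation(standard_pair.X, standard_pair.Y).fit()
        L = canonical_loadings(standard_pair.X, res.U)
        np.testing.assert_allclose(L, res.Lx, atol=1e-10)


class TestParameterRecovery:
    def test_planted_first_mode_recovered_with_optimism(self):
        """Planted rho1 = 0.73 at n = 73: mean fitted r1 over 500 cohorts lies
        in 0.73 +/- 0.08 and the optimism bias is positive."""
        r1s = []
        for seed in range(500):
            table, _ = generate_cohort(
                LatentStructureSpec(
                    n_subjects=73, n_excluded=0, missing_rate=0.0, seed=seed
                )
            )
            pair = build_matrices(invert_scores(table))
            r1s.append(CanonicalCorrelation(pair.X, pair.Y).fit().r[0])
        mean_r1 = float(np.mean(r1s))
        assert abs(mean_r1 - 0.73) < 0.08
        assert mean_r1 > 0.73  # finite-sample optimism of the maximal correlation


class TestModelValidation:
    def test_rejects_small_n_and_nan(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            CanonicalCorrelation(rng.standard_normal((5, 5)), rng.standard_normal((5, 13)))
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 4))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError):
            CanonicalCorrelation(X, Y)

    def test_from_dataframe_roundtrip(self, default_cohort):
        import nvucca.datadict as dd
        import pandas as pd

        table, _ = default_cohort
        pair = build_matrices(invert_scores(table))
        df = pd.DataFrame(
            np.hstack([pair.X, pair.Y]), columns=pair.x_names + pair.y_names
        )
        m = CanonicalCorrelation.from_dataframe(df, dd.NVU_VARS, pair.y_names)
        res = m.fit()
        assert res.n_modes == 5
        assert m.x_names == dd.NVU_VARS

    def test_summary_renders(self, standard_pair):
        res = CanonicalCorrelation(standard_pair.X, standard_pair.Y).fit()
        text = res.summary()
        assert "Canonical Correlation Analysis" in text
        assert "total redundancy" in text
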