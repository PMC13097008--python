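import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from adaptscape.structure import (
    geography_matrix,
    haversine_matrix,
    mantel,
    partial_mantel,
    pca_genotypes,
    prda_outliers,
    rda_fit,
    variance_partition,
)


class TestPCA:
    def test_duplicated_individuals_get_identical_scores(self):
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 3, size=(10, 30)).astype(float)
        Y = np.vstack([Y, Y[0]])
        res = pca_genotypes(Y)
        assert np.allclose(res.scores[0], res.scores[-1], atol=1e-8)

    def test_explained_fractions_valid(self):
        rng = np.random.default_rng(1)
        res = pca_genotypes(rng.integers(0, 3, size=(20, 50)).astype(float))
        assert res.explained_fraction.sum() <= 1 + 1e-9
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_two_individual_toy_single_axis(self):
        Y = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 2.0]])
        res = pca_genotypes(Y)
        # one nonzero axis; scores symmetric about 0
        assert res.explained_fraction[0] > 1 - 1e-12
        assert np.isclose(res.scores[0, 0], -res.scores[1, 0])

    def test_missing_rejected(self):
        Y = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            pca_genotypes(Y)


class TestHaversine:
    def test_closed_form_one_degree(self):
        coords = pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 0.0]})
        d = haversine_matrix(coords)
        assert abs(d[0, 1] - np.pi * 6371.0 / 180.0) < 1e-6  # 111.195 km
        assert abs(d[0, 1] - 111.195) < 1e-3

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        coords = pd.DataFrame({
            "lon": rng.uniform(-120, -115, 6), "lat": rng.uniform(33, 38, 6),
        })
        d = haversine_matrix(coords)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestMantel:
    def _dist(self, seed, n=15, k=3):
        rng = np.random.default_rng(seed)
        return squareform(pdist(rng.normal(size=(n, k))))

    def test_identical_matrices_r1_minimal_p(self):
        d = self._dist(0)
        res = mantel(d, d, n_perm=99, seed=1)
        assert np.isclose(res.statistic, 1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_matches_independent_oracle(self):
        """Cross-check the statistic and p-value against scikit-bio's mantel."""
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 3))
        Y = X + rng.normal(size=(15, 3)) * 0.5
        dA, dB = squareform(pdist(X)), squareform(pdist(Y))
        ours = mantel(dA, dB, n_perm=999, seed=1)
        r_sk, p_sk, _ = sk_mantel(
            DistanceMatrix(dA), DistanceMatrix(dB),
            permutations=999, alternative="greater",
        )
        assert np.isclose(ours.statistic, r_sk, atol=1e-12)
        assert abs(ours.p_value - p_sk) < 0.05

    def test_null_r_near_zero_over_seeds(self):
        rs = []
        for s in range(20):
            dA, dB = self._dist(100 + s), self._dist(200 + s)
            rs.append(mantel(dA, dB, n_perm=49, seed=s).statistic)
        assert abs(np.mean(rs)) < 0.1

    def test_p_at_least_permutation_resolution(self):
        d = self._dist(4)
        res = mantel(d, d + 0, n_perm=19, seed=0)
        assert res.p_value >= 1 / 20


class TestPartialMantel:
    def test_environment_equal_geography_gives_null_partial(self):
        rng = np.random.default_rng(5)
        dC = squareform(pdist(rng.normal(size=(15, 2))))
        dA = dC * 2 + squareform(pdist(rng.normal(size=(15, 2)))) * 0.05
        res = partial_mantel(dA, dC.copy(), dC, n_perm=99, seed=0)
        assert abs(res.statistic) < 0.3  # signal absorbed by the covariate

    def test_constant_covariate_reduces_to_simple_mantel(self):
        rng = np.random.default_rng(6)
        dA = squareform(pdist(rng.normal(size=(12, 2))))
        dB = squareform(pdist(rng.normal(size=(12, 2))))
        dC = np.ones_like(dA) - np.eye(len(dA))
        simple = mantel(dA, dB, n_perm=9, seed=0)
        partial = partial_mantel(dA, dB, dC, n_perm=9, seed=0)
        assert np.isclose(partial.statistic, simple.statistic, atol=1e-10)


class TestRDA:
    def test_orthogonal_predictor_explains_nothing(self):
        rng = np.random.default_rng(7)
        n = 200
        X = rng.normal(size=(n, 1))
        Y = rng.normal(size=(n, 10))  # independent of X
        fit = rda_fit(Y, X)
        assert fit.constrained_variance / fit.total_variance < 0.05

    def test_conditioning_on_x_removes_everything(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3))
        Y = X @ rng.normal(size=(3, 20)) + rng.normal(size=(50, 20)) * 0.1
        fit = rda_fit(Y, X, Z=X)
        assert fit.constrained_variance < 1e-12

    def test_single_predictor_recovers_regression_fit(self):
        rng = np.random.default_rng(9)
        n, m = 100, 15
        x = rng.normal(size=(n, 1))
        B = rng.normal(size=(1, m))
        Y = x @ B + rng.normal(size=(n, m)) * 0.3
        fit = rda_fit(Y, x)
        # constrained variance equals the fitted variance of the direct
        # multivariate least-squares regression
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        beta = np.linalg.lstsq(xc, Yc, rcond=None)[0]
        expected = ((xc @ beta) ** 2).sum() / (n - 1)
        assert np.isclose(fit.constrained_variance, expected, rtol=1e-10)

    def test_eigenvalues_non_negative_non_increasing(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(60, 40))
        X = rng.normal(size=(60, 5))
        fit = rda_fit(Y, X)
        assert np.all(fit.eigenvalues >= 0)
        assert np.all(np.diff(fit.eigenvalues) <= 1e-12)

    def test_empty_condition_equals_plain(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(30, 8))
        X = rng.normal(size=(30, 2))
        f1, f2 = rda_fit(Y, X), rda_fit(Y, X, Z=None)
        assert np.allclose(f1.eigenvalues, f2.eigenvalues)


class TestVariancePartition:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(12)
        n = 80
        clim = rng.normal(size=(n, 3))
        geo = rng.normal(size=(n, 3))
        struct = rng.normal(size=(n, 1))
        Y = clim @ rng.normal(size=(3, 30)) + rng.normal(size=(n, 30))
        vp = variance_partition(Y, clim, geo, struct, n_perm=19, seed=0)
        assert abs(sum(vp.fractions.values()) - 1.0) < 1e-9

    def test_duplicated_climate_in_geography_kills_unique_fraction(self):
        rng = np.random.default_rng(13)
        n = 80
        clim = rng.normal(size=(n, 3))
        Y = clim @ rng.normal(size=(3, 30)) + rng.normal(size=(n, 30)) * 0.2
        vp = variance_partition(Y, clim, clim.copy(), rng.normal(size=(n, 1)),
                                n_perm=9, seed=0)
        assert vp.fractions["climate"] < 0.02
        assert vp.fractions["confounded"] > 0.3

    def test_orthogonal_groups_are_additive(self):
        rng = np.random.default_rng(14)
        n = 500
        clim, geo, struct = (rng.normal(size=(n, 2)) for _ in range(3))
        Y = (clim @ rng.normal(size=(2, 20)) + geo @ rng.normal(size=(2, 20))
             + rng.normal(size=(n, 20)) * 0.5)
        vp = variance_partition(Y, clim, geo, struct, n_perm=9, seed=0)
        full = 1 - vp.fractions["unexplained"]
        uniques = (vp.fractions["climate"] + vp.fractions["geography"]
                   + vp.fractions["structure"])
        assert abs(full - uniques) < 0.05  # confounded ~ 0 for orthogonal groups


class TestPrdaOutliers:
    def test_locus_order_invariance(self, small_fixture):
        import adaptscape as a

        cfg, gm, truth, coords, grids = small_fixture
        gm = a.impute_major(gm)
        env = a.extract_at_points(grids["recent"], coords)[list(cfg.variables)]
        pca = pca_genotypes(gm.dosages)
        cond = np.column_stack([geography_matrix(coords), pca.scores[:, :1]])
        ids = gm.variants["id"].tolist()
        r1 = prda_outliers(gm.dosages, env.to_numpy(), cond, locus_ids=ids, seed=3)
        perm = np.random.default_rng(0).permutation(gm.n_variants)
        r2 = prda_outliers(
            gm.dosages[:, perm], env.to_numpy(), cond,
            locus_ids=[ids[j] for j in perm], seed=3,
        )
        assert set(r1.outlier_ids) == set(r2.outlier_ids)

    def test_alpha_is_bonferroni_exact(self):
        rng = np.random.default_rng(15)
        Y = rng.normal(size=(40, 123))
        X = rng.normal(size=(40, 3))
        res = prda_outliers(Y, X, None, seed=0, n_axis_perm=19)
        assert res.alpha == 0.01 / 123

    def test_missing_dosages_rejected(self):
        Y = np.array([[0.0, np.nan], [1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            prda_outliers(Y, np.random.default_rng(0).normal(size=(3, 2)), None)
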