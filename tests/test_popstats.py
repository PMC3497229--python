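import itertools

import numpy as np
import pandas as pd
import pytest

import genomosaic as g
from genomosaic.popstats import (
    DistanceMatrix,
    covariate_pca,
    isolation_index,
    morph_divergence,
)
from genomosaic.types import GenotypePosterior, ValidationError


def random_dm(rng, n, labels=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels or [f"P{i}" for i in range(n)], m)


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(["a", "b"], m)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValidationError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 0.0]]))


class TestMantel:
    def test_self_correlation_is_one_with_floor_p(self):
        rng = np.random.default_rng(0)
        x = random_dm(rng, 8)
        res = g.mantel(x, x, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_exact_enumeration_oracle_n4(self):
        """Random-permutation mode is replaced by exhaustive enumeration at n=4
        and must match an independently coded oracle."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = random_dm(rng, 4)
            y = random_dm(rng, 4)
            res = g.mantel(x, y, exact=True)
            iu = np.triu_indices(4, 1)
            u = x.values[iu]
            r_obs = np.corrcoef(u, y.values[iu])[0, 1]
            hits = 0
            for perm in itertools.permutations(range(4)):
                yp = y.values[np.ix_(perm, perm)]
                r_p = np.corrcoef(u, yp[iu])[0, 1]
                hits += abs(r_p) >= abs(r_obs) - 1e-15
            assert res.p == pytest.approx(hits / 24)
            assert res.r == pytest.approx(r_obs)

    def test_agrees_with_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(3)
        x = random_dm(rng, 9)
        y = random_dm(rng, 9)
        r_sk, p_sk, _ = sk_mantel(
            SkDM(x.values, ids=x.labels), SkDM(y.values, ids=y.labels),
            permutations=999, alternative="two-sided",
        )
        res = g.mantel(x, y, n_perm=999, seed=4)
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)
        assert res.p == pytest.approx(float(p_sk), abs=0.05)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            x = random_dm(rng, 8)
            y = random_dm(rng, 8)
            res = g.mantel(x, y, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se

    def test_label_reordering_invariance(self):
        rng = np.random.default_rng(6)
        x = random_dm(rng, 6)
        y = random_dm(rng, 6)
        y_shuffled = y.reorder(["P3", "P0", "P5", "P1", "P4", "P2"])
        res1 = g.mantel(x, y, n_perm=99, seed=7)
        res2 = g.mantel(x, y_shuffled, n_perm=99, seed=7)
        assert res1.r == pytest.approx(res2.r)
        assert res1.p == res2.p

    def test_p_floor_respected(self):
        rng = np.random.default_rng(8)
        x = random_dm(rng, 7)
        for n_perm in (9, 99):
            res = g.mantel(x, x, n_perm=n_perm, seed=9)
            assert res.p >= 1 / (n_perm + 1) - 1e-15

    def test_constant_matrix_rejected(self):
        ones = np.ones((5, 5)) - np.eye(5)
        x = DistanceMatrix(list("abcde"), ones)
        with pytest.raises(ValidationError, match="constant"):
            g.mantel(x, x, n_perm=9)


class TestPartialMantel:
    def test_covariate_equal_to_y_removes_signal(self):
        rng = np.random.default_rng(10)
        x = random_dm(rng, 8)
        y = random_dm(rng, 8)
        res = g.partial_mantel(x, y, y, n_perm=99, seed=11)
        assert abs(res.r) < 1e-10

    def test_uncorrelated_covariate_preserves_r(self):
        rng = np.random.default_rng(12)
        diffs = []
        for _ in range(10):
            x = random_dm(rng, 10)
            y = random_dm(rng, 10)
            z = random_dm(rng, 10)
            simple = g.mantel(x, y, n_perm=9, seed=1).r
            partial = g.partial_mantel(x, y, z, n_perm=9, seed=1).r
            diffs.append(abs(simple - partial))
        assert np.mean(diffs) < 0.15

    def test_confound_removal(self):
        """X and Y correlated only through Z: simple rejects, partial near null."""
        rng = np.random.default_rng(13)
        simple_p, partial_p = [], []
        for _ in range(25):
            z = random_dm(rng, 9)
            noise1 = random_dm(rng, 9)
            noise2 = random_dm(rng, 9)
            x = DistanceMatrix(z.labels, z.values + 0.4 * noise1.values)
            y = DistanceMatrix(z.labels, z.values + 0.4 * noise2.values)
            simple_p.append(g.mantel(x, y, n_perm=99, seed=14).p)
            partial_p.append(g.partial_mantel(x, y, z, n_perm=99, seed=14).p)
        assert np.mean(np.array(simple_p) <= 0.05) > 0.5
        assert np.mean(np.array(partial_p) <= 0.05) < 0.3


class TestGenotypePca:
    def _gpost(self, probs):
        n_ind, n_loc, _ = probs.shape
        return GenotypePosterior(
            [f"i{k}" for k in range(n_ind)], [f"c:{j}" for j in range(n_loc)], probs
        )

    def test_identical_individuals_have_zero_variance(self):
        probs = np.tile(np.array([0.25, 0.5, 0.25]), (4, 5, 1))
        scores, ratios = g.genotype_pca(self._gpost(probs))
        assert not scores.any()
        assert np.isnan(ratios).all()

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(20)
        a = np.tile(np.array([0.9, 0.09, 0.01]), (10, 40, 1))
        b = np.tile(np.array([0.01, 0.09, 0.9]), (10, 40, 1))
        probs = np.concatenate([a, b]) + rng.normal(0, 0.01, (20, 40, 3))
        scores, ratios = g.genotype_pca(self._gpost(np.clip(probs, 0, 1)))
        pc1 = scores[:, 0]
        assert (pc1[:10].max() < pc1[10:].min()) or (pc1[10:].max() < pc1[:10].min())
        assert ratios[0] > 0.9

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(21)
        probs = rng.dirichlet(np.ones(3), size=(12, 30))
        s1, _ = g.genotype_pca(self._gpost(probs))
        s2, _ = g.genotype_pca(self._gpost(probs))
        np.testing.assert_array_equal(s1, s2)

    def test_isolation_by_distance_recovered(self, small_truth, small_counts):
        """PC-score distances correlate with geography on simulated data."""
        from scipy.spatial.distance import pdist, squareform

        from genomosaic.allele_freq import MCMCConfig

        _, gpost = g.estimate_allele_frequencies(
            small_counts,
            mcmc=MCMCConfig(iterations=1500, burn_in=300, thinning=3, seed=22),
        )
        scores, _ = g.genotype_pca(gpost, mode="two_state")
        # mean PC1-2 position per population vs geographic distance
        pops = small_truth.pop_labels
        centroids = []
        for lab in pops:
            idx = small_counts.individual_indices(lab)
            centroids.append(scores[idx, :2].mean(axis=0))
        gen_d = squareform(pdist(np.array(centroids)))
        geo_d = squareform(pdist(small_truth.config.coords))
        res = g.mantel(
            DistanceMatrix(pops, geo_d), DistanceMatrix(pops, gen_d),
            n_perm=999, tail="greater", seed=23,
        )
        assert res.r > 0
        assert res.p <= 0.05


class TestClineRegression:
    def _covariates(self, rng, n=12):
        return pd.DataFrame(
            {
                "climPC1": rng.normal(size=n),
                "climPC2": rng.normal(size=n),
                "longitude": rng.normal(size=n),
            }
        )

    def test_constant_frequency_has_zero_slopes(self):
        rng = np.random.default_rng(30)
        cov = self._covariates(rng)
        fit = g.cline_regression(np.full(12, 0.4), cov)
        assert np.allclose(fit.coefficients, 0.0)
        assert (fit.p_values == 1.0).all()

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(31)
        cov = self._covariates(rng)
        freq = 0.1 + 0.05 * cov["climPC1"].to_numpy()
        fit = g.cline_regression(freq, cov)
        sd = cov["climPC1"].to_numpy().std()  # ddof=0, matching the z-scoring
        assert fit.coefficients["climPC1"] == pytest.approx(0.05 * sd, abs=1e-10)
        assert abs(fit.coefficients["climPC2"]) < 1e-10
        assert fit.p_values["climPC1"] < 1e-9

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(32)
        cov = self._covariates(rng, n=15)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            freq = rng.random(15)
            fit = g.cline_regression(freq, cov)
            rejections += fit.p_values["climPC1"] <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se + 0.01

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(33)
        cov = self._covariates(rng)
        cov["climPC2"] = 2.0 * cov["climPC1"]
        with pytest.raises(ValidationError, match="collinear"):
            g.cline_regression(rng.random(12), cov)

    def test_covariate_pca_helper(self):
        rng = np.random.default_rng(34)
        cov = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        scores, ratios = covariate_pca(cov)
        assert scores.shape == (10, 4)
        assert ratios.sum() == pytest.approx(1.0)


class TestBehaviouralIndices:
    def test_isolation_index_formula(self):
        assert isolation_index(50.0, 50.0) == 0.0
        assert isolation_index(50.0, 0.0) == 1.0
        assert isolation_index(50.0, 25.0) == 0.5
        assert isolation_index(20.0, 30.0) == pytest.approx(-0.5)  # not clamped

    def test_isolation_index_undefined_at_zero_within(self):
        with pytest.raises(ValidationError):
            isolation_index(0.0, 10.0)

    def test_morph_divergence(self):
        assert morph_divergence(90.0, 6.0) == pytest.approx(84.0)
        assert morph_divergence(6.0, 90.0) == pytest.approx(-84.0)
        assert morph_divergence(50.0, 50.0) == 0.0
        with pytest.raises(ValidationError):
            morph_divergence(110.0, 50.0)


class TestTwoSampleTTest:
    def test_identical_groups(self):
        t, df, p = g.two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_student_df_convention(self):
        _, df, _ = g.two_sample_ttest([0.5, 0.6, 0.4], [0.2, 0.25, 0.3])
        assert df == 4.0  # n1 + n2 - 2, the pooled-variance convention

    def test_matches_reference_implementation(self):
        from scipy import stats as sps

        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, df, p = g.two_sample_ttest(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(t_ref), abs=1e-9)
        assert p == pytest.approx(float(p_ref), abs=1e-9)

    def test_welch_df_differs_under_variance_heterogeneity(self):
        a = [1.0, 1.1, 0.9, 1.05]
        b = [2.0, 5.0, -1.0, 3.0]
        _, df_s, _ = g.two_sample_ttest(a, b, variant="student")
        _, df_w, _ = g.two_sample_ttest(a, b, variant="welch")
        assert df_w < df_s

    def test_degenerate_zero_variance(self):
        t, _, p = g.two_sample_ttest([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = g.two_sample_ttest([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and np.isinf(t)
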