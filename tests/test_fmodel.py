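import numpy as np
import pytest
from scipy.special import expit, logit

import genomosaic as g
from genomosaic.allele_freq import MCMCConfig
from genomosaic.fmodel import (
    PairAlleleCounts,
    fmodel_beta_params,
    sample_fmodel_counts,
)
from genomosaic.types import ValidationError

FAST = MCMCConfig(iterations=4000, burn_in=1000, thinning=3, seed=0)


def counts_from_arrays(x, n):
    x = np.asarray(x)
    loci = [f"l{i}:1" for i in range(x.shape[1])]
    return PairAlleleCounts(("A", "B"), loci, x, n)


class TestBetaParameterization:
    @pytest.mark.parametrize("pi", [0.5, 0.2])
    @pytest.mark.parametrize("fst", [0.05, 0.3])
    def test_variance_is_fst_pi_one_minus_pi(self, pi, fst):
        a, b = fmodel_beta_params(pi, fst)
        analytic_var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert analytic_var == pytest.approx(fst * pi * (1 - pi), rel=1e-12)
        draws = np.random.default_rng(7).beta(a, b, size=100_000)
        assert draws.var() == pytest.approx(fst * pi * (1 - pi), rel=0.05)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValidationError):
            fmodel_beta_params(0.5, 1.0)


class TestFitFmodel:
    def test_identical_balanced_counts_give_near_zero_fst(self):
        x = np.full((2, 200), 30)
        n = np.full((2, 200), 60)
        fit = g.fit_fmodel(counts_from_arrays(x, n), mcmc=FAST, store_samples=False)
        genome_fst = float(expit(fit.mu_samples).mean())
        assert genome_fst < 0.05

    def test_extreme_divergence_has_max_alpha_and_high_flag(self):
        rng = np.random.default_rng(3)
        pc = sample_fmodel_counts(logit(0.05), 6.0, 501, 40, rng)
        # one locus fixed for alternative alleles across the pair
        pc.alt[:, 0] = (0, 40)
        pc.total[:, 0] = 40
        fit = g.fit_fmodel(pc, mcmc=FAST, store_samples=False)
        assert np.nanargmax(fit.alpha_point) == 0
        assert fit.outlier_flags[0] == "high"

    def test_no_data_loci_excluded_and_too_few_polymorphic_raises(self):
        x = np.array([[0, 0, 5, 0], [0, 10, 5, 0]])
        n = np.array([[8, 10, 10, 0], [9, 10, 10, 0]])
        pc = counts_from_arrays(x, n)
        # locus 0 is sample-monomorphic but stays usable (the full SNP panel
        # enters every pairwise comparison); locus 3 carries no data at all
        assert list(pc.usable_mask()) == [True, True, True, False]
        assert list(pc.polymorphic_mask()) == [False, True, True, False]
        with pytest.raises(ValidationError, match="polymorphic"):
            g.fit_fmodel(counts_from_arrays(x[:, :1], n[:, :1]), mcmc=FAST)

    def test_recovery_of_genome_level_mu(self):
        """95% CI for mu covers the generating value (spot check, 4 reps)."""
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(4):
            pc = sample_fmodel_counts(logit(0.1), 4.0, 400, 40, rng)
            fit = g.fit_fmodel(
                pc,
                mcmc=MCMCConfig(iterations=5000, burn_in=1200, thinning=3,
                                seed=50 + rep),
                store_samples=False,
            )
            lo, hi = np.quantile(fit.mu_samples, [0.025, 0.975])
            hits += lo <= logit(0.1) <= hi
        assert hits >= 3

    def test_migration_monotonically_reduces_genome_fst(self):
        """More migration in the landscape -> lower posterior genome F_ST."""
        genome_fst = []
        for m0 in (0.0, 0.05, 0.2):
            cfg = g.LandscapeConfig(
                n_pops=2,
                coords=np.array([[0.0, 0.0], [2.0, 0.0]]),
                hosts=["Adenostoma", "Ceanothus"],
                adjacency_pairs=[],
                n_loci=300,
                locus_class_fractions={"neutral": 1.0},
                m0=m0,
                n_generations=100,
                n_sampled=20,
                seed=77,
            )
            truth = g.simulate_landscape(cfg)
            counts = g.simulate_reads(truth, mean_coverage=3.0, seed=78)
            pc = g.counts_from_reads(counts, tuple(truth.pop_labels))
            fit = g.fit_fmodel(pc, mcmc=FAST, store_samples=False)
            genome_fst.append(float(expit(fit.mu_samples).mean()))
        assert genome_fst[0] >= genome_fst[1] >= genome_fst[2]

    def test_doubling_iterations_is_stable(self):
        rng = np.random.default_rng(5)
        pc = sample_fmodel_counts(logit(0.08), 5.0, 300, 40, rng)
        short = g.fit_fmodel(
            pc, mcmc=MCMCConfig(iterations=4000, burn_in=1000, thinning=3, seed=1),
            store_samples=True,
        )
        long = g.fit_fmodel(
            pc, mcmc=MCMCConfig(iterations=8000, burn_in=1000, thinning=3, seed=2),
            store_samples=True,
        )
        se = short.alpha_samples.std(axis=1) / 10  # crude MC error per locus
        close = np.abs(short.alpha_point - long.alpha_point) < 3 * np.maximum(se, 0.05)
        assert close[short.included].mean() >= 0.95


class TestGenomewideQuantiles:
    def test_degenerate_distribution_collapses(self):
        mu = np.zeros(200)
        tau = np.full(200, 1e8)
        lo, hi = g.genomewide_alpha_quantiles(mu, tau, q=0.95, seed=0)
        assert abs(lo) < 1e-3 and abs(hi) < 1e-3

    def test_standard_normal_quantiles(self):
        mu = np.zeros(2000)
        tau = np.ones(2000)
        lo, hi = g.genomewide_alpha_quantiles(mu, tau, q=0.95, k_per_draw=50, seed=1)
        assert lo == pytest.approx(-1.645, abs=0.05)
        assert hi == pytest.approx(1.645, abs=0.05)

    def test_hyperparameter_uncertainty_widens_interval(self):
        rng = np.random.default_rng(2)
        tau = np.ones(2000)
        lo0, hi0 = g.genomewide_alpha_quantiles(np.zeros(2000), tau, seed=3)
        spread_mu = rng.normal(0.0, 1.5, 2000)
        lo1, hi1 = g.genomewide_alpha_quantiles(spread_mu, tau, seed=3)
        assert hi1 - lo1 > hi0 - lo0

    def test_domain_checks(self):
        with pytest.raises(ValidationError):
            g.genomewide_alpha_quantiles(np.zeros(200), np.ones(200), q=0.4)
        with pytest.raises(ValidationError):
            g.genomewide_alpha_quantiles(np.zeros(50), np.ones(50))


class TestOutlierFlags:
    def test_points_at_center_are_never_outliers(self):
        rng = np.random.default_rng(4)
        pc = sample_fmodel_counts(logit(0.05), 6.0, 300, 40, rng)
        fit = g.fit_fmodel(pc, mcmc=FAST, store_samples=False)
        mu_mean = fit.mu_samples.mean()
        fit.alpha_point = np.full_like(fit.alpha_point, mu_mean)
        flags = g.call_outliers(fit, seed=0)
        assert set(flags[fit.included]) == {"none"}

    def test_flags_respect_interval(self):
        rng = np.random.default_rng(8)
        pc = sample_fmodel_counts(logit(0.05), 6.0, 300, 40, rng)
        fit = g.fit_fmodel(pc, mcmc=FAST, store_samples=False)
        lo, hi = fit.predictive_q
        flags = fit.outlier_flags
        pts = fit.alpha_point
        inc = fit.included
        assert ((pts[inc] > hi) == (flags[inc] == "high")).all()
        assert ((pts[inc] < lo) == (flags[inc] == "low")).all()


class TestFstDistributionSummary:
    def test_toy_skewness_hand_computation(self):
        # fst values {0, 0, 1}: m2 = 2/9, m3 = 2/27, g1 = 1/sqrt(2)
        fit = _summary_fixture(np.array([0.0, 0.0, 1.0]))
        s = g.fst_distribution_summary(fit)
        assert s.skewness == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert s.variance == pytest.approx(2 / 9, rel=1e-12)

    def test_symmetric_vector_has_zero_skew(self):
        s = g.fst_distribution_summary(_summary_fixture(np.array([0.1, 0.2, 0.3])))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.kurtosis_raw == pytest.approx(s.kurtosis_excess + 3.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            g.fst_distribution_summary(_summary_fixture(np.full(5, 0.2)))


def _summary_fixture(fst_values):
    n = len(fst_values)
    return g.PairDivergence(
        pair=("A", "B"),
        loci=[f"l{i}:1" for i in range(n)],
        included=np.ones(n, dtype=bool),
        alpha_point=logit(np.clip(fst_values, 1e-6, 1 - 1e-6)),
        fst_point=np.asarray(fst_values, dtype=float),
        mu_samples=np.zeros(200),
        tau_samples=np.ones(200),
    )
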