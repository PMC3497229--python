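import numpy as np
import pytest

import genomosaic as g
from genomosaic.gene_flow import hudson_fst_per_locus
from genomosaic.popstats import hudson_fst
from genomosaic.simulate import migration_kernel, migration_matrix
from genomosaic.types import ValidationError


def _two_pop_config(d_km, **kw):
    base = dict(
        n_pops=2,
        coords=np.array([[0.0, 0.0], [d_km, 0.0]]),
        hosts=["Adenostoma", "Adenostoma"],
        adjacency_pairs=[],
        n_loci=400,
        locus_class_fractions={"neutral": 1.0},
        n_sampled=10,
    )
    base.update(kw)
    return g.LandscapeConfig(**base)


class TestMigrationKernel:
    def test_hard_zero_beyond_cutoff(self):
        d = np.array([0.0, 5.0, 11.9, 12.0, 12.1, 25.0])
        m = migration_kernel(d, m0=0.1, delta_km=2.5, cutoff_km=12.0)
        assert m[3] > 0.0
        assert m[4] == 0.0
        assert m[5] == 0.0

    def test_monotone_non_increasing(self):
        d = np.linspace(0, 30, 301)
        m = migration_kernel(d, m0=0.2, delta_km=3.0, cutoff_km=15.0)
        assert (np.diff(m) <= 1e-15).all()

    def test_row_mass_capped(self):
        cfg = g.default_landscape_config(m0=0.5, delta_km=50.0, cutoff_km=100.0)
        m = migration_matrix(cfg)
        assert (m.sum(axis=1) <= 0.5 + 1e-12).all()


class TestSimulateLandscape:
    def test_determinism(self):
        cfg = g.default_landscape_config(n_loci=100, n_generations=20, seed=5)
        a = g.simulate_landscape(cfg)
        b = g.simulate_landscape(cfg)
        np.testing.assert_array_equal(a.true_freqs, b.true_freqs)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_zero_generations_means_no_divergence(self):
        cfg = _two_pop_config(20.0, n_generations=0, seed=3)
        truth = g.simulate_landscape(cfg)
        np.testing.assert_allclose(truth.true_freqs[0], truth.true_freqs[1])
        assert hudson_fst(truth.true_freqs[0], truth.true_freqs[1]) == pytest.approx(0.0)

    def test_no_migration_removes_distance_effect(self):
        """With m0 = 0 a 1 km pair and a 20 km pair drift apart equally fast."""
        fsts = {1.0: [], 20.0: []}
        for seed in range(4):
            for d in fsts:
                cfg = _two_pop_config(d, m0=0.0, pop_size=50, n_generations=200,
                                      seed=100 + seed)
                t = g.simulate_landscape(cfg)
                fsts[d].append(hudson_fst(t.true_freqs[0], t.true_freqs[1]))
        # group means agree within Monte-Carlo error (3 x combined SEM)
        a, b = np.array(fsts[1.0]), np.array(fsts[20.0])
        sem = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3 * sem + 0.02

    def test_isolation_by_distance_direction(self):
        """m(d) decay makes the 1 km pair less diverged than the 20 km pair."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            near = g.simulate_landscape(
                _two_pop_config(1.0, m0=0.25, delta_km=2.0, cutoff_km=12.0,
                                n_generations=100, seed=seed)
            )
            far = g.simulate_landscape(
                _two_pop_config(20.0, m0=0.25, delta_km=2.0, cutoff_km=12.0,
                                n_generations=100, seed=1000 + seed)
            )
            wins += hudson_fst(near.true_freqs[0], near.true_freqs[1]) < hudson_fst(
                far.true_freqs[0], far.true_freqs[1]
            )
        assert wins >= int(0.95 * n_rep)

    def test_class_specific_divergence_structure(self):
        """Host loci diverge between hosts; adjacency loci mainly in contact."""
        cfg = g.default_landscape_config(n_loci=2000, seed=21)
        truth = g.simulate_landscape(cfg)
        cls, p = truth.locus_class, truth.true_freqs
        adj = set(cfg.adjacency_pairs)
        hosts = cfg.hosts

        def pair_means(mask):
            vals = {}
            for i in range(cfg.n_pops):
                for j in range(i + 1, cfg.n_pops):
                    vals[(i, j)] = np.nanmean(
                        hudson_fst_per_locus(p[i, mask], p[j, mask])
                    )
            return vals

        host_vals = pair_means(cls == "host_selected")
        diff_host = [v for (i, j), v in host_vals.items() if hosts[i] != hosts[j]]
        same_host = [v for (i, j), v in host_vals.items() if hosts[i] == hosts[j]]
        assert np.mean(diff_host) > 5 * np.mean(same_host)

        adj_vals = pair_means(cls == "adjacency_specific")
        adjacent = [v for k, v in adj_vals.items() if k in adj]
        separated = [v for k, v in adj_vals.items() if k not in adj]
        assert np.mean(adjacent) > np.mean(separated)
        neut_vals = pair_means(cls == "neutral")
        assert np.mean(adjacent) > 10 * np.mean(
            [v for k, v in neut_vals.items() if k in adj]
        )


class TestSimulateReads:
    def test_zero_coverage_gives_empty_matrices(self, small_truth):
        counts = g.simulate_reads(small_truth, mean_coverage=0.0, seed=1)
        assert not counts.n_reads.any()
        assert not counts.alt_reads.any()

    def test_zero_error_homozygous_reference_never_alt(self, small_truth):
        counts = g.simulate_reads(small_truth, mean_coverage=3.0, error_rate=0.0,
                                  seed=2)
        hom_ref = small_truth.genotypes == 0
        assert not counts.alt_reads[hom_ref].any()

    def test_poisson_coverage_moment(self, small_truth):
        counts = g.simulate_reads(small_truth, mean_coverage=5.0, seed=3)
        n = counts.n_reads
        assert n.size >= 10_000
        se = np.sqrt(5.0 / n.size)
        assert abs(n.mean() - 5.0) < 3 * se

    def test_read_model_calibration(self, small_truth):
        """Empirical P(alt read | genotype) matches e_g within binomial error."""
        err = 0.01
        counts = g.simulate_reads(small_truth, mean_coverage=4.0, error_rate=err,
                                  seed=4)
        for gval, e in ((0, err), (1, 0.5), (2, 1 - err)):
            mask = small_truth.genotypes == gval
            n_tot = counts.n_reads[mask].sum()
            if n_tot == 0:
                continue
            p_hat = counts.alt_reads[mask].sum() / n_tot
            assert abs(p_hat - e) < 3 * np.sqrt(e * (1 - e) / n_tot) + 1e-9

    def test_negative_coverage_rejected(self, small_truth):
        with pytest.raises(ValidationError):
            g.simulate_reads(small_truth, mean_coverage=-1.0)

    def test_vcf_of_simulated_reads_round_trips(self, small_truth, tmp_path):
        import genomosaic.io as gio

        counts = g.simulate_reads(small_truth, mean_coverage=1.0, seed=9)
        path = str(tmp_path / "sim.vcf")
        gio.write_vcf(counts, path)
        back = gio.read_variant_counts(path, populations=counts.populations)
        np.testing.assert_array_equal(back.n_reads, counts.n_reads)
        np.testing.assert_array_equal(back.alt_reads, counts.alt_reads)


class TestMatingTrials:
    def test_equal_probabilities_give_zero_isolation(self):
        from genomosaic.popstats import isolation_index_from_trials

        trials = g.simulate_mating_trials(0.5, 0.5, n_trials_per_cell=4000, seed=1)
        assert abs(isolation_index_from_trials(trials)) < 0.1

    def test_zero_between_mating_gives_full_isolation(self):
        from genomosaic.popstats import isolation_index_from_trials

        trials = g.simulate_mating_trials(0.6, 0.0, n_trials_per_cell=50, seed=2)
        assert isolation_index_from_trials(trials) == pytest.approx(1.0)

    def test_isolation_index_recovery(self):
        """p_within=0.6, p_between=0.276 targets an isolation index of 0.54."""
        from genomosaic.popstats import isolation_index_from_trials

        hits = 0
        for seed in range(50):
            trials = g.simulate_mating_trials(0.6, 0.276, n_trials_per_cell=500,
                                              seed=seed)
            hits += abs(isolation_index_from_trials(trials) - 0.54) < 0.1
        assert hits >= 45
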