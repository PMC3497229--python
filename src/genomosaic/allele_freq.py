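"""Bayesian allele-frequency estimation from low-coverage read counts.

Genotypic state and population allele frequency are treated jointly as
model parameters: for individual k with genotype g in {0, 1, 2} copies of
the non-reference allele, reads are Binomial(n_k, e_g) with
e_0 = error_rate, e_1 = 1/2, e_2 = 1 - error_rate; genotypes follow a
Hardy-Weinberg prior Binomial(g | 2, p) and the population frequency p a
flat Beta(1, 1) prior.  A Gibbs sampler alternates genotype draws from
their categorical full conditionals and conjugate Beta updates for p.
Zero-coverage individuals therefore contribute no data and their genotype
posterior collapses to the Hardy-Weinberg prior at the posterior allele
frequency, so missing data and low coverage are handled identically.

Populations and loci are conditionally independent and are processed as
vectorized blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .types import AlleleFreqPosterior, GenotypePosterior, ReadCountMatrix, ValidationError

DEFAULT_ERROR_RATE = 0.005


@dataclass
class MCMCConfig:
    """Chain length settings; defaults are 20,000 iterations thinned to every 4th."""

    iterations: int = 20_000
    burn_in: int = 2_000
    thinning: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValidationError("iterations must exceed burn_in")
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")
        if self.n_retained < 1:
            raise ValidationError("no retained samples after burn-in/thinning")

    @property
    def n_retained(self) -> int:
        # iterations burn_in, burn_in + thinning, ... below iterations
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


def genotype_likelihood(alt_reads, n_reads, error_rate: float = DEFAULT_ERROR_RATE):
    """Unnormalized likelihood of the read data under each genotype.

    Returns an array with a trailing axis of length 3 giving
    Binomial(alt_reads | n_reads, e_g) for g = 0, 1, 2.  With no reads all
    three entries are 1 (no information).
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValidationError("error_rate must be in [0, 0.5)")
    alt = np.asarray(alt_reads)
    n = np.asarray(n_reads)
    if (alt < 0).any() or (alt > n).any():
        raise ValidationError("need 0 <= alt_reads <= n_reads")
    e = np.array([error_rate, 0.5, 1.0 - error_rate])
    alt3 = alt[..., None]
    n3 = n[..., None]
    log_coef = gammaln(n3 + 1) - gammaln(alt3 + 1) - gammaln(n3 - alt3 + 1)
    # xlogy gives 0 * log(0) = 0, so the error_rate == 0 boundary yields an
    # exact zero likelihood for impossible read configurations
    log_p = xlogy(alt3, e) + xlogy(n3 - alt3, 1.0 - e)
    return np.exp(log_coef + log_p)


def _population_gibbs(
    lik: np.ndarray, mcmc: MCMCConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs sampler for one population block.

    lik: (n_ind, L, 3) per-genotype likelihoods.  Returns retained p draws
    (L, n_retained) and Rao-Blackwellized genotype posteriors (n_ind, L, 3).
    """
    n_ind, n_loci, _ = lik.shape
    p = np.full(n_loci, 0.5)
    p_draws = np.empty((n_loci, mcmc.n_retained))
    g_post = np.zeros((n_ind, n_loci, 3))
    kept = 0
    n_acc = 0
    for it in range(mcmc.iterations):
        hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)  # (L, 3)
        w = lik * hwe  # (n_ind, L, 3)
        tot = w.sum(axis=2, keepdims=True)
        # guard: fully impossible cells cannot occur (e=0 edge handled in lik)
        cond = w / tot
        u = rng.random((n_ind, n_loci))
        c0 = cond[:, :, 0]
        g = (u >= c0).astype(np.int64) + (u >= c0 + cond[:, :, 1])
        s = g.sum(axis=0)
        p = rng.beta(1.0 + s, 1.0 + 2 * n_ind - s)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            p_draws[:, kept] = p
            g_post += cond
            kept += 1
            n_acc += 1
    g_post /= max(n_acc, 1)
    return p_draws, g_post


def estimate_allele_frequencies(
    counts: ReadCountMatrix,
    error_rate: float = DEFAULT_ERROR_RATE,
    mcmc: MCMCConfig | None = None,
    ci_level: float = 0.9,
) -> tuple[AlleleFreqPosterior, GenotypePosterior]:
    """MCMC posterior of per-population allele frequencies and genotype states.

    Each (population, locus) block is sampled independently; genotype
    posteriors are Monte-Carlo averages of the full-conditional genotype
    probabilities over retained iterations (Rao-Blackwellized, which has
    strictly smaller Monte-Carlo error than averaging sampled indicators).
    """
    if mcmc is None:
        mcmc = MCMCConfig()
    if not counts.populations:
        raise ValidationError("counts must carry population assignments")
    rng = np.random.default_rng(mcmc.seed)
    pops = counts.population_labels
    n_loci = counts.n_loci

    samples = np.empty((len(pops), n_loci, mcmc.n_retained), dtype=np.float32)
    g_probs = np.empty((counts.n_individuals, n_loci, 3), dtype=np.float64)

    lik_all = genotype_likelihood(counts.alt_reads, counts.n_reads, error_rate)
    for k, pop in enumerate(pops):
        idx = counts.individual_indices(pop)
        p_draws, g_post = _population_gibbs(lik_all[idx], mcmc, rng)
        samples[k] = p_draws
        g_probs[idx] = g_post

    a = (1.0 - ci_level) / 2.0
    freq_post = AlleleFreqPosterior(
        populations=pops,
        loci=counts.loci,
        samples=samples,
        mean=samples.mean(axis=2).astype(float),
        median=np.median(samples, axis=2).astype(float),
        lower=np.quantile(samples, a, axis=2).astype(float),
        upper=np.quantile(samples, 1.0 - a, axis=2).astype(float),
        ci_level=ci_level,
        mcmc_meta={
            "iterations": mcmc.iterations,
            "burn_in": mcmc.burn_in,
            "thinning": mcmc.thinning,
            "seed": mcmc.seed,
            "error_rate": error_rate,
        },
    )
    geno_post = GenotypePosterior(
        individuals=counts.individuals, loci=counts.loci, probs=g_probs
    )
    return freq_post, geno_post
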