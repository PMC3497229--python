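"""Hierarchical Bayesian F-model for pairwise genomic differentiation.

Model
-----
For locus i with ancestral allele frequency pi_i and locus-specific
differentiation F_ST,i, the allele frequency p_ij in each member j of the
population pair is Beta distributed:

    p_ij ~ Beta(pi_i * (1 - F_i) / F_i,  (1 - pi_i) * (1 - F_i) / F_i)

so that Var(p_ij) = F_i * pi_i * (1 - pi_i), the defining moment of the
F-model.  The logit-transformed differentiation alpha_i = logit(F_ST,i)
follows a genome-wide normal hyperdistribution Normal(mu, 1/tau): mu is
the genome-level mean logit F_ST and tau the precision of locus-specific
logit F_ST across the genome.  Hyperpriors are diffuse: mu ~ Normal(0, 10)
(variance), tau ~ Gamma(0.01, 0.01), pi_i ~ Uniform(0, 1).

Observed allele counts x_ij out of n_ij sampled allele copies are
binomial given p_ij; p_ij is integrated out analytically, leaving a
beta-binomial likelihood, and the chain samples (alpha_i, pi_i) by
adaptive Metropolis steps with conjugate Gibbs updates for mu and tau.

Outlier calling
---------------
A locus is a statistical outlier when its alpha point estimate (posterior
median) falls outside the interval bounded by the q-th and (1-q)-th
quantiles of the genome-wide distribution of alpha, obtained by
integrating Normal(mu, 1/tau) over the joint posterior of (mu, tau).
Both tails are flagged, but the headline count ``n_outliers_high`` counts
the high tail only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .allele_freq import MCMCConfig
from .types import GenotypePosterior, ReadCountMatrix, ValidationError

ALPHA_CLIP = (-18.0, 12.0)
ZPI_CLIP = (-13.0, 13.0)
MU_PRIOR_VAR = 10.0
TAU_PRIOR_SHAPE = 0.01
TAU_PRIOR_RATE = 0.01


@dataclass
class PairAlleleCounts:
    """Population-level allele counts for one pair: alt / total allele copies."""

    pair: tuple[str, str]
    loci: list[str]
    alt: np.ndarray  # (2, n_loci)
    total: np.ndarray  # (2, n_loci)

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.alt.shape != (2, len(self.loci)) or self.total.shape != self.alt.shape:
            raise ValidationError("count arrays must have shape (2, n_loci)")
        if (self.alt < 0).any() or (self.alt > self.total).any():
            raise ValidationError("need 0 <= alt <= total")

    def usable_mask(self) -> np.ndarray:
        """Loci that carry any data for this pair (nonzero count total).

        Loci monomorphic within the pair stay in the model — the full SNP
        panel is represented in every pairwise comparison, and dropping
        sample-monomorphic loci is an unmodelled ascertainment that biases
        the genome-level mean of logit F_ST downward.  Their alpha is
        prior-dominated and they are never flagged.
        """
        return self.total.sum(axis=0) > 0

    def polymorphic_mask(self) -> np.ndarray:
        """Loci polymorphic within the pair (used for sanity checks/logging)."""
        has_data = (self.total > 0).all(axis=0)
        all_ref = (self.alt == 0).all(axis=0)
        all_alt = (self.alt == self.total).all(axis=0)
        return has_data & ~(all_ref | all_alt)


def counts_from_genotype_posterior(
    gpost: GenotypePosterior,
    populations: dict[str, str],
    pair: tuple[str, str],
) -> PairAlleleCounts:
    """Expected allele counts 2N * mean dosage / 2 from genotype posteriors.

    This is the default coupling between the allele-frequency model and the
    F-model: posterior-expected dosages are summed per population and
    rounded to integer allele counts out of 2N copies.
    """
    dose = gpost.expected_dosage()
    alt = np.zeros((2, len(gpost.loci)))
    total = np.zeros_like(alt)
    for j, pop in enumerate(pair):
        idx = [k for k, ind in enumerate(gpost.individuals) if populations.get(ind) == pop]
        if not idx:
            raise ValidationError(f"no individuals assigned to population {pop!r}")
        alt[j] = dose[idx].sum(axis=0)
        total[j] = 2 * len(idx)
    return PairAlleleCounts(tuple(pair), list(gpost.loci),
                            np.rint(alt).astype(np.int64), total.astype(np.int64))


def counts_from_reads(counts: ReadCountMatrix, pair: tuple[str, str]) -> PairAlleleCounts:
    """Pooled per-population read counts as allele counts (read-level mode).

    At sub-1x individual coverage nearly every read samples a distinct
    chromosome, so pooled reads approximate binomial draws of allele copies.
    """
    alt = np.zeros((2, counts.n_loci), dtype=np.int64)
    total = np.zeros_like(alt)
    for j, pop in enumerate(pair):
        idx = counts.individual_indices(pop)
        if idx.size == 0:
            raise ValidationError(f"no individuals assigned to population {pop!r}")
        alt[j] = counts.alt_reads[idx].sum(axis=0)
        total[j] = counts.n_reads[idx].sum(axis=0)
    return PairAlleleCounts(tuple(pair), list(counts.loci), alt, total)


@dataclass
class PairDivergence:
    """Posterior of the pairwise F-model plus derived outlier calls."""

    pair: tuple[str, str]
    loci: list[str]
    included: np.ndarray  # (L,) bool; excluded loci were monomorphic/no-data
    alpha_point: np.ndarray  # (L,) posterior point estimate of logit F_ST (NaN if excluded)
    fst_point: np.ndarray  # inverse-logit of alpha_point
    mu_samples: np.ndarray  # (n_ret,)
    tau_samples: np.ndarray  # (n_ret,)
    alpha_samples: np.ndarray | None = None  # (L, n_ret)
    pi_samples: np.ndarray | None = None  # (L, n_ret)
    predictive_q: tuple[float, float] | None = None
    outlier_flags: np.ndarray | None = None  # (L,) in {"none","high","low",""}
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_outliers_high(self) -> int:
        if self.outlier_flags is None:
            raise ValidationError("call_outliers has not been run")
        return int((self.outlier_flags == "high").sum())

    def to_locus_frame(self) -> pd.DataFrame:
        flags = (
            self.outlier_flags
            if self.outlier_flags is not None
            else np.full(len(self.loci), "", dtype=object)
        )
        return pd.DataFrame(
            {
                "pair": f"{self.pair[0]}x{self.pair[1]}",
                "locus": self.loci,
                "alpha_point": self.alpha_point,
                "fst_point": self.fst_point,
                "outlier_flag": flags,
            }
        )


def fmodel_beta_params(pi, fst):
    """Beta(a, b) shape parameters of daughter frequencies around pi.

    a = pi (1-F)/F, b = (1-pi)(1-F)/F, so Var(p) = F * pi * (1 - pi): the
    F-model's defining moment.
    """
    pi = np.asarray(pi, dtype=float)
    fst = np.asarray(fst, dtype=float)
    if ((fst <= 0) | (fst >= 1)).any():
        raise ValidationError("fst must lie strictly in (0, 1)")
    c = (1.0 - fst) / fst
    return pi * c, (1.0 - pi) * c


def sample_fmodel_counts(
    mu: float,
    tau: float,
    n_loci: int,
    n_chrom: int,
    rng: np.random.Generator,
    pair: tuple[str, str] = ("A", "B"),
) -> PairAlleleCounts:
    """Generate pair allele counts from the F-model's own generative process.

    alpha_i ~ Normal(mu, 1/tau), pi_i ~ Uniform(0, 1), daughter frequencies
    Beta as in :func:`fmodel_beta_params`, counts Binomial(n_chrom, p).
    Used for parameter-recovery and calibration checks.
    """
    alpha = rng.normal(mu, 1.0 / np.sqrt(tau), n_loci)
    pi = rng.uniform(0.0, 1.0, n_loci)
    a, b = fmodel_beta_params(pi, expit(alpha))
    p = rng.beta(np.repeat(a[None, :], 2, 0), np.repeat(b[None, :], 2, 0))
    x = rng.binomial(n_chrom, p)
    loci = [f"sim{i:05d}:1" for i in range(n_loci)]
    return PairAlleleCounts(pair, loci, x, np.full((2, n_loci), n_chrom))


def _betabinom_loglik(alt: np.ndarray, total: np.ndarray, a: np.ndarray,
                      b: np.ndarray) -> np.ndarray:
    """Beta-binomial log likelihood summed over the two pair members.

    alt, total: (..., 2, L); a, b: (..., L).  The binomial coefficient is
    dropped (constant in the parameters).
    """
    c = a + b
    ll = -2.0 * (gammaln(a) + gammaln(b) - gammaln(c))
    for j in (0, 1):
        x = alt[..., j, :]
        n = total[..., j, :]
        ll = ll + gammaln(a + x) + gammaln(b + n - x) - gammaln(c + n)
    return ll


def _default_mcmc(seed: int | None) -> MCMCConfig:
    return MCMCConfig(iterations=6000, burn_in=1000, thinning=5, seed=seed)


def fit_fmodel_pairs(
    counts: Sequence[PairAlleleCounts],
    mcmc: MCMCConfig | None = None,
    q: float = 0.95,
    point: str = "median",
    store_samples: bool = True,
) -> list[PairDivergence]:
    """Fit the F-model to several pairs in one vectorized chain.

    Pairs are statistically independent; batching them into arrays of shape
    (n_pairs, n_loci) just amortizes the per-iteration numpy overhead.  All
    pairs must share the same locus list length (they may differ in which
    loci are excluded).
    """
    if not counts:
        raise ValidationError("no pairs supplied")
    if mcmc is None:
        mcmc = _default_mcmc(None)
    if point not in ("median", "mean"):
        raise ValidationError("point must be 'median' or 'mean'")
    n_loci = len(counts[0].loci)
    if any(len(c.loci) != n_loci for c in counts):
        raise ValidationError("all pairs must share the same number of loci")
    P = len(counts)
    rng = np.random.default_rng(mcmc.seed)

    alt = np.stack([c.alt for c in counts])  # (P, 2, L)
    total = np.stack([c.total for c in counts])
    include = np.stack([c.usable_mask() for c in counts])  # (P, L)
    n_inc = include.sum(axis=1)
    n_poly = np.stack([c.polymorphic_mask() for c in counts]).sum(axis=1)
    if (n_poly < 2).any():
        bad = [counts[k].pair for k in np.nonzero(n_poly < 2)[0]]
        raise ValidationError(f"fewer than 2 polymorphic loci for pair(s) {bad}")
    # excluded loci: zero out the data so they contribute nothing
    alt = alt * include[:, None, :]
    total = total * include[:, None, :]

    # moment-based initialization
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = (alt + 0.5) / (total + 1.0)  # (P, 2, L)
        p1, p2 = p_hat[:, 0], p_hat[:, 1]
        denom = p1 * (1 - p2) + p2 * (1 - p1)
        fst0 = np.where(denom > 0, (p1 - p2) ** 2 / np.maximum(denom, 1e-12), 0.05)
    alpha = logit(np.clip(fst0, 0.005, 0.8))
    pi = np.clip((alt.sum(axis=1) + 0.5) / (total.sum(axis=1) + 1.0), 0.01, 0.99)
    z = logit(pi)
    mu = np.array([alpha[k, include[k]].mean() for k in range(P)])
    tau = np.array(
        [1.0 / max(alpha[k, include[k]].var(), 1e-2) for k in range(P)]
    )

    a = pi * np.exp(-alpha)
    b = (1.0 - pi) * np.exp(-alpha)
    ll = _betabinom_loglik(alt, total, a, b)

    s_alpha = np.full((P, 1), 1.0)
    s_z = np.full((P, 1), 1.0)
    acc_a = np.zeros(P)
    acc_z = np.zeros(P)
    window = 50

    n_ret = mcmc.n_retained
    alpha_draws = np.empty((P, n_loci, n_ret), dtype=np.float32)
    pi_draws = np.empty((P, n_loci, n_ret), dtype=np.float32) if store_samples else None
    mu_draws = np.empty((P, n_ret))
    tau_draws = np.empty((P, n_ret))
    kept = 0

    for it in range(mcmc.iterations):
        # --- alpha Metropolis step (vectorized per locus) -------------------
        alpha_prop = np.clip(alpha + s_alpha * rng.standard_normal((P, n_loci)),
                             *ALPHA_CLIP)
        expa = np.exp(-alpha_prop)
        ll_prop = _betabinom_loglik(alt, total, pi * expa, (1.0 - pi) * expa)
        d_prior = -0.5 * tau[:, None] * (
            (alpha_prop - mu[:, None]) ** 2 - (alpha - mu[:, None]) ** 2
        )
        accept = (np.log(rng.random((P, n_loci))) < ll_prop - ll + d_prior) & include
        alpha = np.where(accept, alpha_prop, alpha)
        ll = np.where(accept, ll_prop, ll)
        acc_a += accept.sum(axis=1) / np.maximum(n_inc, 1)

        # --- pi Metropolis step (logit scale, uniform prior on pi) ---------
        z_prop = np.clip(z + s_z * rng.standard_normal((P, n_loci)), *ZPI_CLIP)
        pi_prop = expit(z_prop)
        expa = np.exp(-alpha)
        ll_prop = _betabinom_loglik(alt, total, pi_prop * expa, (1.0 - pi_prop) * expa)
        # Jacobian of the logit transform (uniform prior on pi itself)
        d_jac = (np.log(pi_prop) + np.log1p(-pi_prop)) - (np.log(pi) + np.log1p(-pi))
        accept = (np.log(rng.random((P, n_loci))) < ll_prop - ll + d_jac) & include
        z = np.where(accept, z_prop, z)
        pi = np.where(accept, pi_prop, pi)
        ll = np.where(accept, ll_prop, ll)
        acc_z += accept.sum(axis=1) / np.maximum(n_inc, 1)

        # --- conjugate hyperparameter updates -------------------------------
        sum_alpha = (alpha * include).sum(axis=1)
        post_prec = 1.0 / MU_PRIOR_VAR + n_inc * tau
        mu = rng.normal(tau * sum_alpha / post_prec, np.sqrt(1.0 / post_prec))
        resid2 = (((alpha - mu[:, None]) ** 2) * include).sum(axis=1)
        tau = rng.gamma(TAU_PRIOR_SHAPE + 0.5 * n_inc,
                        1.0 / (TAU_PRIOR_RATE + 0.5 * resid2))

        # --- global block moves, alternating by sweep -----------------------
        # (a) (tau, alpha) rescaling: the hierarchy couples tau to the spread
        # of alpha (a "funnel"), so single-site updates mix tau slowly.
        # Propose tau' = tau * e^eps and rescale
        # alpha' = mu + (alpha - mu) / sqrt(e^eps): the normal prior ratio
        # cancels the Jacobian exactly, leaving the likelihood ratio and the
        # Gamma hyperprior measured in log tau.
        # (b) (mu, alpha) rigid translation: for pairs with little divergence
        # signal the likelihood is flat in alpha below a detectability floor
        # and mu's conjugate update exerts a vanishing pull once tau is
        # large, so the block can random-walk down the flat ridge and freeze.
        # The translation leaves the hierarchy invariant and is accepted on
        # the likelihood ratio times the mu prior, restoring mixing there.
        if it % 2 == 0:
            eps = 0.5 * rng.standard_normal(P)
            scale_f = np.exp(-0.5 * eps)[:, None]
            alpha_prop = np.clip(mu[:, None] + (alpha - mu[:, None]) * scale_f,
                                 *ALPHA_CLIP)
            expa = np.exp(-alpha_prop)
            ll_prop = _betabinom_loglik(alt, total, pi * expa, (1.0 - pi) * expa)
            d_ll = ((ll_prop - ll) * include).sum(axis=1)
            tau_prop = tau * np.exp(eps)
            d_hyper = TAU_PRIOR_SHAPE * eps - TAU_PRIOR_RATE * (tau_prop - tau)
            acc_block = np.log(rng.random(P)) < d_ll + d_hyper
            if acc_block.any():
                alpha = np.where(acc_block[:, None], alpha_prop, alpha)
                ll = np.where(acc_block[:, None], ll_prop, ll)
                tau = np.where(acc_block, tau_prop, tau)
        else:
            shift = 0.4 * rng.standard_normal(P)
            alpha_prop = np.clip(alpha + shift[:, None], *ALPHA_CLIP)
            expa = np.exp(-alpha_prop)
            ll_prop = _betabinom_loglik(alt, total, pi * expa, (1.0 - pi) * expa)
            d_ll = ((ll_prop - ll) * include).sum(axis=1)
            mu_prop = mu + shift
            d_prior_mu = (mu ** 2 - mu_prop ** 2) / (2.0 * MU_PRIOR_VAR)
            acc_block = np.log(rng.random(P)) < d_ll + d_prior_mu
            if acc_block.any():
                alpha = np.where(acc_block[:, None], alpha_prop, alpha)
                ll = np.where(acc_block[:, None], ll_prop, ll)
                mu = np.where(acc_block, mu_prop, mu)

        # --- proposal adaptation, frozen after burn-in ----------------------
        if it < mcmc.burn_in and (it + 1) % window == 0:
            s_alpha[:, 0] *= np.exp(0.6 * (acc_a / window - 0.3))
            s_z[:, 0] *= np.exp(0.6 * (acc_z / window - 0.3))
            np.clip(s_alpha, 0.02, 10.0, out=s_alpha)
            np.clip(s_z, 0.02, 10.0, out=s_z)
            acc_a[:] = 0.0
            acc_z[:] = 0.0
        elif it >= mcmc.burn_in:
            if (it - mcmc.burn_in) % mcmc.thinning == 0:
                alpha_draws[:, :, kept] = alpha
                if pi_draws is not None:
                    pi_draws[:, :, kept] = pi
                mu_draws[:, kept] = mu
                tau_draws[:, kept] = tau
                kept += 1

    results = []
    for k, c in enumerate(counts):
        inc = include[k]
        ad = alpha_draws[k].astype(float)
        if point == "median":
            apt = np.median(ad, axis=1)
        else:
            apt = ad.mean(axis=1)
        apt[~inc] = np.nan
        res = PairDivergence(
            pair=c.pair,
            loci=list(c.loci),
            included=inc,
            alpha_point=apt,
            fst_point=expit(apt),
            mu_samples=mu_draws[k].copy(),
            tau_samples=tau_draws[k].copy(),
            alpha_samples=ad if store_samples else None,
            pi_samples=pi_draws[k].astype(float) if pi_draws is not None else None,
            n_excluded=int((~inc).sum()),
            meta={
                "n_monomorphic": int(n_inc[k] - n_poly[k]),
                "iterations": mcmc.iterations,
                "burn_in": mcmc.burn_in,
                "thinning": mcmc.thinning,
                "seed": mcmc.seed,
                "point": point,
            },
        )
        call_outliers(res, q=q, seed=_derive_seed(mcmc.seed, k))
        results.append(res)
    return results


def _derive_seed(seed: int | None, k: int) -> int | None:
    if seed is None:
        return None
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


def fit_fmodel(
    counts: PairAlleleCounts,
    mcmc: MCMCConfig | None = None,
    q: float = 0.95,
    point: str = "median",
    store_samples: bool = True,
) -> PairDivergence:
    """Fit the hierarchical F-model to one population pair (see module docs)."""
    return fit_fmodel_pairs([counts], mcmc=mcmc, q=q, point=point,
                            store_samples=store_samples)[0]


def genomewide_alpha_quantiles(
    mu_samples: np.ndarray,
    tau_samples: np.ndarray,
    q: float = 0.95,
    k_per_draw: int = 10,
    seed: int | None = None,
) -> tuple[float, float]:
    """Quantiles of the posterior-predictive genome-wide alpha distribution.

    For each retained hyperparameter draw (mu_t, tau_t), ``k_per_draw``
    values alpha* ~ Normal(mu_t, 1/tau_t) are sampled; the pooled sample's
    empirical (1-q) and q quantiles delimit the non-outlier interval.
    Integrating over the hyperparameter posterior rather than plugging in
    point estimates widens the interval by the hyperparameter uncertainty.
    """
    mu_samples = np.asarray(mu_samples, dtype=float)
    tau_samples = np.asarray(tau_samples, dtype=float)
    if mu_samples.shape != tau_samples.shape or mu_samples.ndim != 1:
        raise ValidationError("mu and tau draws must be matching 1-D arrays")
    if mu_samples.size < 100:
        raise ValidationError("need at least 100 retained hyperparameter draws")
    if not 0.5 < q < 1.0:
        raise ValidationError("q must lie in (0.5, 1)")
    rng = np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(tau_samples)
    draws = rng.normal(
        np.repeat(mu_samples, k_per_draw), np.repeat(sd, k_per_draw)
    )
    lo, hi = np.quantile(draws, [1.0 - q, q])
    return float(lo), float(hi)


def call_outliers(
    pair: PairDivergence,
    q: float = 0.95,
    k_per_draw: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Flag loci whose alpha point estimate leaves the genome-wide interval.

    Sets ``pair.predictive_q`` and ``pair.outlier_flags`` in place and
    returns the flags ('high', 'low' or 'none'; excluded loci get '').
    """
    lo, hi = genomewide_alpha_quantiles(
        pair.mu_samples, pair.tau_samples, q=q, k_per_draw=k_per_draw, seed=seed
    )
    flags = np.full(len(pair.loci), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        flags[np.asarray(pair.alpha_point > hi, dtype=bool)] = "high"
        flags[np.asarray(pair.alpha_point < lo, dtype=bool)] = "low"
    flags[~pair.included] = ""
    pair.predictive_q = (lo, hi)
    pair.outlier_flags = flags
    return flags


@dataclass
class FstDistributionSummary:
    """Shape of the per-locus F_ST distribution for one pair.

    ``kurtosis_raw`` is m4/m2**2 and ``kurtosis_excess`` subtracts 3; both
    conventions are emitted because reported kurtosis values in the
    literature rarely state which is used.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis_raw: float
    kurtosis_excess: float
    n_loci: int
    n_outliers_high: int | None = None


def fst_distribution_summary(pair: PairDivergence) -> FstDistributionSummary:
    """Moment summary (denominator n) of fst_point over included loci."""
    values = pair.fst_point[pair.included]
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValidationError("need at least 3 polymorphic loci")
    if np.allclose(values, values[0]):
        raise ValidationError("constant F_ST vector: shape summaries undefined")
    return FstDistributionSummary(
        mean=float(values.mean()),
        variance=float(values.var()),
        skewness=float(_skew(values, bias=True)),
        kurtosis_raw=float(_kurtosis(values, fisher=False, bias=True)),
        kurtosis_excess=float(_kurtosis(values, fisher=True, bias=True)),
        n_loci=int(values.size),
        n_outliers_high=pair.n_outliers_high if pair.outlier_flags is not None else None,
    )
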