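# Methods

This note documents the models, algorithms, numerical conventions and
design choices in `genomosaic`, and what the synthetic-data generator does
and does not emulate.

## The scientific setting

The package analyses population-genomic divergence across a *geographic
mosaic*: a set of demes occupying two host-plant classes (Adenostoma vs
Ceanothus ecotypes), some pairs in direct contact ("adjacent"), others
separated by habitat gaps, with gene flow that decays with distance and
vanishes beyond a cutoff of roughly 10–15 km. Sequencing is shallow
(~0.77× per individual) but many individuals are pooled per deme, so
population-level quantities are well determined while individual genotypes
are uncertain. Every inference component is built to respect that
asymmetry.

## Bayesian allele frequencies from read counts (`allele_freq`)

For individual *k* at a biallelic SNP, with genotype *g* ∈ {0,1,2} copies
of the non-reference allele, reads are modelled as
`alt_k ~ Binomial(n_k, e_g)` with `e_0 = ε`, `e_1 = 1/2`, `e_2 = 1 − ε`,
where ε is a fixed per-read error rate (default 0.005, configurable, not
estimated). Genotypes have a Hardy–Weinberg prior `Binomial(2, p)` and the
population frequency *p* a flat Beta(1,1) prior. A Gibbs sampler
alternates categorical genotype draws with conjugate Beta updates of *p*;
populations and loci are conditionally independent and vectorized.
Defaults: 20,000 iterations thinned to every 4th; burn-in 2,000
(configurable — the burn-in length is a convention of this package).
Genotype posteriors are Rao-Blackwellized (averages of full-conditional
probabilities over retained sweeps), which has strictly smaller Monte
Carlo error than averaging sampled indicators. A zero-coverage individual
contributes no likelihood, so its genotype posterior is the HWE prior
evaluated under the posterior of *p* — missing data and low coverage are
the same thing here.

Sampling noise bound: with N diploids the sample frequency carries
information from only 2N chromosomes. At p = 0.3 and N = 20 the
probability that even a perfect estimator lands within 0.1 of the true
frequency is ≈ 0.83 (exact binomial); recovery rates quoted for such
cohorts should be read against that ceiling. Credible-interval coverage is
the calibration-relevant quantity and is close to nominal.

## Hierarchical F-model and outlier calling (`fmodel`)

For a population pair, locus *i* has ancestral frequency π_i and
locus-specific differentiation F_i; daughter frequencies are
`p_ij ~ Beta(π_i (1−F_i)/F_i, (1−π_i)(1−F_i)/F_i)`, so
`Var(p_ij) = F_i π_i (1−π_i)` — the F-model's defining moment.
`α_i = logit F_i` follows the genome-wide hyperdistribution
`Normal(μ, 1/τ)`; hyperpriors are `μ ~ N(0, 10)`, `τ ~ Gamma(0.01, 0.01)`,
`π_i ~ U(0,1)`.

Data enter as population-level allele counts. Two modes:

* **genotype-posterior mode (default):** expected allele counts
  `round(Σ_k E[g_k])` out of 2N copies, from the allele-frequency stage.
  This two-stage coupling is a plug-in approximation to a joint chain; it
  understates genotype uncertainty slightly and is the documented default.
* **read-count mode:** pooled per-population alt/total read counts used
  directly as binomial draws of allele copies. At ≪1× individual coverage
  nearly every read samples a distinct chromosome, so this is accurate and
  skips the allele-frequency MCMC.

The binomial count likelihood is integrated against the Beta analytically,
giving a beta-binomial marginal — an exact marginalization, not a model
change. The sampler is Metropolis-within-Gibbs: vectorized per-locus
random-walk updates of α and logit(π) (adaptive proposal scales targeting
~30% acceptance, frozen after burn-in), conjugate Gibbs updates of μ
(normal) and τ (gamma), plus a joint (τ, α) rescaling move
(`τ' = τ e^ε`, `α' = μ + (α−μ) e^{−ε/2}`) whose normal-prior ratio cancels
its Jacobian exactly, leaving the likelihood ratio times the Gamma prior in
the log-τ measure. The rescaling move is essential: the hierarchy couples
τ to the spread of α (a funnel), and single-site updates alone mix τ very
slowly. The translation move matters for pairs with little real
divergence: there the likelihood is flat in α below a detectability
floor, the conjugate μ update's restoring pull vanishes once τ is large,
and without a rigid block move the chain can drift down the flat ridge
and freeze; with it, μ for such pairs correctly equilibrates to a diffuse
"below detection" posterior bounded by its prior.

The full SNP panel enters every pairwise comparison: loci monomorphic
within a pair are *kept* in the fit (their α is prior-dominated and they
are never flagged). Dropping sample-monomorphic loci may look natural but
is an unmodelled ascertainment — we verified with a deterministic
quadrature oracle that it biases μ downward by roughly 0.1 logits at 500
loci × 40 chromosomes and destroys the frequentist coverage of μ's
credible interval. Only loci with no data at all for the pair are
excluded, with a logged count; a pair with fewer than two polymorphic
loci is an error.

α is clipped to [−18, 12] and logit π to [−13, 13] for numerical safety;
these bounds correspond to F_ST between ~1.5e−8 and ~0.99999 and are never
approached by real posteriors.

**Outliers.** The genome-wide distribution of α is the posterior
predictive `∫∫ N(μ, 1/τ) dP(μ, τ)`, approximated by sampling K = 10 normal
draws per retained hyperparameter draw. A locus is flagged when its α
point estimate (posterior median; mean available) falls outside the
(1−q, q) quantiles of that pooled sample (default q = 0.95). Both tails
are flagged; the headline count `n_outliers_high` counts the high tail.
Because point estimates are shrunken while the predictive interval carries
hyperparameter uncertainty, the realized two-tail false-positive rate on
null data is well below the nominal 10% — the procedure is conservative by
construction.

Distribution-shape summaries use population moments (denominator n):
skewness g1 = m3/m2^1.5, and kurtosis in both raw (m4/m2²) and excess
(−3) conventions, labelled, because published kurtosis values rarely say
which is meant.

## Burrows' composite disequilibrium (`ld_composite`)

`Δ̂ = (1/2n) Σ_k g_Ak g_Bk − 2 p̂_A p̂_B` from unphased dosages, with
`p̂ = Σg/2n`; the plain moment estimator, no small-sample factor.
Genotype input is the posterior-modal dosage (ties broken toward the
heterozygote). Missing dosages are dropped pairwise and n reported. The
survey subsamples locus pairs uniformly without replacement
(seed-deterministic; default 1e5 pairs in place of an exhaustive scan) and
stratifies by shared contig parsed from `contig:pos` IDs. |Δ̂| is bounded
by the rarer allele's frequency, so low-MAF pairs cannot show large values
even under complete association.

## ABC model choice for gene flow (`abc_gene_flow`)

Two isolation-with-migration scenarios per pair: (i) divergence without
gene flow and (ii) divergence with gene flow, compared by rejection ABC
with equal model priors. Per locus, an ancestral frequency
`~ Beta(θ, θ)` truncated to polymorphic diverges into two daughters by
drift for `t_div` units of 2N generations on a grid with N = 500, with
symmetric per-generation migration `mig/(4N)` under model (ii); loci are
free-recombining. Drift is integrated in chunks of 20 generations, each
chunk one binomial resampling with effective size 2N/dt — this matches the
accumulated drift variance of dt single-generation steps to O((dt/2N)²),
keeps frequencies in [0,1] and preserves absorption; it is what makes ~1e4
prior-predictive simulations feasible on one CPU.

Summary statistics: mean and SD of per-locus Hudson F_ST, expected
heterozygosity per deme, the fraction of fixed differences and the
fraction of private polymorphisms. Distances are Euclidean after
standardizing each statistic by the simulated pool's median absolute
deviation; zero-spread statistics are dropped with a warning; acceptance
is the nearest `tolerance_fraction` of simulations, so the accepted set is
never empty and `tolerance_fraction = 1` provably returns the model prior.

Priors: `t_div ~ U(0.05, 4)`, `θ ~ U(0.2, 2)`, and
`log10(4Ne·m) ~ U(−0.5, 2)` under model (ii). The migration lower bound is
a deliberate identifiability choice: over the divergence times considered,
4Ne·m below ≈ 0.3 exchanges so little that models (i) and (ii) are
observationally identical, and prior mass placed there caps the attainable
posterior probability of zero gene flow no matter how clear the data are
(we measured the cap at ≈ 0.75 with a lower bound of 0.01). Bounding the
with-flow model at a meaningfully nonzero rate — still well below the
classic one-migrant-per-generation threshold 4Ne·m = 1 — keeps the model
comparison well-posed and yields decisive near-0/1 posterior probabilities
for clearly-isolated and clearly-connected pairs. The reference table
depends only on priors and sampling configuration, so one table can score
any number of observed pairs (`build_reference_table`).

## Matrix statistics, ordination, clines (`popstats`)

* **Mantel:** Pearson correlation of strict upper triangles; null by
  simultaneous row/column permutation of Y; `p = (1 + #extreme)/(1 + n_perm)`
  with the discrete floor `1/(n_perm+1)`; two-sided by default, one-sided
  available for signed predictions; `exact=True` enumerates all n!
  permutations (used at small n). Partial Mantel residualizes X and Y on Z
  (triangle OLS) and permutes Y before re-residualizing; the literature has
  competing permutation schemes and this one is stated, not assumed. If Z
  explains Y exactly the partial r is 0 by definition.
* **PCA:** column-centred SVD of the individuals × (loci × states)
  genotype-posterior matrix, no scaling (probabilities share a scale);
  two-state (hom-ref, het) and three-state variants; component signs fixed
  by making each component's largest-magnitude loading positive.
* **Clines:** OLS of per-population frequency on z-scored covariates
  (climate PC1, climate PC2, longitude); per-coefficient two-sided t
  p-values; partial residuals (residual + own component) for partial
  plots; rank-deficient designs are rejected naming the collinear columns;
  a zero-variance response returns zero slopes with p = 1.
* **Indices:** isolation index `1 − %between/%within` (undefined at
  %within = 0; negative values not clamped), morph divergence in
  percentage points, and a two-sample t-test (pooled-variance Student by
  default, df = n1+n2−2, matching the reporting convention of the field;
  Welch available).

## The landscape generator (`synthetic_data`)

Forward Wright–Fisher per locus (free recombination), chosen over a
coalescent because selection classes and arbitrary migration matrices are
simplest forward in time. Each generation: migration
`m(d) = m0 e^{−d/δ}` for d ≤ cutoff, exactly 0 beyond (rows rescaled if
off-diagonal mass would exceed 0.5); a class-specific selection push
`s·p(1−p)` clamped to [0,1]; binomial drift with 2N draws. Genotypes are
`Binomial(2, p)` per sampled individual; reads are Poisson coverage with
the same error model the estimator assumes.

Default conditions emulate the study design: 8 demes at 4 sites (each an
adjacent different-host pair), extent ~23 km, δ = 2.5 km, m0 = 0.1,
cutoff 12 km, N = 500, 100 generations of divergence (≈ 0.1 in units of
2N, putting far-pair background F_ST near 0.1), 20 diploids sampled per
deme, 2,000 loci (scaled down from tens of thousands), 0.77× coverage.
Locus classes: 95% neutral, 1% host-selected (s = 0.15, opposite sign on
the two hosts), 2% adjacency-specific (s = 0.4), 2% climate-clinal
(slope 0.025 per unit of a standardized climatic score; the default score
tracks the west–east extent loosely without being a linear function of
longitude, so climate and space stay separable in regressions). Effect
sizes are deliberately well above drift noise so class structure is
detectable at desk scale.

Adjacency-specific loci get an independent random ± orientation per
contact pair, opposite for the two members. A note on what is achievable:
divergence "only between adjacent pairs" cannot hold exactly for any
global assignment of allele frequencies — demanding opposite states within
every contact pair and equal states across every separated pair is an
inconsistent constraint graph — so contact-zone loci unavoidably show
intermediate divergence in about half the separated comparisons. The
generator therefore delivers (and the tests assert) the pattern as a
contrast: adjacency-class F_ST is about twice as high within contact pairs
as across separated pairs, and markedly above the neutral background.

What the generator does **not** emulate: sequence-level reads (no FASTQ,
no restriction-site structure), linkage and recombination maps (so LD is
near zero by construction except where tests plant it), temporal
fluctuation, and any mechanistic model of mate choice (the
adjacency-specific class is a phenomenological stand-in for
reinforcement's genomic footprint). Passing end-to-end tests therefore
demonstrates that the inference stack recovers the statistical structure
it assumes, not that real data meet those assumptions.

## Pipeline and determinism

Per-stage seeds are derived as `sha256(global_seed:stage) mod 2^31−1`, so
toggling one stage never perturbs another's randomness; reruns with the
same configuration are bit-identical. Every output table embeds a 12-hex
configuration hash; the report stage refuses to combine tables whose
hashes disagree. The pipeline defaults are scaled for a desk machine
(2,000 loci, shortened chains for the freqs/divergence stages); chain
lengths for publication-grade runs are a config edit.

Problem sizes used by the test suite and `scripts/acceptance.py` (e.g.
1,200 loci, 14 of the 28 pairs for the F-model ladder, 5,000–10,000 ABC
simulations, shared ABC reference tables across replicate observations)
are the package's own scaled-down choices for desk-scale verification;
the statistical assertions are sized to be meaningful at those scales.

## Known limitations

* The two-stage freqs → F-model coupling is a plug-in approximation;
  rounded expected counts mildly overstate certainty at very low coverage.
* τ (the precision of locus effects) mixes slowly despite the rescaling
  move and its posterior is heavy-tailed at these locus counts; μ-centred
  quantities are robust, but τ point estimates should be read with care.
* Rejection ABC with six summary statistics cannot separate 4Ne·m below
  ~0.3 from zero at these divergence times; the migration prior encodes
  that explicitly rather than hiding it.
* The outlier procedure is conservative on null data (shrinkage plus
  predictive-interval width), which is the safe direction for a scan.
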