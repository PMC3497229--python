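# genomosaic

Population-genomic divergence analysis across a geographic mosaic of
host-plant ecotypes, built for low-coverage sequencing designs where
individual genotypes are uncertain but population-level signal is strong.

The package is aimed at speciation-genomics practitioners who want to ask,
for a replicated set of population pairs: how differentiated is the
genome, which loci are exceptional, how much gene flow connects the
pairs, and how do those quantities track geography, host use and climate?
It ships with a forward Wright–Fisher landscape simulator that generates
data with the same structure (adjacent vs separated demes on two hosts,
distance-decaying migration with a hard cutoff, selected locus classes),
so every inference component can be validated against known truth.

## What's inside

* **Bayesian allele frequencies from read counts** — genotypes
  g ∈ {0,1,2} and population frequencies p are joint parameters; reads
  are Binomial(n, e_g) with e = (ε, ½, 1−ε); Gibbs sampling under a
  Hardy–Weinberg prior and Beta(1,1) frequency prior. Zero coverage and
  missing data are the same thing.
* **Hierarchical F-model for pairwise divergence** — per-locus
  α_i = logit F_ST,i with genome-wide α_i ~ N(μ, 1/τ); daughter
  frequencies Beta-distributed around an ancestral π_i with
  Var = F·π(1−π); beta-binomial marginal likelihood, adaptive
  Metropolis-within-Gibbs with global funnel/ridge block moves. Outliers
  are loci whose α point estimate leaves the (1−q, q) quantiles of the
  posterior-predictive genome-wide α distribution.
* **Burrows' composite disequilibrium Δ** for unphased genotype dosages,
  with contig-stratified pair surveys.
* **Rejection-ABC model choice** between divergence-without-gene-flow and
  divergence-with-gene-flow (isolation-with-migration, 4Ne·m), with MAD-
  standardized summary statistics and a reusable prior-predictive
  reference table.
* **Mantel / partial Mantel tests, genotype-posterior PCA,
  allele-frequency cline regressions, sexual-isolation and morph
  indices** — the statistics that relate genomic divergence to
  geography, host use and climate.
* **A seed-deterministic pipeline + CLI** (`genomosaic run`, `simulate`,
  `freqs`, `divergence`, `ld`, `abc`, `mantel`, `clines`, `report`)
  producing per-locus and per-pair master tables and figures.

See `docs/methods.md` for model details, numerical conventions, and what
the simulator does and does not emulate.

## Worked example

Simulate the default mosaic (8 demes, 4 adjacent host-ecotype pairs over
~23 km, 0.77× coverage), then compare an adjacent pair against the most
distant separated pair with the F-model in read-count mode:

```python
import genomosaic as g
from genomosaic.allele_freq import MCMCConfig

cfg = g.default_landscape_config(n_loci=600, seed=42)
truth = g.simulate_landscape(cfg)
reads = g.simulate_reads(truth, mean_coverage=0.77, error_rate=0.005, seed=43)

pairs = [("P1A", "P2C"),   # adjacent host-ecotype pair, ~0.3 km apart
         ("P1A", "P8C")]   # separated pair, ~23 km apart
fits = g.fit_fmodel_pairs(
    [g.counts_from_reads(reads, p) for p in pairs],
    mcmc=MCMCConfig(iterations=6000, burn_in=1500, thinning=3, seed=44),
)
for fit in fits:
    s = g.fst_distribution_summary(fit)
    print(f"{fit.pair[0]}x{fit.pair[1]}: mean FST = {s.mean:.3f}, "
          f"skewness = {s.skewness:.2f}, high outliers = {fit.n_outliers_high}")
```

Output:

```
P1AxP2C: mean FST = 0.005, skewness = 11.22, high outliers = 7
P1AxP8C: mean FST = 0.037, skewness = 6.56, high outliers = 10
```

Read: the adjacent pair is nearly undifferentiated genome-wide
(F_ST ≈ 0.005 — homogenized by gene flow) but its F_ST distribution is
strongly L-shaped (skewness 11): a handful of loci, dominated by the
simulator's contact-zone (reinforcement-like) class, stand far out of the
background and are flagged high. The distant pair is an order of
magnitude more differentiated genome-wide, with a flatter distribution
and outliers dominated by climate-clinal loci. These are the two
signatures the pipeline is designed to separate.

The same analysis end to end, with figures:

```bash
genomosaic run --seed 1 --out run/
genomosaic report --out run/
```

which writes `per_pair.tsv` (one row per population pair: distance,
adjacency, host contrast, mean/min/max F_ST, outlier count, shape
summaries, ABC posterior probability of zero gene flow, 4Ne·m estimate),
`per_locus.tsv`, and the outliers-vs-distance, F_ST-distribution and
gene-flow-vs-distance figures.

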