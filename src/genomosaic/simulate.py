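"""Forward Wright-Fisher simulator for a geographic mosaic of host ecotypes.

The generator produces the data structures the inference stack consumes:
per-deme allele-frequency trajectories under distance-decaying migration
(with a hard cutoff), drift and class-specific selection; sampled diploid
genotypes; low-coverage read counts; and mating-trial / morph-count tables.
Loci evolve independently (free recombination), which matches the very low
inter-locus disequilibrium the analysis assumes.

Locus classes
-------------
``neutral``             drift + migration only.
``host_selected``       directional selection of opposite sign on the two
                        host plants (Adenostoma pushes the alternate allele
                        up, Ceanothus down).
``adjacency_specific``  a phenomenological divergence push of magnitude
                        ``s_adj``, applied in opposite directions to the two
                        members of each geographically adjacent pair: the
                        pattern reinforcement is expected to leave, without
                        modelling the mating mechanics.
``climate_clinal``      deterministic per-generation push proportional to
                        ``cline_slope`` times a standardized per-population
                        climatic covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    PairTable,
    PopulationTable,
    ReadCountMatrix,
    ValidationError,
    build_pair_table,
)

LOCUS_CLASSES = ("neutral", "host_selected", "adjacency_specific", "climate_clinal")


@dataclass
class LandscapeConfig:
    """Study-design parameters of the geographic mosaic.

    Defaults emulate the sampled system: 8 populations (4 sites, each an
    adjacent Adenostoma/Ceanothus pair) spread over ~23 km, migration
    decaying exponentially with distance and exactly zero beyond
    ``cutoff_km`` (the spatial scale at which gene flow vanishes, 10-15 km),
    ~20 sampled individuals per deme and a scaled-down set of 2,000 loci.
    """

    n_pops: int
    coords: np.ndarray  # (n_pops, 2) km
    hosts: list[str]
    adjacency_pairs: list[tuple[int, int]]  # population indices
    n_loci: int = 2000
    # selected classes are each a small percent of loci: genome scans assume
    # exceptional divergence is rare, and the class-specific outlier sets the
    # design emulates were below 1% of all SNPs
    locus_class_fractions: dict = field(
        default_factory=lambda: {
            "neutral": 0.95,
            "host_selected": 0.01,
            "adjacency_specific": 0.02,
            "climate_clinal": 0.02,
        }
    )
    n_generations: int = 100
    pop_size: int = 500  # diploid N per deme
    m0: float = 0.1  # migration proportion at distance 0
    delta_km: float = 2.5  # migration decay scale
    cutoff_km: float = 12.0  # hard zero beyond this distance
    s_host: float = 0.15
    s_adj: float = 0.4
    cline_slope: float = 0.025
    n_sampled: int = 20  # diploid individuals sampled per deme
    covariate: np.ndarray | None = None  # per-pop climate covariate; default: x_km
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.n_pops, 2):
            raise ValidationError("coords must be (n_pops, 2)")
        if len(self.hosts) != self.n_pops:
            raise ValidationError("hosts must have one entry per population")
        frac = sum(self.locus_class_fractions.get(c, 0.0) for c in LOCUS_CLASSES)
        if abs(frac - 1.0) > 1e-9:
            raise ValidationError("locus_class_fractions must sum to 1")
        if not 0.0 <= self.m0 <= 0.5:
            raise ValidationError("m0 must be in [0, 0.5]")
        if self.cutoff_km <= 0:
            raise ValidationError("cutoff_km must be positive")
        if self.pop_size < 2:
            raise ValidationError("pop_size must be at least 2")
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if not np.isfinite(self.covariate).all():
                raise ValidationError("covariate values must be finite")

    @property
    def pop_labels(self) -> list[str]:
        return [f"P{i + 1}{'A' if h == 'Adenostoma' else 'C'}"
                for i, h in enumerate(self.hosts)]

    def standardized_covariate(self) -> np.ndarray:
        cov = self.covariate if self.covariate is not None else self.coords[:, 0]
        cov = np.asarray(cov, dtype=float)
        sd = cov.std()
        return (cov - cov.mean()) / sd if sd > 0 else np.zeros_like(cov)


def default_landscape_config(**overrides) -> LandscapeConfig:
    """The default mosaic: 4 sites of adjacent host-ecotype pairs, ~23 km extent."""
    sites = np.array([[0.0, 0.0], [4.0, 0.0], [10.0, 3.0], [22.0, 6.0]])
    coords = []
    hosts = []
    adjacency = []
    for k, (sx, sy) in enumerate(sites):
        coords.append([sx, sy])
        coords.append([sx + 0.2, sy + 0.2])
        hosts.extend(["Adenostoma", "Ceanothus"])
        adjacency.append((2 * k, 2 * k + 1))
    # a temperature/precipitation-like score per deme: tracks the west-east
    # extent loosely but is not a linear function of longitude, so climate
    # and space remain separable covariates in cline regressions
    climate = np.array([0.1, 0.0, 0.9, 1.0, 0.7, 0.8, 1.9, 2.1])
    cfg = dict(
        n_pops=8,
        coords=np.array(coords),
        hosts=hosts,
        adjacency_pairs=adjacency,
        covariate=climate,
    )
    cfg.update(overrides)
    return LandscapeConfig(**cfg)


@dataclass
class LandscapeTruth:
    """Simulator ground truth used for parameter-recovery tests."""

    config: LandscapeConfig
    pop_labels: list[str]
    true_freqs: np.ndarray  # (n_pops, n_loci)
    locus_class: np.ndarray  # (n_loci,) str
    migration_matrix: np.ndarray  # (n_pops, n_pops) per-generation proportions
    genotypes: np.ndarray  # (n_individuals, n_loci) dosages in {0,1,2}
    individuals: list[str]
    populations: dict[str, str]
    loci: list[str]

    def population_table(self) -> PopulationTable:
        frame = pd.DataFrame(
            {
                "population": self.pop_labels,
                "host": self.config.hosts,
                "x_km": self.config.coords[:, 0],
                "y_km": self.config.coords[:, 1],
                "n_sampled": self.config.n_sampled,
            }
        )
        return PopulationTable(frame)

    def pair_table(self) -> PairTable:
        adj = [
            (self.pop_labels[i], self.pop_labels[j])
            for i, j in self.config.adjacency_pairs
        ]
        return build_pair_table(self.population_table(), adj)

    def sample_freqs(self) -> np.ndarray:
        """Per-population sample allele frequencies from the drawn genotypes."""
        out = np.empty_like(self.true_freqs)
        gen = np.asarray(self.genotypes)
        pops = np.asarray([self.populations[i] for i in self.individuals])
        for k, lab in enumerate(self.pop_labels):
            sel = gen[pops == lab]
            out[k] = sel.sum(axis=0) / (2.0 * len(sel))
        return out


def migration_kernel(d_km: np.ndarray, m0: float, delta_km: float,
                     cutoff_km: float) -> np.ndarray:
    """m(d) = m0 * exp(-d / delta); exactly zero beyond the cutoff."""
    d = np.asarray(d_km, dtype=float)
    m = m0 * np.exp(-d / delta_km)
    return np.where(d > cutoff_km, 0.0, m)


def migration_matrix(config: LandscapeConfig) -> np.ndarray:
    """Pairwise per-generation migration proportions from the distance kernel.

    Rows whose off-diagonal mass would exceed 0.5 are rescaled to 0.5 so a
    deme never replaces more than half of itself in one generation.
    """
    diff = config.coords[:, None, :] - config.coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    m = migration_kernel(d, config.m0, config.delta_km, config.cutoff_km)
    np.fill_diagonal(m, 0.0)
    row = m.sum(axis=1)
    over = row > 0.5
    if over.any():
        m[over] *= (0.5 / row[over])[:, None]
    return m


def simulate_landscape(config: LandscapeConfig) -> LandscapeTruth:
    """Run the forward Wright-Fisher simulation and sample genotypes.

    Each generation applies migration, then class-specific selection, then
    binomial drift with 2*pop_size draws; allele frequencies are clamped to
    [0, 1] after the selection push.  Genotypes for the ``n_sampled``
    individuals per deme are Binomial(2, p) draws from the final
    frequencies (Hardy-Weinberg sampling within demes).
    """
    rng = np.random.default_rng(config.seed)
    n_pops, n_loci = config.n_pops, config.n_loci

    counts = np.array(
        [int(round(config.locus_class_fractions.get(c, 0.0) * n_loci))
         for c in LOCUS_CLASSES]
    )
    counts[0] += n_loci - counts.sum()  # absorb rounding into the neutral class
    locus_class = np.repeat(LOCUS_CLASSES, counts)

    host_dir = np.where(np.asarray(config.hosts) == "Adenostoma", 1.0, -1.0)
    climate = config.standardized_covariate()

    is_host = locus_class == "host_selected"
    is_adj = locus_class == "adjacency_specific"
    is_cline = locus_class == "climate_clinal"

    # adjacency-specific loci: each locus gets an independent random +/-
    # orientation per contact pair (opposite signs for the two members, no
    # push elsewhere), so their divergence is tied to contact zones rather
    # than to host class
    adj_dir = np.zeros((n_pops, int(is_adj.sum())))
    for i, j in config.adjacency_pairs:
        signs = rng.choice([-1.0, 1.0], size=adj_dir.shape[1])
        adj_dir[i] = signs
        adj_dir[j] = -signs

    mig = migration_matrix(config)
    row_mass = mig.sum(axis=1, keepdims=True)

    p = np.broadcast_to(
        rng.uniform(config.ancestral_low, config.ancestral_high, size=n_loci),
        (n_pops, n_loci),
    ).copy()
    two_n = 2 * config.pop_size
    for _ in range(config.n_generations):
        p = (1.0 - row_mass) * p + mig @ p
        push = np.zeros_like(p)
        if is_host.any():
            push[:, is_host] = config.s_host * host_dir[:, None]
        if is_adj.any():
            push[:, is_adj] = config.s_adj * adj_dir
        if is_cline.any():
            push[:, is_cline] = config.cline_slope * climate[:, None]
        p = np.clip(p + push * p * (1.0 - p), 0.0, 1.0)
        p = rng.binomial(two_n, p) / two_n

    individuals = []
    populations = {}
    labels = config.pop_labels
    geno_rows = []
    for k, lab in enumerate(labels):
        for s in range(config.n_sampled):
            ind = f"{lab}_i{s:02d}"
            individuals.append(ind)
            populations[ind] = lab
        geno_rows.append(rng.binomial(2, p[k], size=(config.n_sampled, n_loci)))
    genotypes = np.concatenate(geno_rows, axis=0).astype(np.int8)

    # two SNPs per synthetic contig, mirroring short sequenced fragments
    loci = [f"ctg{j // 2:05d}:{100 + 50 * (j % 2)}" for j in range(n_loci)]

    return LandscapeTruth(
        config=config,
        pop_labels=labels,
        true_freqs=p,
        locus_class=np.asarray(locus_class),
        migration_matrix=mig,
        genotypes=genotypes,
        individuals=individuals,
        populations=populations,
        loci=loci,
    )


def simulate_reads(
    truth: LandscapeTruth,
    mean_coverage: float = 0.77,
    error_rate: float = 0.005,
    seed: int | None = None,
) -> ReadCountMatrix:
    """Low-coverage read counts: n ~ Poisson(coverage), alt ~ Binomial(n, e_g).

    The per-read alternate-allele probability is ``error_rate`` for
    homozygous-reference individuals, 1/2 for heterozygotes and
    ``1 - error_rate`` for homozygous-alternate individuals.  The default
    0.77x per-individual coverage matches the sequencing design the
    pipeline emulates (per-population coverage stays high because many
    individuals are pooled per deme).
    """
    if mean_coverage < 0:
        raise ValidationError("mean_coverage must be non-negative")
    if not 0.0 <= error_rate < 0.5:
        raise ValidationError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    g = np.asarray(truth.genotypes)
    n = rng.poisson(mean_coverage, size=g.shape)
    e = np.choose(g, [error_rate, 0.5, 1.0 - error_rate])
    alt = rng.binomial(n, e)
    return ReadCountMatrix(
        individuals=truth.individuals,
        populations=dict(truth.populations),
        loci=truth.loci,
        n_reads=n,
        alt_reads=alt,
    )


def simulate_mating_trials(
    p_within: float = 0.6,
    p_between: float = 0.276,
    n_trials_per_cell: int = 18,
    seed: int | None = None,
    pairs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """No-choice mating trials: Bernoulli copulation outcomes per pairing type.

    Returns a table with one row per (pair, type) cell, type in
    {within, between}.  The defaults put the expected isolation index
    1 - p_between/p_within near 0.54, the level observed for adjacent
    host-ecotype pairs in the system this emulates.
    """
    if not (0.0 <= p_within <= 1.0 and 0.0 <= p_between <= 1.0):
        raise ValidationError("mating probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = ["pair1"]
    rows = []
    for pair in pairs:
        for kind, prob in (("within", p_within), ("between", p_between)):
            n_mat = int(rng.binomial(n_trials_per_cell, prob))
            rows.append((pair, kind, n_trials_per_cell, n_mat))
    return pd.DataFrame(rows, columns=["pair", "type", "n_trials", "n_matings"])


def simulate_morph_counts(
    pops: PopulationTable,
    p_striped_adenostoma: float = 0.9,
    p_striped_ceanothus: float = 0.06,
    n_scored: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Counts of striped individuals per population, host-dependent."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in pops.frame.iterrows():
        prob = p_striped_adenostoma if r["host"] == "Adenostoma" else p_striped_ceanothus
        rows.append(
            (r["population"], r["host"], n_scored, int(rng.binomial(n_scored, prob)))
        )
    return pd.DataFrame(rows, columns=["population", "host", "n_scored", "n_striped"])
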