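"""Burrows' composite measure of Hardy-Weinberg and linkage disequilibrium.

Delta is a population-level, genotype-based joint measure of intralocus
and interlocus disequilibrium that assumes neither Hardy-Weinberg
equilibrium nor phased data:

    Delta_hat = (1 / 2n) * sum_k g_Ak * g_Bk - 2 * p_A * p_B

with g the dosage in {0, 1, 2} and p = sum(g) / 2n.  Its attainable
magnitude is constrained by the allele frequencies of the two loci, so
low-minor-allele-frequency pairs cannot reach large |Delta| even under
complete association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError


def burrows_delta(genotypes_a, genotypes_b) -> tuple[float, int]:
    """Composite disequilibrium for one pair of loci from unphased dosages.

    Missing dosages (negative or NaN) are dropped pairwise; returns
    (delta, n) where n is the number of individuals actually used.
    """
    ga = np.asarray(genotypes_a, dtype=float)
    gb = np.asarray(genotypes_b, dtype=float)
    if ga.shape != gb.shape or ga.ndim != 1:
        raise ValidationError("dosage vectors must be matching 1-D arrays")
    keep = np.isfinite(ga) & np.isfinite(gb) & (ga >= 0) & (gb >= 0)
    ga, gb = ga[keep], gb[keep]
    n = ga.size
    if n == 0:
        raise ValidationError("no individuals left after missing-data removal")
    p_a = ga.sum() / (2.0 * n)
    p_b = gb.sum() / (2.0 * n)
    delta = float((ga * gb).sum() / (2.0 * n) - 2.0 * p_a * p_b)
    return delta, n


@dataclass
class DeltaSummary:
    """Survey summary of composite LD across sampled locus pairs."""

    population: str
    mean_delta: float
    mean_abs_delta: float
    within_contig_mean: float
    within_contig_mean_abs: float
    between_contig_mean: float
    between_contig_mean_abs: float
    n_pairs_evaluated: int
    n_within_contig: int
    n_between_contig: int


def _contig_of(locus: str) -> str:
    return locus.rpartition(":")[0]


def delta_survey(
    genotypes: np.ndarray,
    loci: list[str],
    population: str = "all",
    n_pairs: int | str = 100_000,
    seed: int | None = None,
    return_pairs: bool = False,
) -> DeltaSummary | tuple[DeltaSummary, pd.DataFrame]:
    """Survey Delta over all, or a seed-deterministic random subsample of,
    locus pairs for one population's dosage matrix.

    ``genotypes`` is (n_individuals, n_loci), typically the posterior-modal
    dosages from the genotype posterior.  Contig membership is parsed from
    the "contig:pos" locus IDs; summaries are stratified by whether the two
    loci share a contig.  A requested subsample larger than the pair
    universe is clamped (all pairs evaluated).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    n_loci = genotypes.shape[1]
    if n_loci != len(loci):
        raise ValidationError("loci list must match genotype matrix columns")
    if n_loci < 2:
        raise ValidationError("need at least 2 loci")
    universe = n_loci * (n_loci - 1) // 2
    if n_pairs == "all" or int(n_pairs) >= universe:
        ii, jj = np.triu_indices(n_loci, k=1)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(universe, size=int(n_pairs), replace=False)
        # invert the row-major upper-triangle linear index
        ii = (
            n_loci
            - 2
            - np.floor(
                np.sqrt(-8.0 * flat + 4.0 * n_loci * (n_loci - 1) - 7) / 2.0 - 0.5
            )
        ).astype(np.int64)
        jj = (
            flat + ii + 1 - n_loci * (n_loci - 1) // 2
            + (n_loci - ii) * ((n_loci - ii) - 1) // 2
        ).astype(np.int64)

    # vectorized Delta across the sampled pairs (no missing data path here;
    # burrows_delta handles per-pair missingness for single calls)
    n_ind = genotypes.shape[0]
    p = genotypes.sum(axis=0) / (2.0 * n_ind)
    cross = genotypes.T @ genotypes  # (L, L) sums of g_A * g_B
    deltas = cross[ii, jj] / (2.0 * n_ind) - 2.0 * p[ii] * p[jj]

    contigs = np.asarray([_contig_of(l) for l in loci])
    same = contigs[ii] == contigs[jj]

    def _mean(x: np.ndarray) -> float:
        return float(x.mean()) if x.size else float("nan")

    summary = DeltaSummary(
        population=population,
        mean_delta=_mean(deltas),
        mean_abs_delta=_mean(np.abs(deltas)),
        within_contig_mean=_mean(deltas[same]),
        within_contig_mean_abs=_mean(np.abs(deltas[same])),
        between_contig_mean=_mean(deltas[~same]),
        between_contig_mean_abs=_mean(np.abs(deltas[~same])),
        n_pairs_evaluated=int(deltas.size),
        n_within_contig=int(same.sum()),
        n_between_contig=int((~same).sum()),
    )
    if return_pairs:
        frame = pd.DataFrame(
            {
                "locus_a": np.asarray(loci)[ii],
                "locus_b": np.asarray(loci)[jj],
                "delta": deltas,
                "same_contig": same,
            }
        )
        return summary, frame
    return summary
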