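"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HOSTS = ("Adenostoma", "Ceanothus")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ReadCountMatrix:
    """Per-individual, per-locus sequencing read counts.

    ``n_reads`` is total read depth and ``alt_reads`` the number of reads
    carrying the non-reference allele.  Missing data are represented as
    zero coverage (``n_reads == 0``); the allele-frequency model treats
    missingness and low coverage identically.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: list[str]
    n_reads: np.ndarray
    alt_reads: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        self.n_reads = np.asarray(self.n_reads, dtype=np.int64)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        shape = (len(self.individuals), len(self.loci))
        if self.n_reads.shape != shape or self.alt_reads.shape != shape:
            raise ValidationError(
                f"count matrices must have shape {shape}, got "
                f"{self.n_reads.shape} / {self.alt_reads.shape}"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("locus IDs must be unique")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("individual IDs must be unique")
        if (self.n_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValidationError("read counts must be non-negative")
        if (self.alt_reads > self.n_reads).any():
            bad = np.argwhere(self.alt_reads > self.n_reads)[0]
            raise ValidationError(
                f"alt_reads > n_reads at individual {self.individuals[bad[0]]}, "
                f"locus {self.loci[bad[1]]}"
            )
        if self.populations:
            missing = [i for i in self.individuals if i not in self.populations]
            if missing:
                raise ValidationError(
                    f"individuals without a population assignment: {missing[:5]}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Population labels in first-appearance order of the individuals."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def individual_indices(self, population: str) -> np.ndarray:
        idx = [
            k
            for k, ind in enumerate(self.individuals)
            if self.populations.get(ind) == population
        ]
        return np.asarray(idx, dtype=np.intp)

    def with_populations(self, populations: Mapping[str, str]) -> "ReadCountMatrix":
        return ReadCountMatrix(
            individuals=self.individuals,
            populations=dict(populations),
            loci=self.loci,
            n_reads=self.n_reads,
            alt_reads=self.alt_reads,
        )


@dataclass
class PopulationTable:
    """Sampled populations with host class and planar (or lon/lat) coordinates."""

    frame: pd.DataFrame
    lonlat: bool = False  # coordinates are (lon, lat) degrees, not km

    REQUIRED = ("population", "host", "x_km", "y_km", "n_sampled")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"population table missing column {col!r}")
        if self.frame["population"].duplicated().any():
            dup = self.frame.loc[self.frame["population"].duplicated(), "population"]
            raise ValidationError(f"duplicate population label(s): {list(dup)}")
        bad_host = set(self.frame["host"]) - set(HOSTS)
        if bad_host:
            raise ValidationError(f"unknown host value(s): {bad_host}; expected {HOSTS}")
        coords = self.frame[["x_km", "y_km"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("population coordinates must be finite")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return list(self.frame["population"])

    def host(self, population: str) -> str:
        row = self.frame.loc[self.frame["population"] == population]
        if row.empty:
            raise KeyError(population)
        return str(row["host"].iloc[0])

    def coords(self, population: str) -> tuple[float, float]:
        row = self.frame.loc[self.frame["population"] == population]
        if row.empty:
            raise KeyError(population)
        return float(row["x_km"].iloc[0]), float(row["y_km"].iloc[0])

    def distance_km(self, pop_a: str, pop_b: str) -> float:
        xa, ya = self.coords(pop_a)
        xb, yb = self.coords(pop_b)
        if self.lonlat:
            return _haversine_km(xa, ya, xb, yb)
        return float(np.hypot(xa - xb, ya - yb))


def _haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    r = 6371.0088
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * r * np.arcsin(np.sqrt(a)))


@dataclass
class PairTable:
    """All unordered population pairs with distance, adjacency and host contrast.

    Adjacency is a categorical field observation supplied by the user, never
    derived from a distance threshold.
    """

    frame: pd.DataFrame

    REQUIRED = ("pop_a", "pop_b", "distance_km", "adjacency", "same_host")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"pair table missing column {col!r}")
        keys = {
            tuple(sorted((a, b)))
            for a, b in zip(self.frame["pop_a"], self.frame["pop_b"])
        }
        if len(keys) != len(self.frame):
            raise ValidationError("pair table must have one row per unordered pair")
        if (self.frame["distance_km"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("pair distances must be non-negative")
        bad = set(self.frame["adjacency"]) - {"adjacent", "separated"}
        if bad:
            raise ValidationError(f"unknown adjacency value(s): {bad}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(t) for t in self.frame[["pop_a", "pop_b"]].itertuples(index=False)]

    def row(self, pop_a: str, pop_b: str) -> pd.Series:
        key = tuple(sorted((pop_a, pop_b)))
        for _, r in self.frame.iterrows():
            if tuple(sorted((r["pop_a"], r["pop_b"]))) == key:
                return r
        raise KeyError(key)


def build_pair_table(
    pops: PopulationTable, adjacency_pairs: Sequence[tuple[str, str]] = ()
) -> PairTable:
    """Enumerate all unordered pairs of ``pops`` with computed distances.

    ``adjacency_pairs`` lists the pairs in direct geographic contact; all
    other pairs are classed ``separated``.
    """
    adj = {tuple(sorted(p)) for p in adjacency_pairs}
    labels = pops.populations
    unknown = {p for pair in adj for p in pair} - set(labels)
    if unknown:
        raise ValidationError(f"adjacency pairs reference unknown population(s): {unknown}")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "distance_km": pops.distance_km(a, b),
                    "adjacency": "adjacent" if tuple(sorted((a, b))) in adj else "separated",
                    "same_host": pops.host(a) == pops.host(b),
                }
            )
    return PairTable(pd.DataFrame(rows))


@dataclass
class GenotypePosterior:
    """Posterior probabilities over genotypes {0, 1, 2 non-reference copies}."""

    individuals: list[str]
    loci: list[str]
    probs: np.ndarray  # (n_individuals, n_loci, 3)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.individuals), len(self.loci), 3):
            raise ValidationError("genotype posterior has wrong shape")

    def modal_genotypes(self) -> np.ndarray:
        """Posterior-modal dosage per cell; ties broken toward the heterozygote."""
        p = self.probs
        # argmax with het-favouring tie-break: bump the het column by a hair
        bumped = p.copy()
        bumped[:, :, 1] += 1e-12
        return np.argmax(bumped, axis=2).astype(np.int8)

    def expected_dosage(self) -> np.ndarray:
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]


@dataclass
class AlleleFreqPosterior:
    """MCMC posterior of population allele frequencies per SNP."""

    populations: list[str]
    loci: list[str]
    samples: np.ndarray  # (n_pops, n_loci, n_retained)
    mean: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ci_level: float
    mcmc_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_p, n_l = len(self.populations), len(self.loci)
        if self.samples.shape[:2] != (n_p, n_l):
            raise ValidationError("posterior sample array has wrong shape")
        for arr in (self.mean, self.median, self.lower, self.upper):
            if arr.shape != (n_p, n_l):
                raise ValidationError("posterior summary array has wrong shape")

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    def point_frame(self) -> pd.DataFrame:
        rows = []
        for i, pop in enumerate(self.populations):
            for j, locus in enumerate(self.loci):
                rows.append((pop, locus, self.mean[i, j], self.median[i, j],
                             self.lower[i, j], self.upper[i, j]))
        return pd.DataFrame(
            rows, columns=["population", "locus", "mean", "median", "lower", "upper"]
        )
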