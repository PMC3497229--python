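"""On-disk formats: VCF and TSV read counts, metadata tables, results tables.

Conventions: variant coordinates are 1-based (VCF), locus IDs are
"contig:pos" strings, only biallelic SNPs enter the pipeline.  TSV files
are UTF-8, tab-delimited, with '##key=value' metadata lines followed by a
'#'-prefixed column-header line.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    PairTable,
    PopulationTable,
    ReadCountMatrix,
    ValidationError,
    build_pair_table,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# generic commented-TSV round trip


def write_tsv(frame: pd.DataFrame, path: str, meta: Mapping[str, str] | None = None,
              float_format: str = "%.10g") -> None:
    """Write a DataFrame as a commented TSV ('##' metadata, '#' header line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"##{key}={value}\n")
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)


def read_tsv(path: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a commented TSV written by :func:`write_tsv` (plain TSV also accepted)."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##"):
                skip += 1
                key, _, value = line[2:].rstrip("\n").partition("=")
                meta[key] = value
            elif line.startswith("#"):
                skip += 1
                header = line[1:].rstrip("\n").split("\t")
                break
            else:
                break
    frame = pd.read_csv(path, sep="\t", skiprows=skip, header=None if header else 0,
                        names=header)
    return frame, meta


# ---------------------------------------------------------------------------
# read counts


def read_variant_counts(
    path: str,
    populations: Mapping[str, str] | None = None,
    multiallelic: str = "skip",
) -> ReadCountMatrix:
    """Load per-individual, per-locus read counts from a VCF or a TSV.

    VCF records must carry per-sample AD (allelic depth) or DP fields;
    TSV input is long-format with columns (individual, locus, n_reads,
    alt_reads).  Missing sample entries become zero coverage.

    Parameters
    ----------
    multiallelic:
        'skip' drops records with more than one ALT allele; 'error' raises.
    """
    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic must be 'skip' or 'error'")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        counts = _read_vcf_counts(path, multiallelic)
    else:
        counts = _read_tsv_counts(path)
    if populations is not None:
        counts = counts.with_populations(populations)
    return counts


def _read_vcf_counts(path: str, multiallelic: str) -> ReadCountMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    loci: list[str] = []
    n_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise ParseError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS} (ALT={rec.ALT})"
                )
            continue
        locus = f"{rec.CHROM}:{rec.POS}"
        ad = rec.format("AD")
        if ad is not None:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes missing as negative sentinels
            ref = ad[:, 0]
            alt = ad[:, 1] if ad.shape[1] > 1 else np.zeros_like(ref)
            total = ref + alt
        else:
            dp = rec.format("DP")
            if dp is None:
                raise ParseError(
                    f"record {locus} has neither AD nor DP per-sample fields"
                )
            total = np.asarray(dp, dtype=np.int64).reshape(-1)
            total[total < 0] = 0
            alt = np.zeros_like(total)
        loci.append(locus)
        n_cols.append(total)
        alt_cols.append(alt)
    n_reads = np.column_stack(n_cols) if n_cols else np.zeros((len(samples), 0), int)
    alt_reads = np.column_stack(alt_cols) if alt_cols else np.zeros((len(samples), 0), int)
    try:
        return ReadCountMatrix(samples, {}, loci, n_reads, alt_reads)
    except ValidationError as exc:
        raise ParseError(f"invalid counts in {path}: {exc}") from exc


def _read_tsv_counts(path: str) -> ReadCountMatrix:
    frame, _ = read_tsv(path)
    required = {"individual", "locus", "n_reads", "alt_reads"}
    if not required <= set(frame.columns):
        raise ParseError(
            f"count TSV needs columns {sorted(required)}, got {list(frame.columns)}"
        )
    individuals = list(dict.fromkeys(frame["individual"].astype(str)))
    loci = list(dict.fromkeys(frame["locus"].astype(str)))
    ind_idx = {v: i for i, v in enumerate(individuals)}
    loc_idx = {v: j for j, v in enumerate(loci)}
    n = np.zeros((len(individuals), len(loci)), dtype=np.int64)
    alt = np.zeros_like(n)
    rows = frame["individual"].astype(str).map(ind_idx).to_numpy()
    cols = frame["locus"].astype(str).map(loc_idx).to_numpy()
    n[rows, cols] = frame["n_reads"].to_numpy(dtype=np.int64)
    alt[rows, cols] = frame["alt_reads"].to_numpy(dtype=np.int64)
    try:
        return ReadCountMatrix(individuals, {}, loci, n, alt)
    except ValidationError as exc:
        raise ParseError(f"invalid counts in {path}: {exc}") from exc


def write_counts_tsv(counts: ReadCountMatrix, path: str,
                     meta: Mapping[str, str] | None = None) -> None:
    """Write counts long-format; zero-coverage cells are written too (explicit)."""
    n_ind, n_loc = counts.n_reads.shape
    frame = pd.DataFrame(
        {
            "individual": np.repeat(counts.individuals, n_loc),
            "locus": np.tile(counts.loci, n_ind),
            "n_reads": counts.n_reads.reshape(-1),
            "alt_reads": counts.alt_reads.reshape(-1),
        }
    )
    write_tsv(frame, path, meta)


def write_vcf(counts: ReadCountMatrix, path: str, ref: str = "A", alt: str = "G") -> None:
    """Write counts as a minimal VCF 4.2 with per-sample DP and AD fields.

    Genotypes are emitted as missing ('./.'): the pipeline carries genotype
    uncertainty in the read counts, not in hard calls.
    """
    contigs: dict[str, int] = {}
    parsed = []
    for locus in counts.loci:
        contig, _, pos = locus.rpartition(":")
        pos_i = int(pos)
        parsed.append((contig, pos_i))
        contigs[contig] = max(contigs.get(contig, 0), pos_i)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genomosaic\n")
        for contig, length in contigs.items():
            fh.write(f"##contig=<ID={contig},length={length + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(counts.individuals)
            + "\n"
        )
        for j, (contig, pos) in enumerate(parsed):
            cells = []
            for i in range(counts.n_individuals):
                dp = counts.n_reads[i, j]
                ad_alt = counts.alt_reads[i, j]
                cells.append(f"./.:{dp}:{dp - ad_alt},{ad_alt}")
            fh.write(
                f"{contig}\t{pos}\t{contig}:{pos}\t{ref}\t{alt}\t.\tPASS\t.\t"
                "GT:DP:AD\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# metadata tables


def read_population_table(
    pop_path: str,
    adjacency: str | Sequence[tuple[str, str]] = (),
    lonlat: bool = False,
) -> tuple[PopulationTable, PairTable]:
    """Read the population metadata TSV and enumerate all unordered pairs.

    ``adjacency`` is either a path to a two-column TSV (pop_a, pop_b) or an
    explicit pair list; adjacency is metadata, never inferred from distance.
    """
    frame, meta = read_tsv(pop_path)
    pops = PopulationTable(frame, lonlat=lonlat or meta.get("coords") == "lonlat")
    if isinstance(adjacency, str):
        adj_frame, _ = read_tsv(adjacency)
        pairs = [tuple(t) for t in adj_frame.iloc[:, :2].astype(str).itertuples(index=False)]
    else:
        pairs = [tuple(p) for p in adjacency]
    return pops, build_pair_table(pops, pairs)


def write_population_table(pops: PopulationTable, path: str) -> None:
    meta = {"coords": "lonlat" if pops.lonlat else "planar_km"}
    write_tsv(pops.frame, path, meta)


def write_pair_table(pairs: PairTable, path: str,
                     meta: Mapping[str, str] | None = None) -> None:
    write_tsv(pairs.frame, path, meta)


def validate_counts_populations(counts: ReadCountMatrix, pops: PopulationTable) -> None:
    """Every individual's population must appear in the population table."""
    known = set(pops.populations)
    orphans = {
        ind: pop for ind, pop in counts.populations.items() if pop not in known
    }
    if orphans:
        raise ValidationError(
            f"individuals assigned to unknown population(s): {dict(list(orphans.items())[:5])}"
        )


# ---------------------------------------------------------------------------
# results tables

PER_LOCUS_COLUMNS = ["pair", "locus", "alpha_point", "fst_point", "outlier_flag"]
PER_PAIR_COLUMNS = [
    "pair",
    "distance_km",
    "adjacency",
    "same_host",
    "mean_fst",
    "min_fst",
    "max_fst",
    "n_outliers_high",
    "skewness",
    "kurtosis_raw",
    "kurtosis_excess",
    "p_zero_flow",
    "mig_estimate",
]


def write_results_tables(
    per_locus: pd.DataFrame,
    per_pair: pd.DataFrame,
    out_dir: str,
    meta: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Write the per-locus and per-pair results tables with deterministic columns.

    Missing columns are added as NA so stages can be toggled independently;
    returns the mapping of table name to path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame, columns in (
        ("per_locus", per_locus, PER_LOCUS_COLUMNS),
        ("per_pair", per_pair, PER_PAIR_COLUMNS),
    ):
        out = frame.copy()
        for col in columns:
            if col not in out.columns:
                out[col] = np.nan
        out = out[columns]
        path = os.path.join(out_dir, f"{name}.tsv")
        write_tsv(out, path, meta)
        paths[name] = path
    return paths


def read_results_table(path: str) -> tuple[pd.DataFrame, dict[str, str]]:
    return read_tsv(path)
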