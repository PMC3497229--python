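"""Seed-deterministic orchestration: simulate -> freqs -> divergence/ld/abc
-> mantel/clines -> report.

A run is driven by a nested configuration (YAML-compatible dict).  Every
output table embeds the hash of the configuration that produced it, so
tables from mismatched runs refuse to combine; the global seed
deterministically derives an independent seed per stage, so toggling one
stage never perturbs another's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .allele_freq import MCMCConfig, estimate_allele_frequencies
from .fmodel import (
    counts_from_genotype_posterior,
    counts_from_reads,
    fit_fmodel_pairs,
    fst_distribution_summary,
)
from .gene_flow import (
    AbcPriors,
    IsoMigParams,
    abc_model_choice,
    build_reference_table,
    summary_stats_from_freqs,
)
from .ld import delta_survey
from .popstats import DistanceMatrix, cline_regression, mantel
from .simulate import default_landscape_config, simulate_landscape, simulate_reads
from .types import ValidationError

log = logging.getLogger("genomosaic")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "stages": {
        "simulate": True,
        "freqs": True,
        "divergence": True,
        "ld": True,
        "abc": True,
        "mantel": True,
        "clines": True,
    },
    "landscape": {},  # overrides of default_landscape_config
    "reads": {"mean_coverage": 0.77, "error_rate": 0.005},
    "freqs": {"iterations": 4000, "burn_in": 1000, "thinning": 4,
              "error_rate": 0.005},
    "divergence": {"iterations": 5000, "burn_in": 1000, "thinning": 4,
                   "q": 0.95, "mode": "genotype_posterior"},
    "ld": {"n_pairs": 20000},
    "abc": {"n_sims": 5000, "tolerance_fraction": 0.01, "n_chrom": "auto",
            "n_loci": 400},
    "mantel": {"n_perm": 999},
    "clines": {"n_outlier_loci": 16, "n_random_loci": 16},
}


def merge_config(overrides: dict | None = None) -> dict:
    def _merge(base: dict, over: dict) -> dict:
        out = dict(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = _merge(out[k], v)
            else:
                out[k] = v
        return out

    return _merge(DEFAULT_CONFIG, overrides or {})


def load_config(path: str | None) -> dict:
    if path is None:
        return merge_config()
    with open(path, "r", encoding="utf-8") as fh:
        return merge_config(yaml.safe_load(fh) or {})


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


@dataclass
class RunResult:
    out_dir: str
    config: dict
    master: pd.DataFrame | None = None
    errors: dict[str, str] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(config: dict | None = None, out_dir: str = "run") -> RunResult:
    """Execute the configured stages in dependency order.

    A failing stage is recorded and its dependents are skipped; independent
    stages still run.  Reruns with identical config reproduce all outputs.
    """
    config = merge_config(config)
    os.makedirs(out_dir, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash}
    seed = int(config["seed"])
    result = RunResult(out_dir=out_dir, config=config)

    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config hash %s; config: %s", chash, json.dumps(config, default=str))

    stages = config["stages"]
    truth = counts = freqs = gpost = None
    pair_table = pop_table = None
    divergences = {}
    abc_results = {}

    def _fail(stage: str, exc: Exception) -> None:
        log.error("stage %s failed: %s", stage, exc)
        result.errors[stage] = str(exc)

    # --- simulate -----------------------------------------------------------
    if stages.get("simulate", True):
        try:
            lc = dict(config["landscape"])
            lc.setdefault("seed", stage_seed(seed, "simulate"))
            cfg = default_landscape_config(**lc)
            truth = simulate_landscape(cfg)
            counts = simulate_reads(
                truth,
                mean_coverage=float(config["reads"]["mean_coverage"]),
                error_rate=float(config["reads"]["error_rate"]),
                seed=stage_seed(seed, "reads"),
            )
            pop_table = truth.population_table()
            pair_table = truth.pair_table()
            log.info(
                "simulated %d pops x %d loci (classes: %s); coverage %.2fx",
                cfg.n_pops, cfg.n_loci, cfg.locus_class_fractions,
                config["reads"]["mean_coverage"],
            )
            gio.write_population_table(pop_table, os.path.join(out_dir, "populations.tsv"))
            gio.write_pair_table(pair_table, os.path.join(out_dir, "pairs.tsv"), meta)
            gio.write_counts_tsv(counts, os.path.join(out_dir, "counts.tsv"), meta)
            gio.write_vcf(counts, os.path.join(out_dir, "counts.vcf"))
            truth_frame = pd.DataFrame(
                truth.true_freqs.T, columns=truth.pop_labels
            )
            truth_frame.insert(0, "locus", truth.loci)
            truth_frame.insert(1, "locus_class", truth.locus_class)
            gio.write_tsv(truth_frame, os.path.join(out_dir, "truth_freqs.tsv"), meta)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            _fail("simulate", exc)
            truth = counts = None

    # --- freqs --------------------------------------------------------------
    if stages.get("freqs", True) and counts is not None:
        try:
            fcfg = config["freqs"]
            freqs, gpost = estimate_allele_frequencies(
                counts,
                error_rate=float(fcfg["error_rate"]),
                mcmc=MCMCConfig(
                    iterations=int(fcfg["iterations"]),
                    burn_in=int(fcfg["burn_in"]),
                    thinning=int(fcfg["thinning"]),
                    seed=stage_seed(seed, "freqs"),
                ),
            )
            gio.write_tsv(freqs.point_frame(), os.path.join(out_dir, "allele_freqs.tsv"),
                          meta)
            log.info("allele frequencies estimated for %d populations", len(freqs.populations))
        except Exception as exc:  # noqa: BLE001
            _fail("freqs", exc)
            freqs = gpost = None

    # --- divergence ---------------------------------------------------------
    per_locus_frames = []
    if stages.get("divergence", True) and counts is not None and pair_table is not None:
        try:
            dcfg = config["divergence"]
            mode = dcfg.get("mode", "genotype_posterior")
            pairs = pair_table.pairs
            if mode == "genotype_posterior":
                if gpost is None:
                    raise ValidationError(
                        "divergence mode 'genotype_posterior' needs the freqs stage"
                    )
                pair_counts = [
                    counts_from_genotype_posterior(gpost, counts.populations, p)
                    for p in pairs
                ]
            elif mode == "reads":
                pair_counts = [counts_from_reads(counts, p) for p in pairs]
            else:
                raise ValidationError(f"unknown divergence mode {mode!r}")
            fits = fit_fmodel_pairs(
                pair_counts,
                mcmc=MCMCConfig(
                    iterations=int(dcfg["iterations"]),
                    burn_in=int(dcfg["burn_in"]),
                    thinning=int(dcfg["thinning"]),
                    seed=stage_seed(seed, "divergence"),
                ),
                q=float(dcfg["q"]),
                store_samples=False,
            )
            divergences = dict(zip(pairs, fits))
            for fit in fits:
                per_locus_frames.append(fit.to_locus_frame())
                log.info(
                    "pair %s: %d loci without data, %d monomorphic in pair, %d high outliers",
                    fit.pair, fit.n_excluded, fit.meta.get("n_monomorphic", -1),
                    fit.n_outliers_high,
                )
        except Exception as exc:  # noqa: BLE001
            _fail("divergence", exc)
            divergences = {}

    # --- ld -----------------------------------------------------------------
    if stages.get("ld", True) and gpost is not None and counts is not None:
        try:
            rows = []
            modal = gpost.modal_genotypes()
            for pop in counts.population_labels:
                idx = counts.individual_indices(pop)
                summary = delta_survey(
                    modal[idx],
                    counts.loci,
                    population=pop,
                    n_pairs=int(config["ld"]["n_pairs"]),
                    seed=stage_seed(seed, f"ld:{pop}"),
                )
                rows.append(vars(summary))
            gio.write_tsv(pd.DataFrame(rows), os.path.join(out_dir, "ld_summary.tsv"),
                          meta)
            log.info("composite LD surveyed for %d populations", len(rows))
        except Exception as exc:  # noqa: BLE001
            _fail("ld", exc)

    # --- abc ----------------------------------------------------------------
    if stages.get("abc", True) and freqs is not None and pair_table is not None:
        try:
            acfg = config["abc"]
            n_loci_abc = min(int(acfg["n_loci"]), len(freqs.loci))
            sel = np.linspace(0, len(freqs.loci) - 1, n_loci_abc).astype(int)
            if acfg["n_chrom"] == "auto":
                # reads approximate draws of distinct allele copies at low
                # coverage; cap at 2N sampled copies
                depth = [
                    int(np.median(counts.n_reads[counts.individual_indices(p)].sum(axis=0)))
                    for p in freqs.populations
                ]
                n_chrom = int(np.clip(np.median(depth), 8, 2 * counts.n_individuals))
            else:
                n_chrom = int(acfg["n_chrom"])
            template = IsoMigParams(n_loci=n_loci_abc, n_chrom_1=n_chrom,
                                    n_chrom_2=n_chrom)
            reference = build_reference_table(
                AbcPriors(), n_sims=int(acfg["n_sims"]),
                seed=stage_seed(seed, "abc"), template=template,
            )
            log.info("ABC reference table: %d simulations, n_chrom=%d, %d loci",
                     reference.stats.shape[0], n_chrom, n_loci_abc)
            for pair in pair_table.pairs:
                i = freqs.pop_index(pair[0])
                j = freqs.pop_index(pair[1])
                obs = summary_stats_from_freqs(
                    freqs.mean[i, sel], freqs.mean[j, sel], atol=1.0 / (2 * n_chrom)
                )
                abc_results[pair] = abc_model_choice(
                    obs,
                    tolerance_fraction=float(acfg["tolerance_fraction"]),
                    reference=reference,
                    seed=stage_seed(seed, f"abc:{pair}"),
                )
        except Exception as exc:  # noqa: BLE001
            _fail("abc", exc)
            abc_results = {}

    # --- master table -------------------------------------------------------
    master_rows = []
    if pair_table is not None:
        for _, prow in pair_table.frame.iterrows():
            pair = (prow["pop_a"], prow["pop_b"])
            row = {
                "pair": f"{pair[0]}x{pair[1]}",
                "distance_km": prow["distance_km"],
                "adjacency": prow["adjacency"],
                "same_host": prow["same_host"],
            }
            fit = divergences.get(pair)
            if fit is not None:
                fst = fit.fst_point[fit.included]
                row.update(
                    mean_fst=float(np.nanmean(fst)),
                    min_fst=float(np.nanmin(fst)),
                    max_fst=float(np.nanmax(fst)),
                    n_outliers_high=fit.n_outliers_high,
                )
                try:
                    shape = fst_distribution_summary(fit)
                    row.update(
                        skewness=shape.skewness,
                        kurtosis_raw=shape.kurtosis_raw,
                        kurtosis_excess=shape.kurtosis_excess,
                    )
                except ValidationError:
                    pass
            abc_res = abc_results.get(pair)
            if abc_res is not None:
                row.update(
                    p_zero_flow=abc_res.p_zero_flow,
                    mig_estimate=abc_res.m_posterior_median,
                )
            master_rows.append(row)
        master = pd.DataFrame(master_rows)
        per_locus = (
            pd.concat(per_locus_frames, ignore_index=True)
            if per_locus_frames
            else pd.DataFrame(columns=gio.PER_LOCUS_COLUMNS)
        )
        paths = gio.write_results_tables(per_locus, master, out_dir, meta)
        result.artifacts.update(paths)
        result.master = master

    # --- mantel -------------------------------------------------------------
    if stages.get("mantel", True) and result.master is not None and divergences:
        try:
            mrows = _mantel_stage(result.master, pair_table,
                                  int(config["mantel"]["n_perm"]),
                                  stage_seed(seed, "mantel"))
            gio.write_tsv(pd.DataFrame(mrows), os.path.join(out_dir, "mantel.tsv"), meta)
        except Exception as exc:  # noqa: BLE001
            _fail("mantel", exc)

    # --- clines -------------------------------------------------------------
    if stages.get("clines", True) and freqs is not None and divergences:
        try:
            ccfg = config["clines"]
            cline_frame = _clines_stage(
                freqs, divergences, truth,
                n_outlier=int(ccfg["n_outlier_loci"]),
                n_random=int(ccfg["n_random_loci"]),
                seed=stage_seed(seed, "clines"),
            )
            gio.write_tsv(cline_frame, os.path.join(out_dir, "clines.tsv"), meta)
        except Exception as exc:  # noqa: BLE001
            _fail("clines", exc)

    log.removeHandler(handler)
    handler.close()
    return result


def _mantel_stage(master: pd.DataFrame, pair_table, n_perm: int, seed: int) -> list[dict]:
    labels = sorted(
        set(pair_table.frame["pop_a"]) | set(pair_table.frame["pop_b"])
    )
    geo = {}
    gen = {}
    outl = {}
    for _, r in pair_table.frame.iterrows():
        key = (r["pop_a"], r["pop_b"])
        geo[key] = r["distance_km"]
        sub = master.loc[master["pair"] == f"{key[0]}x{key[1]}"]
        gen[key] = float(sub["mean_fst"].iloc[0]) if "mean_fst" in sub else np.nan
        outl[key] = (
            float(sub["n_outliers_high"].iloc[0]) if "n_outliers_high" in sub else np.nan
        )
    rows = []
    dm_geo = DistanceMatrix.from_pairs(labels, geo)
    for name, vals in (("mean_fst", gen), ("n_outliers_high", outl)):
        if any(np.isnan(v) for v in vals.values()):
            continue
        dm = DistanceMatrix.from_pairs(labels, vals)
        res = mantel(dm_geo, dm, n_perm=n_perm, seed=seed)
        rows.append(
            {"comparison": f"geographic_distance~{name}", "r": res.r, "p": res.p,
             "n_perm": res.n_perm, "tail": res.tail}
        )
    return rows


def _clines_stage(freqs, divergences, truth, n_outlier: int, n_random: int,
                  seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    # rank loci by how often they are flagged high across pairs
    counts_high = np.zeros(len(freqs.loci))
    for fit in divergences.values():
        counts_high += np.asarray(fit.outlier_flags == "high", dtype=float)
    order = np.argsort(-counts_high, kind="stable")
    outlier_loci = [i for i in order if counts_high[i] > 0][:n_outlier]
    pool = [i for i in range(len(freqs.loci)) if i not in set(outlier_loci)]
    random_loci = list(rng.choice(pool, size=min(n_random, len(pool)), replace=False))

    cfg = truth.config
    covariates = pd.DataFrame(
        {
            "climPC1": cfg.standardized_covariate(),
            "climPC2": cfg.coords[:, 1],
            "longitude": cfg.coords[:, 0],
        }
    )
    rows = []
    for cls, loci in (("outlier", outlier_loci), ("random", random_loci)):
        for j in loci:
            fitc = cline_regression(freqs.mean[:, j], covariates, locus=freqs.loci[j])
            for cov in covariates.columns:
                rows.append(
                    {
                        "locus": freqs.loci[j],
                        "locus_set": cls,
                        "covariate": cov,
                        "slope": fitc.coefficients[cov],
                        "p": fitc.p_values[cov],
                        "r_squared": fitc.r_squared,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def report(run_dir: str, fmt: str = "png") -> list[str]:
    """Figures from a completed run directory (only what its stages produced).

    (a) log-log outliers vs distance with adjacency coded; (b) per-pair
    logit F_ST histograms with the genome-wide predictive overlay and the
    95th-quantile line need per-locus output; (c) gene flow vs distance.
    Figures whose inputs are missing are skipped with a notice.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[str] = []
    master_path = os.path.join(run_dir, "per_pair.tsv")
    if not os.path.exists(master_path):
        raise FileNotFoundError(f"no master table at {master_path}")
    master, master_meta = gio.read_results_table(master_path)

    def _check_hash(meta: dict, path: str) -> None:
        if meta.get("config_hash") not in (None, master_meta.get("config_hash")):
            raise ValidationError(
                f"{path} was produced by a different configuration "
                f"({meta.get('config_hash')} != {master_meta.get('config_hash')})"
            )

    # (a) outliers vs distance
    if master["n_outliers_high"].notna().any():
        fig, ax = plt.subplots(figsize=(5, 4))
        for adj, mk in (("separated", "o"), ("adjacent", "^")):
            sub = master[master["adjacency"] == adj]
            ax.scatter(
                sub["distance_km"], sub["n_outliers_high"].clip(lower=0.5),
                marker=mk, label=adj,
                facecolors="k" if adj == "separated" else "none", edgecolors="k",
            )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("geographic distance (km, log scale)")
        ax.set_ylabel("high F$_{ST}$ outliers (log scale)")
        if len(master) > 1:
            sep = master[(master["adjacency"] == "separated")
                         & master["n_outliers_high"].notna()]
            if len(sep) > 2:
                x = np.log10(sep["distance_km"])
                y = np.log10(sep["n_outliers_high"].clip(lower=0.5))
                b, a = np.polyfit(x, y, 1)
                xs = np.linspace(x.min(), x.max(), 50)
                ax.plot(10 ** xs, 10 ** (a + b * xs), "k--", lw=1)
        ax.legend()
        fig.tight_layout()
        path = os.path.join(run_dir, f"outliers_vs_distance.{fmt}")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    else:
        log.info("report: no outlier counts; skipping outliers-vs-distance figure")

    # (b) per-pair logit FST distributions
    locus_path = os.path.join(run_dir, "per_locus.tsv")
    if os.path.exists(locus_path):
        per_locus, meta = gio.read_results_table(locus_path)
        _check_hash(meta, locus_path)
        if per_locus["alpha_point"].notna().any():
            pairs = list(dict.fromkeys(per_locus["pair"]))[:6]
            fig, axes = plt.subplots(
                1, len(pairs), figsize=(3 * len(pairs), 3), squeeze=False
            )
            for ax, pair in zip(axes[0], pairs):
                vals = per_locus.loc[per_locus["pair"] == pair, "alpha_point"].dropna()
                ax.hist(vals, bins=40, density=True, color="0.7")
                mu, sd = vals.mean(), vals.std()
                xs = np.linspace(vals.min() - 1, vals.max() + 1, 200)
                ax.plot(xs, np.exp(-0.5 * ((xs - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)),
                        "k--", lw=1)
                ax.axvline(np.quantile(vals, 0.95), color="k", lw=1)
                ax.set_title(pair, fontsize=9)
                ax.set_xlabel(r"logit $F_{ST}$")
            fig.tight_layout()
            path = os.path.join(run_dir, f"fst_distributions.{fmt}")
            fig.savefig(path, dpi=150)
            plt.close(fig)
            written.append(path)
    else:
        log.info("report: no per-locus table; skipping distribution figure")

    # (c) gene flow vs distance
    if master["p_zero_flow"].notna().any():
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].scatter(master["distance_km"], master["p_zero_flow"], c="k")
        axes[0].set_xlabel("geographic distance (km)")
        axes[0].set_ylabel("P(zero gene flow)")
        axes[1].scatter(master["distance_km"], master["mig_estimate"], c="k")
        axes[1].set_xlabel("geographic distance (km)")
        axes[1].set_ylabel(r"$4N_e m$ (posterior median)")
        fig.tight_layout()
        path = os.path.join(run_dir, f"gene_flow_vs_distance.{fmt}")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    else:
        log.info("report: no ABC output; skipping gene-flow figure")
    return written
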