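"""Matrix correlations, ordination, clines and behavioural indices.

Covers the analyses that relate genomic divergence to geography, host use
and climate: simple and partial Mantel permutation tests on distance
matrices, PCA of genotype-state posterior probabilities, ordinary
least-squares allele-frequency clines on climatic and spatial covariates,
the sexual-isolation index from no-choice mating trials, host morph
divergence and the two-sample t-test used to compare adjacent vs
separated population pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GenotypePosterior, ValidationError


# ---------------------------------------------------------------------------
# distance matrices and Mantel tests


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix keyed by population labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("labels must be unique")
        if self.values.shape != (n, n):
            raise ValidationError("matrix must be square on the labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("diagonal must be zero")

    @classmethod
    def from_pairs(cls, labels: list[str], pair_values: dict) -> "DistanceMatrix":
        n = len(labels)
        m = np.zeros((n, n))
        idx = {lab: i for i, lab in enumerate(labels)}
        for (a, b), v in pair_values.items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
        return cls(labels, m)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int | None = None


def _triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _check_pair(x: DistanceMatrix, y: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if x.labels != y.labels:
        y = y.reorder(x.labels)
    if len(x.labels) < 4:
        raise ValidationError("Mantel tests need at least 4 labels")
    return x.values, y.values


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise ValidationError("constant distance triangle: correlation undefined")
    return float(np.corrcoef(u, v)[0, 1])


def _perm_p(r_obs: float, r_perm: np.ndarray, tail: str) -> float:
    n_perm = len(r_perm)
    if tail == "two_sided":
        hits = int((np.abs(r_perm) >= abs(r_obs) - 1e-15).sum())
    elif tail == "greater":
        hits = int((r_perm >= r_obs - 1e-15).sum())
    elif tail == "less":
        hits = int((r_perm <= r_obs + 1e-15).sum())
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (1 + hits) / (1 + n_perm)


def mantel(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_perm: int = 999,
    tail: str = "two_sided",
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test of the correlation between two distance matrices.

    The observed statistic is the Pearson correlation of the strict upper
    triangles; the null is generated by simultaneous row/column permutation
    of ``y``, which preserves the dependence among entries sharing a label.
    p = (1 + #{r_perm as extreme}) / (1 + n_perm).  With ``exact=True`` all
    n! permutations are enumerated (identity included) and
    p = #{as extreme} / n!.
    """
    mx, my = _check_pair(x, y)
    u = _triangle(mx)
    r_obs = _corr(u, _triangle(my))
    n = mx.shape[0]
    if exact:
        perms = itertools.permutations(range(n))
        r_perm = np.array(
            [_corr(u, _triangle(my[np.ix_(p, p)])) for p in perms]
        )
        # exact mode: p = #{r_perm as extreme} / n! (identity always counts)
        if tail == "two_sided":
            p_val = float((np.abs(r_perm) >= abs(r_obs) - 1e-15).mean())
        elif tail == "greater":
            p_val = float((r_perm >= r_obs - 1e-15).mean())
        else:
            p_val = float((r_perm <= r_obs + 1e-15).mean())
        return MantelResult(r_obs, p_val, len(r_perm), tail, seed)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        r_perm[k] = _corr(u, _triangle(my[np.ix_(perm, perm)]))
    return MantelResult(r_obs, _perm_p(r_obs, r_perm, tail), n_perm, tail, seed)


def partial_mantel(
    x: DistanceMatrix,
    y: DistanceMatrix,
    z: DistanceMatrix,
    n_perm: int = 999,
    tail: str = "two_sided",
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of x ~ y controlling for z (residual method).

    The triangles of x and y are each regressed on the triangle of z; the
    observed statistic is the correlation of the residuals.  The null
    permutes y's rows/columns and recomputes its residuals, preserving the
    covariate structure of x and z.
    """
    mx, my = _check_pair(x, y)
    _, mz = _check_pair(x, z)
    u, w = _triangle(mx), _triangle(mz)

    def _resid(v: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones_like(w), w])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ru = _resid(u)
    ry = _resid(_triangle(my))
    scale = max(float(_triangle(my).std()), 1.0)
    if ry.std() <= 1e-12 * scale:
        # y fully explained by the covariate matrix: partial r is 0 by
        # definition and no permutation can make it smaller
        return MantelResult(0.0, 1.0, n_perm, tail, seed)
    r_obs = _corr(ru, ry)
    rng = np.random.default_rng(seed)
    n = mx.shape[0]
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        r_perm[k] = _corr(ru, _resid(_triangle(my[np.ix_(perm, perm)])))
    return MantelResult(r_obs, _perm_p(r_obs, r_perm, tail), n_perm, tail, seed)


# ---------------------------------------------------------------------------
# ordination


def genotype_pca(
    gpost: GenotypePosterior, mode: str = "two_state"
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of genotype-state posterior probabilities.

    Variables are the per-locus posterior probabilities of two genotype
    states (hom-ref and het; the third is redundant given the first two)
    or all three states; individuals are rows.  Columns are centered, not
    scaled (probabilities share a scale).  Component signs are fixed by
    making each component's largest-magnitude loading positive.

    Returns (scores, explained_variance_ratio); with zero total variance
    the scores are all zero and the ratios NaN.
    """
    if mode not in ("two_state", "three_state"):
        raise ValidationError("mode must be 'two_state' or 'three_state'")
    p = gpost.probs
    if p.shape[0] < 2 or p.shape[1] < 2:
        raise ValidationError("need at least 2 individuals and 2 loci")
    n_states = 2 if mode == "two_state" else 3
    x = p[:, :, :n_states].reshape(p.shape[0], -1)
    x = x - x.mean(axis=0, keepdims=True)
    if not x.any():
        n_comp = min(x.shape)
        return np.zeros((p.shape[0], n_comp)), np.full(n_comp, np.nan)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    var = s ** 2
    return scores, var / var.sum()


def covariate_pca(covariates: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-population covariates (z-scored), e.g. synthetic climate axes."""
    x = covariates.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = pd.DataFrame(
        u * s,
        index=covariates.index,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    var = s ** 2
    return scores, var / var.sum()


# ---------------------------------------------------------------------------
# clines


@dataclass
class ClineFit:
    locus: str
    coefficients: pd.Series  # standardized-covariate slopes
    p_values: pd.Series
    partial_residuals: pd.DataFrame  # per-covariate component + residual series
    r_squared: float


def cline_regression(
    freq_point: np.ndarray,
    covariates: pd.DataFrame,
    locus: str = "",
) -> ClineFit:
    """OLS of per-population allele frequency on standardized covariates.

    Covariates (e.g. climPC1, climPC2, longitude) are z-scored before the
    fit, so slopes are per-SD effects; per-coefficient two-sided t-test
    p-values and partial residual series (residual + own component, for
    partial plots) are returned.
    """
    import statsmodels.api as sm

    y = np.asarray(freq_point, dtype=float)
    names = list(covariates.columns)
    x = covariates.to_numpy(dtype=float)
    if len(y) != x.shape[0]:
        raise ValidationError("frequency vector and covariates must align")
    if len(y) <= x.shape[1] + 1:
        raise ValidationError("need n populations > n covariates + 1")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [names[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"constant covariate column(s): {bad}")
    xz = (x - x.mean(axis=0)) / sd
    if y.std() <= 1e-14:
        # nothing to explain: all slopes zero with no evidence against them
        zeros = pd.Series(np.zeros(len(names)), index=names)
        ones = pd.Series(np.ones(len(names)), index=names)
        partial = pd.DataFrame({n: np.zeros(len(y)) for n in names})
        return ClineFit(locus, zeros, ones, partial, 0.0)
    design = sm.add_constant(xz)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(xz, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValidationError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(y, design).fit()
    coefs = pd.Series(fit.params[1:], index=names)
    pvals = pd.Series(fit.pvalues[1:], index=names)
    resid = fit.resid
    partial = pd.DataFrame(
        {name: resid + coefs[name] * xz[:, i] for i, name in enumerate(names)}
    )
    return ClineFit(locus, coefs, pvals, partial, float(fit.rsquared))


# ---------------------------------------------------------------------------
# behavioural / phenotypic indices


def isolation_index(pct_within: float, pct_between: float) -> float:
    """Sexual isolation: 1 - (% between-population mating / % within).

    May be negative (between-matings exceed within); not clamped.
    """
    if pct_within <= 0:
        raise ValidationError("isolation index undefined when % within-mating is 0")
    return 1.0 - pct_between / pct_within


def isolation_index_from_trials(trials: pd.DataFrame) -> float:
    """Isolation index from a mating-trial table (pair, type, n_trials, n_matings)."""
    agg = trials.groupby("type")[["n_trials", "n_matings"]].sum()
    for kind in ("within", "between"):
        if kind not in agg.index:
            raise ValidationError(f"trial table lacks {kind!r} rows")
    pct = 100.0 * agg["n_matings"] / agg["n_trials"]
    return isolation_index(float(pct["within"]), float(pct["between"]))


def morph_divergence(pct_striped_adenostoma: float, pct_striped_ceanothus: float) -> float:
    """Signed host difference in % striped (Adenostoma minus Ceanothus)."""
    for v in (pct_striped_adenostoma, pct_striped_ceanothus):
        if not 0.0 <= v <= 100.0:
            raise ValidationError("percentages must be in [0, 100]")
    return pct_striped_adenostoma - pct_striped_ceanothus


def two_sample_ttest(
    group_a, group_b, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test; returns (t, df, p).

    'student' pools variances (df = n1 + n2 - 2); 'welch' uses the
    Welch-Satterthwaite df.  Degenerate zero-variance inputs return t = 0,
    p = 1 when the means are equal and p -> 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "student":
        df = a.size + b.size - 2.0
    elif variant == "welch":
        if va == 0 and vb == 0:
            df = a.size + b.size - 2.0
        else:
            num = (va / a.size + vb / b.size) ** 2
            den = (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
            df = num / den
    else:
        raise ValidationError("variant must be 'student' or 'welch'")
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(df), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(df), float(p)


def hudson_fst(p1, p2) -> float:
    """Genome-wide Hudson F_ST as a ratio of averages over loci (the
    recommended multi-locus combination: mean numerator / mean denominator)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not keep.any():
        raise ValidationError("F_ST undefined: all loci monomorphic")
    return float(num[keep].mean() / den[keep].mean())
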