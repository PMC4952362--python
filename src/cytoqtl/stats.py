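"""Core association statistics.

The statistical primitives every pipeline stage builds on: the Gaussian-family
Rao score test used for eQTL mapping, the allelic case-control chi-squared
test, the genomic-control inflation factor lambda and its lambda_1000
rescaling, empirical permutation p values, the pooled-permutation FDR
estimator, Benjamini-Hochberg adjustment, Spearman rank correlation and
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AssocStat",
    "InflationResult",
    "CHI2_1_MEDIAN",
    "score_test_glm",
    "allelic_chi2",
    "genomic_inflation",
    "lambda_1000",
    "empirical_p",
    "bh_adjust",
    "permutation_fdr",
    "spearman_rho",
    "fisher_exact_2x2",
]

#: Median of the chi-squared distribution with 1 degree of freedom.
CHI2_1_MEDIAN = 0.4549364231


@dataclass(frozen=True)
class AssocStat:
    """A 1-df chi-squared association statistic with its upper-tail p value."""

    snp_id: str
    chi2: float
    p: float


@dataclass(frozen=True)
class InflationResult:
    """Genomic inflation factor and its rescaling to 1000 cases/1000 controls."""

    lam: float
    lambda_1000: float
    n_cases: int
    n_controls: int


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def score_test_glm(
    expression,
    genotype,
    covariates=None,
    snp_id: str = "",
) -> AssocStat:
    """Rao score test for adding genotype to a Gaussian linear model.

    Fits the covariate-only (null) model of expression by least squares,
    then scores the genotype term at the null fit. The statistic is

        U^2 / (sigma0^2 * g' M g),  U = g' e,

    where ``e`` are null-model residuals, ``M`` the annihilator of the
    covariate design (intercept always included) and ``sigma0^2`` the
    null-model maximum-likelihood variance ``e'e / n``. This equals
    ``n`` times the squared partial correlation of expression and genotype
    given the covariates. The p value is the upper tail of chi-squared
    with 1 df (one-tailed in the chi-squared score).

    Samples with missing (NaN) genotype are removed pairwise before testing.
    """
    y = _as_1d(expression, "expression")
    g = _as_1d(genotype, "genotype")
    if y.shape != g.shape:
        raise ValueError("expression and genotype lengths differ")
    if covariates is None:
        X = np.empty((y.size, 0))
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError("covariate rows do not match sample count")
    keep = ~np.isnan(g)
    y, g, X = y[keep], g[keep], X[keep]
    n = y.size
    if np.unique(g).size < 2:
        raise ValueError("degenerate genotype: fewer than 2 distinct dosage values")
    Xi = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta_null, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    e = y - Xi @ beta_null
    sigma0_sq = float(e @ e) / n
    gcoef, *_ = np.linalg.lstsq(Xi, g, rcond=None)
    mg = g - Xi @ gcoef
    gmg = float(g @ mg)
    if sigma0_sq <= 0.0 or gmg <= 0.0:
        # expression fully explained by covariates, or genotype collinear with
        # them: no information left to score
        chi2 = 0.0
    else:
        u = float(g @ e)
        chi2 = u * u / (sigma0_sq * gmg)
    return AssocStat(snp_id=snp_id, chi2=chi2, p=float(sps.chi2.sf(chi2, df=1)))


def allelic_chi2(case_dosages, control_dosages, snp_id: str = "") -> AssocStat:
    """Pearson chi-squared on the 2x2 allele-count table, 1 df, no correction.

    Each sample contributes two alleles; the table rows are cases/controls
    and the columns REF/ALT allele counts. Missing dosages are excluded.
    Invariant under swapping which allele is counted.
    """
    a = _as_1d(case_dosages, "case_dosages")
    b = _as_1d(control_dosages, "control_dosages")
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    both = np.concatenate([a, b])
    if not np.all(np.isin(both, (0.0, 1.0, 2.0))):
        bad = both[~np.isin(both, (0.0, 1.0, 2.0))][0]
        raise ValueError(f"dosage {bad} outside {{0,1,2}}")
    alt_case, alt_ctrl = float(a.sum()), float(b.sum())
    ref_case, ref_ctrl = 2.0 * a.size - alt_case, 2.0 * b.size - alt_ctrl
    chi2 = _chi2_2x2(ref_case, alt_case, ref_ctrl, alt_ctrl)
    return AssocStat(snp_id=snp_id, chi2=chi2, p=float(sps.chi2.sf(chi2, df=1)))


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-squared of [[a, b], [c, d]] without continuity correction."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("undefined statistic: zero margin in allele-count table")
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def allelic_chi2_counts(ref_case, alt_case, ref_ctrl, alt_ctrl):
    """Vectorized allelic chi-squared from allele counts (no margin checks)."""
    a = np.asarray(ref_case, dtype=float)
    b = np.asarray(alt_case, dtype=float)
    c = np.asarray(ref_ctrl, dtype=float)
    d = np.asarray(alt_ctrl, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    return chi2


def genomic_inflation(chi2_values) -> float:
    """Genomic-control inflation factor: median chi2 over the chi2_1 median."""
    v = _as_1d(chi2_values, "chi2_values")
    if v.size == 0:
        raise ValueError("empty chi2 vector")
    return float(np.median(v)) / CHI2_1_MEDIAN


def lambda_1000(lam: float, n_cases: int, n_controls: int) -> float:
    """Rescale an inflation factor to an equivalent 1000-case/1000-control study.

    lambda_1000 = 1 + (lambda - 1) * ((1/n_cases + 1/n_controls) /
                                      (1/1000 + 1/1000))
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("case and control counts must be positive")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    scale = (1.0 / n_cases + 1.0 / n_controls) / (1.0 / 1000 + 1.0 / 1000)
    return 1.0 + (lam - 1.0) * scale


def empirical_p(observed: float, permuted, conservative: bool = False) -> float:
    """Fraction of permuted statistics strictly greater than the observed one.

    Ties count as not greater, so the result may be exactly 0. With
    ``conservative=True`` the (b+1)/(B+1) variant is returned instead.
    """
    perm = _as_1d(permuted, "permuted")
    if perm.size == 0:
        raise ValueError("permuted vector is empty")
    b = int((perm > observed).sum())
    if conservative:
        return (b + 1) / (perm.size + 1)
    return b / perm.size


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = _as_1d(pvals, "pvals")
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return np.asarray(sps.false_discovery_control(p, method="bh"))


def permutation_fdr(
    observed_p,
    permuted_p_pool,
    n_perms: int,
    threshold: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in FDR from a pooled permutation null, with monotonization.

    For each observed p value t,

        FDR(t) = min(1, (#{permuted <= t} / n_perms) / max(#{observed <= t}, 1))

    where the permuted pool concatenates the p values from ``n_perms``
    label permutations of the same test family. Raw values are then
    monotonized (q(t) = min over t' >= t of raw FDR) so the estimate is
    non-decreasing in t. Returns ``(fdr, significant)`` aligned with the
    input order; ``significant`` is ``fdr < threshold``.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    obs = _as_1d(observed_p, "observed_p")
    pool = np.sort(_as_1d(permuted_p_pool, "permuted_p_pool"))
    order = np.argsort(obs, kind="stable")
    obs_sorted = obs[order]
    n_perm_le = np.searchsorted(pool, obs_sorted, side="right") / n_perms
    n_obs_le = np.searchsorted(obs_sorted, obs_sorted, side="right")
    raw = np.minimum(1.0, n_perm_le / np.maximum(n_obs_le, 1))
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    fdr = np.empty_like(mono)
    fdr[order] = mono
    return fdr, fdr < threshold


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p value comes from the standard large-sample approximation.
    Raises on constant input, where the correlation is undefined.
    """
    xv = _as_1d(x, "x")
    yv = _as_1d(y, "y")
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise ValueError("undefined correlation: constant vector")
    rho, p = sps.spearmanr(xv, yv)
    return float(rho), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])
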