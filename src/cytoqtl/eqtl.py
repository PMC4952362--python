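"""Targeted cis-eQTL mapping with permutation FDR.

For every gene, SNPs inside the cis window (gene span plus a symmetric
radius, 100 kbp by default) passing the minor-allele-frequency floor are
scored against expression with a Gaussian-family Rao score test, adjusting
for covariates. The null for FDR estimation is built by permuting genotype
sample labels against the fixed expression/covariate pairs, so confounder
structure survives under the null. Downstream helpers extract the best SNP
per gene and cell type, compare effect sizes between sample subgroups, and
run exhaustive best-subset selection at multi-SNP loci.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GenotypeMatrix
from .stats import permutation_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "EqtlMapping",
    "define_cis_window",
    "map_cis_eqtls",
    "best_snp_per_gene",
    "subgroup_concordance",
    "exhaustive_selection",
    "selection_sizes",
]

_MAX_EXHAUSTIVE_SNPS = 10

EQTL_COLUMNS = ["gene_id", "snp_id", "cell_type", "chi2", "p", "fdr", "significant", "beta_all"]


@dataclass
class EqtlMapping:
    """Mapped eQTL table plus the genes skipped for lack of testable SNPs."""

    table: pd.DataFrame
    skipped_genes: list[str]
    n_perms: int
    fdr_threshold: float


def define_cis_window(gene: pd.Series, radius_bp: int) -> tuple[str, int, int]:
    """Cis window: gene span extended by ``radius_bp`` on both sides.

    Strand-ignored; the lower bound is clamped at position 1.
    """
    if radius_bp < 0:
        raise ValueError("radius must be non-negative")
    return (
        str(gene["chrom"]),
        max(1, int(gene["start_bp"]) - radius_bp),
        int(gene["end_bp"]) + radius_bp,
    )


def _design(covars: pd.DataFrame | None, samples: list[str]) -> np.ndarray:
    if covars is None or covars.shape[1] == 0:
        return np.ones((len(samples), 1))
    X = covars.loc[samples].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(samples)), X])


def map_cis_eqtls(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covars: pd.DataFrame | None,
    genes: pd.DataFrame,
    cis_radius_bp: int = 100_000,
    maf_min: float = 0.05,
    fdr_threshold: float = 0.10,
    n_perms: int = 320,
    seed: int = 0,
) -> EqtlMapping:
    """Score every cis SNP of every annotated gene in one cell type.

    Samples are the intersection of expression, genotype and covariate
    tables (at least 20 required). MAF is computed on the analysed samples;
    SNPs below ``maf_min`` are excluded. Samples with a missing dosage at
    any cis SNP of a gene are dropped for that gene. FDR is the pooled
    permutation estimate across all (gene, SNP) rows of the cell type.
    """
    shared = [s for s in expr.samples if s in geno.dosages.index]
    if covars is not None:
        shared = [s for s in shared if s in covars.index]
    if len(shared) < 20:
        raise ValueError(f"only {len(shared)} shared samples; need >= 20")
    geno_s = geno.subset_samples(shared)
    rng = np.random.default_rng(seed)

    # assemble per-gene test units: (gene, sample mask, cis SNP ids)
    skipped: list[str] = []
    units: list[tuple[str, np.ndarray, list[str]]] = []
    for gene_id, gene_row in genes.iterrows():
        if gene_id not in expr.values.columns:
            skipped.append(gene_id)
            continue
        chrom, lo, hi = define_cis_window(gene_row, cis_radius_bp)
        cis = geno_s.snps_in_window(chrom, lo, hi)
        if not cis:
            skipped.append(gene_id)
            continue
        dos = geno_s.dosages[cis].to_numpy(dtype=float)
        mask = ~np.isnan(dos).any(axis=1)
        if mask.sum() < 20:
            skipped.append(gene_id)
            continue
        sub = dos[mask]
        p_alt = sub.mean(axis=0) / 2.0
        maf = np.minimum(p_alt, 1.0 - p_alt)
        keep = maf >= maf_min
        cis_kept = [s for s, k in zip(cis, keep) if k]
        if not cis_kept:
            skipped.append(gene_id)
            continue
        units.append((gene_id, mask, cis_kept))

    if not units:
        return EqtlMapping(
            table=pd.DataFrame(columns=EQTL_COLUMNS),
            skipped_genes=skipped,
            n_perms=n_perms,
            fdr_threshold=fdr_threshold,
        )

    # group genes sharing an analysis-sample mask so the permutation stream
    # and projections vectorize across the whole group
    groups: dict[bytes, list[int]] = {}
    for i, (_, mask, _) in enumerate(units):
        groups.setdefault(mask.tobytes(), []).append(i)

    obs_rows: list[pd.DataFrame] = []
    perm_p_chunks: list[np.ndarray] = []
    for unit_idx in groups.values():
        gene_ids = [units[i][0] for i in unit_idx]
        mask = units[unit_idx[0]][1]
        samples_g = [s for s, m in zip(shared, mask) if m]
        snp_ids = sorted({s for i in unit_idx for s in units[i][2]})
        snp_pos = {s: j for j, s in enumerate(snp_ids)}
        pair_gene, pair_snp, pair_gene_id, pair_snp_id = [], [], [], []
        for gi, i in enumerate(unit_idx):
            for s in units[i][2]:
                pair_gene.append(gi)
                pair_snp.append(snp_pos[s])
                pair_gene_id.append(gene_ids[gi])
                pair_snp_id.append(s)
        pg = np.array(pair_gene)
        ps = np.array(pair_snp)

        n = len(samples_g)
        X = _design(covars, samples_g)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        Q, _ = np.linalg.qr(X)
        Y = expr.values.loc[samples_g, gene_ids].to_numpy(dtype=float)
        E = Y - Q @ (Q.T @ Y)
        sigma0 = (E * E).sum(axis=0) / n
        G = geno_s.dosages.loc[samples_g, snp_ids].to_numpy(dtype=float)

        def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            MG = Gm - Q @ (Q.T @ Gm)
            gmg = (Gm * MG).sum(axis=0)
            lin = (E[:, pg] * Gm[:, ps]).sum(axis=0)
            den = sigma0[pg] * gmg[ps]
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.where(den > 0, lin**2 / den, 0.0)
                beta = np.where(gmg[ps] > 0, lin / gmg[ps], np.nan)
            return chi2, beta

        chi2_obs, beta_obs = stats_for(G)
        obs_rows.append(
            pd.DataFrame(
                {
                    "gene_id": pair_gene_id,
                    "snp_id": pair_snp_id,
                    "chi2": chi2_obs,
                    "beta_all": beta_obs,
                }
            )
        )
        perm_p = np.empty((n_perms, len(pg)))
        for b in range(n_perms):
            idx = rng.permutation(n)
            chi2_b, _ = stats_for(G[idx])
            perm_p[b] = sps.chi2.sf(chi2_b, df=1)
        perm_p_chunks.append(perm_p.ravel())

    table = pd.concat(obs_rows, ignore_index=True)
    table["cell_type"] = expr.cell_type
    table["p"] = sps.chi2.sf(table["chi2"].to_numpy(), df=1)
    pool = np.concatenate(perm_p_chunks)
    fdr, signif = permutation_fdr(
        table["p"].to_numpy(), pool, n_perms=n_perms, threshold=fdr_threshold
    )
    table["fdr"] = fdr
    table["significant"] = signif
    table = table[EQTL_COLUMNS].sort_values(["gene_id", "snp_id"]).reset_index(drop=True)
    if skipped:
        logger.info("cell type %s: skipped genes %s", expr.cell_type, skipped)
    return EqtlMapping(
        table=table, skipped_genes=skipped, n_perms=n_perms, fdr_threshold=fdr_threshold
    )


def best_snp_per_gene(
    table: pd.DataFrame, fdr_floor: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best (most significant) SNP per gene and cell type.

    Ties on p are broken by larger chi2, then lexicographically smaller
    SNP id. Also returns the gene x cell-type matrix of -log10(FDR) for
    the best SNPs; FDR values of exactly 0 are floored at ``fdr_floor``
    (default: the smallest positive FDR in the table, or 1e-6).
    """
    if table.empty:
        raise ValueError("empty eQTL table")
    ordered = table.sort_values(
        ["gene_id", "cell_type", "p", "chi2", "snp_id"],
        ascending=[True, True, True, False, True],
        kind="stable",
    )
    best = ordered.groupby(["gene_id", "cell_type"], as_index=False).first()
    if fdr_floor is None:
        pos = table.loc[table["fdr"] > 0, "fdr"]
        fdr_floor = float(pos.min()) if len(pos) else 1e-6
    matrix = best.pivot(index="gene_id", columns="cell_type", values="fdr")
    matrix = -np.log10(matrix.clip(lower=fdr_floor))
    return best, matrix


def subgroup_concordance(
    table: pd.DataFrame,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covars: pd.DataFrame,
    group_label: str = "status",
) -> pd.DataFrame:
    """Per-group OLS slopes of expression on dosage for significant eQTLs.

    For each significant row of ``table`` (in this expression matrix's cell
    type), expression is regressed on dosage within each level of
    ``group_label`` separately, keeping the remaining covariates. Returns
    one row per eQTL per group with the slope and its standard error;
    monomorphic-within-group SNPs are reported with a reason instead.
    Both groups need at least 10 samples.
    """
    if group_label not in covars.columns:
        raise KeyError(f"covariates lack group column {group_label!r}")
    rows = []
    other_cov = covars.drop(columns=[group_label])
    sig = table[(table["significant"]) & (table["cell_type"] == expr.cell_type)]
    shared = [s for s in expr.samples if s in geno.dosages.index and s in covars.index]
    levels = sorted(covars.loc[shared, group_label].unique())
    for level in levels:
        members = [s for s in shared if covars.at[s, group_label] == level]
        if len(members) < 10:
            raise ValueError(f"group {group_label}={level} has fewer than 10 samples")
    for _, r in sig.iterrows():
        for level in levels:
            members = [s for s in shared if covars.at[s, group_label] == level]
            y = expr.values.loc[members, r["gene_id"]].to_numpy(dtype=float)
            g = geno.dosages.loc[members, r["snp_id"]].to_numpy(dtype=float)
            keep = ~np.isnan(g)
            y, g = y[keep], g[keep]
            sub_cov = other_cov.loc[members].to_numpy(dtype=float)[keep]
            rec = {
                "gene_id": r["gene_id"],
                "snp_id": r["snp_id"],
                "cell_type": r["cell_type"],
                "group": level,
            }
            if np.unique(g).size < 2:
                rec.update(beta=np.nan, se=np.nan, reason="monomorphic in group")
            else:
                beta, se = _ols_slope(y, g, sub_cov)
                rec.update(beta=beta, se=se, reason="")
            rows.append(rec)
    return pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "cell_type", "group", "beta", "se", "reason"]
    )


def _ols_slope(y: np.ndarray, g: np.ndarray, covs: np.ndarray) -> tuple[float, float]:
    """Slope of y on g adjusting for covariates, with its standard error."""
    X = np.column_stack([np.ones(y.size), g, covs])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = y.size - rank
    if dof <= 0:
        return float(coef[1]), np.nan
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    return float(coef[1]), float(np.sqrt(sigma2 * xtx_inv[1, 1]))


def exhaustive_selection(
    expr_gene,
    candidate_snps: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    criterion: str = "bic",
) -> list[str]:
    """Best-subset search over candidate SNPs by information criterion.

    Evaluates all 2^k subsets of the candidate dosage columns (k <= 10) in
    a Gaussian linear model that always retains the covariates, and returns
    the subset minimizing the criterion (BIC by default; "aic" and
    "adjr2" available). Ties go to the smaller subset, then to the
    lexicographically smaller id tuple. The empty subset (covariate-only
    model) is a legal winner.
    """
    y = np.asarray(expr_gene, dtype=float)
    k = candidate_snps.shape[1]
    if k > _MAX_EXHAUSTIVE_SNPS:
        raise ValueError(
            f"exhaustive search bound exceeded: {k} > {_MAX_EXHAUSTIVE_SNPS} SNPs"
        )
    n = y.size
    C = _design(covars, list(candidate_snps.index)) if covars is not None else np.ones((n, 1))
    ids = list(candidate_snps.columns)
    G = candidate_snps.to_numpy(dtype=float)

    def score(subset: tuple[int, ...]) -> float:
        X = np.column_stack([C] + [G[:, [j]] for j in subset]) if subset else C
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = max(float(np.sum((y - X @ coef) ** 2)), 1e-300)
        p = X.shape[1]
        if criterion == "bic":
            return n * np.log(rss / n) + p * np.log(n)
        if criterion == "aic":
            return n * np.log(rss / n) + 2 * p
        if criterion == "adjr2":
            tss = float(np.sum((y - y.mean()) ** 2))
            if n - p <= 0:
                return np.inf
            return (rss / (n - p)) / (tss / (n - 1))  # minimize 1 - adjusted R^2
        raise ValueError(f"unknown criterion {criterion!r}")

    results = []
    for r in range(k + 1):
        for subset in itertools.combinations(range(k), r):
            results.append((score(subset), subset))
    best_score = min(s for s, _ in results)
    tol = 1e-9 * (1.0 + abs(best_score))
    tied = [sub for s, sub in results if s <= best_score + tol]
    winner = min(tied, key=lambda sub: (len(sub), tuple(sorted(ids[j] for j in sub))))
    return sorted(ids[j] for j in winner)


def selection_sizes(
    table: pd.DataFrame,
    expr_by_celltype: dict[str, ExpressionMatrix],
    geno: GenotypeMatrix,
    covars: pd.DataFrame | None,
    criterion: str = "bic",
) -> pd.DataFrame:
    """Model size after best-subset selection per (gene, cell type).

    Genes with a single significant SNP trivially select it. Loci with more
    than 10 significant SNPs are reduced to the 10 most significant before
    the exhaustive search (documented search bound).
    """
    rows = []
    sig = table[table["significant"]]
    for (gene_id, cell_type), grp in sig.groupby(["gene_id", "cell_type"]):
        expr = expr_by_celltype[cell_type]
        snps = sorted(grp.sort_values("p")["snp_id"].head(_MAX_EXHAUSTIVE_SNPS))
        if len(snps) == 1:
            selected = snps
        else:
            shared = [
                s for s in expr.samples if s in geno.dosages.index
                and (covars is None or s in covars.index)
            ]
            cand = geno.dosages.loc[shared, snps]
            complete = ~cand.isna().any(axis=1)
            cand = cand[complete]
            y = expr.values.loc[cand.index, gene_id]
            cov = covars.loc[cand.index] if covars is not None else None
            selected = exhaustive_selection(y, cand, cov, criterion=criterion)
        rows.append(
            {
                "gene_id": gene_id,
                "cell_type": cell_type,
                "n_significant": len(grp),
                "n_selected": len(selected),
                "selected_snps": ",".join(selected),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "cell_type", "n_significant", "n_selected", "selected_snps"]
    )
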