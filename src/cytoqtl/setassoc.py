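"""eQTL SNP-set construction and self-contained disease association testing.

The SNP set tags the best significant cis-eQTL SNP of each gene/cell type
at LD r^2 >= 0.8, keeps only proxies genotyped in the target cohort, drops
genes overlapping the MHC (whose long-range LD with strong disease
associations would confound the set), and prunes the remainder for relative
independence (multiple correlation <= 0.33). Association is measured by the
sum of allelic chi-squared statistics over the set compared with sums from
phenotype-permuted data (a self-contained test), together with
genomic-control inflation factors for the set and the genome-wide
background, the latter rescaled to a 1000-case/1000-control cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CaseControlCohort, GenotypeMatrix
from . import ld
from .stats import (
    allelic_chi2_counts,
    empirical_p,
    bh_adjust,
    genomic_inflation,
    lambda_1000,
    fisher_exact_2x2,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SnpSet",
    "SetAssocResult",
    "build_snp_set",
    "set_association",
    "gene_level_association",
    "classify_effect_direction",
    "catalog_enrichment",
    "qq_coordinates",
]

DEFAULT_MHC_REGION = ("chr6", 25_000_000, 34_000_000)


@dataclass
class SnpSet:
    """Independence-filtered SNP identifiers with per-SNP gene provenance."""

    members: list[str]
    provenance: pd.DataFrame  # member, source_gene, source_cell_type, index_snp, r2
    filter_audit: pd.DataFrame  # snp_id, order, multiple_R, retained

    def genes(self) -> list[str]:
        return sorted(self.provenance["source_gene"].unique())


@dataclass
class SetAssocResult:
    """Summed chi-squared test of one SNP set against one cohort."""

    sum_chi2: float
    n_perms: int
    empirical_p: float
    lambda_set: float
    lambda_genome: float
    lambda_1000_set: float
    n_cases: int
    n_controls: int
    seed: int
    n_snps_used: int
    dropped_snps: list[str] = field(default_factory=list)
    perm_sums: np.ndarray | None = None

    @property
    def p_string(self) -> str:
        """Reported p value; a raw fraction of 0 becomes '<1/n_perms'."""
        if self.empirical_p == 0.0:
            return f"<{1.0 / self.n_perms:g}"
        return f"{self.empirical_p:g}"


def _gene_overlaps_region(
    gene: pd.Series, region: tuple[str, int, int]
) -> bool:
    chrom, lo, hi = region
    return (
        str(gene["chrom"]) == str(chrom)
        and int(gene["start_bp"]) <= int(hi)
        and int(gene["end_bp"]) >= int(lo)
    )


def build_snp_set(
    best_eqtls: pd.DataFrame,
    ld_panel: GenotypeMatrix,
    cohort_snps: list[str],
    genes: pd.DataFrame,
    r2_tag_min: float = 0.8,
    max_multiple_corr: float = 0.33,
    mhc_region: tuple[str, int, int] = DEFAULT_MHC_REGION,
    tag_window_bp: int = 1_000_000,
) -> SnpSet:
    """Tag, intersect, MHC-exclude and independence-filter the eQTL SNPs.

    ``best_eqtls`` must hold significant best-eQTL rows (gene_id, snp_id,
    cell_type, p). Proxies are found in the LD panel at r^2 >= ``r2_tag_min``,
    intersected with the cohort's genotyped SNPs, stripped of genes
    overlapping ``mhc_region`` and finally pruned greedily (ordered by index
    eQTL significance) at multiple correlation <= ``max_multiple_corr``.
    Duplicate proxies across genes enter the set once but keep every
    provenance row.
    """
    if best_eqtls.empty:
        raise ValueError("no testable SNPs: empty best-eQTL input")
    cohort = set(cohort_snps)

    non_mhc = best_eqtls[
        [
            not _gene_overlaps_region(genes.loc[g], mhc_region)
            for g in best_eqtls["gene_id"]
        ]
    ]
    if non_mhc.empty:
        raise ValueError("no testable SNPs: all source genes overlap the MHC region")

    prov_rows = []
    for _, row in non_mhc.sort_values(["p", "snp_id"]).iterrows():
        try:
            tags = ld.tag_snps(row["snp_id"], ld_panel, r2_min=r2_tag_min,
                               window_bp=tag_window_bp)
        except (KeyError, ValueError) as exc:
            logger.info("index SNP %s not taggable: %s", row["snp_id"], exc)
            continue
        for proxy, r2 in tags.proxies.items():
            if proxy not in cohort:
                continue
            prov_rows.append(
                {
                    "member": proxy,
                    "source_gene": row["gene_id"],
                    "source_cell_type": row["cell_type"],
                    "index_snp": row["snp_id"],
                    "r2": r2,
                    "index_p": row["p"],
                }
            )
    if not prov_rows:
        raise ValueError(
            "no testable SNPs: cohort-chip intersection removed every proxy"
        )
    provenance = pd.DataFrame(prov_rows)

    # candidate order: ascending index-eQTL p (descending significance),
    # duplicates keep their most significant provenance for ordering
    order = (
        provenance.groupby("member")["index_p"].min().sort_values(kind="stable")
    )
    candidates = sorted(order.index, key=lambda m: (order[m], m))
    panel_snps = [s for s in candidates if s in ld_panel.snps.index]
    audit = ld.independence_filter(panel_snps, ld_panel, max_R=max_multiple_corr)
    members = ld.retained_ids(audit)
    if not members:
        raise ValueError("no testable SNPs: independence filter removed all proxies")
    provenance = provenance[provenance["member"].isin(members)].reset_index(drop=True)
    return SnpSet(members=members, provenance=provenance, filter_audit=audit)


def _allele_chi2_matrix(
    dosages: np.ndarray, status: np.ndarray
) -> np.ndarray:
    """Allelic chi2 per SNP column for one 0/1 status vector."""
    n_case = int(status.sum())
    n_ctrl = status.size - n_case
    alt_case = status @ dosages
    alt_all = dosages.sum(axis=0)
    alt_ctrl = alt_all - alt_case
    return allelic_chi2_counts(
        2.0 * n_case - alt_case, alt_case, 2.0 * n_ctrl - alt_ctrl, alt_ctrl
    )


def _permuted_chi2_sums(
    dosages: np.ndarray, status: np.ndarray, n_perms: int, rng: np.random.Generator
) -> np.ndarray:
    """Sum of per-SNP allelic chi2 under ``n_perms`` phenotype permutations."""
    sums = np.empty(n_perms)
    for b in range(n_perms):
        perm = rng.permutation(status)
        sums[b] = np.nansum(_allele_chi2_matrix(dosages, perm))
    return sums


def _usable_set_columns(
    cohort: CaseControlCohort, members: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    present = [m for m in members if m in cohort.genotypes.snps.index]
    dos = cohort.genotypes.dosages[present].to_numpy(dtype=float)
    alt = np.nansum(dos, axis=0)
    total = 2.0 * (~np.isnan(dos)).sum(axis=0)
    ok = (alt > 0) & (alt < total)
    dropped = [s for s, k in zip(present, ok) if not k] + [
        m for m in members if m not in cohort.genotypes.snps.index
    ]
    used = [s for s, k in zip(present, ok) if k]
    return dos[:, ok], used, dropped


def set_association(
    snp_set: SnpSet,
    cohort: CaseControlCohort,
    n_perms: int = 10_000,
    seed: int = 0,
    genome_max_R: float = 0.33,
    keep_perm_sums: bool = False,
) -> SetAssocResult:
    """Self-contained sum-of-chi-squared association of the set with disease.

    Per-SNP allelic chi2 values over the set are summed; case/control labels
    are then permuted ``n_perms`` times (genotypes untouched, preserving LD)
    and the observed sum is compared with the permuted sums for an empirical
    p. Inflation factors: lambda over the set's chi2 values, lambda over the
    position-ordered independence-filtered genome-wide SNPs, and the set
    lambda rescaled to 1000 cases / 1000 controls. SNPs with a zero
    allele-count margin are dropped with a log entry.
    """
    if cohort.n_cases < 1 or cohort.n_controls < 1:
        raise ValueError("cohort needs at least one case and one control")
    if not snp_set.members:
        raise ValueError("empty SNP set")
    dosages, used, dropped = _usable_set_columns(cohort, snp_set.members)
    if dropped:
        logger.info("set_association: dropped SNPs %s", dropped)
    if not used:
        raise ValueError("no usable SNPs after margin checks")
    status = cohort.status.to_numpy(dtype=float)

    chi2_obs = _allele_chi2_matrix(dosages, status)
    sum_obs = float(np.nansum(chi2_obs))
    rng = np.random.default_rng(seed)
    perm_sums = _permuted_chi2_sums(dosages, status, n_perms, rng)
    emp_p = empirical_p(sum_obs, perm_sums)

    lam_set = genomic_inflation(chi2_obs[~np.isnan(chi2_obs)])
    lam_genome = genome_wide_lambda(cohort, max_R=genome_max_R)
    lam_1000 = lambda_1000(lam_set, cohort.n_cases, cohort.n_controls)
    return SetAssocResult(
        sum_chi2=sum_obs,
        n_perms=n_perms,
        empirical_p=emp_p,
        lambda_set=lam_set,
        lambda_genome=lam_genome,
        lambda_1000_set=lam_1000,
        n_cases=cohort.n_cases,
        n_controls=cohort.n_controls,
        seed=seed,
        n_snps_used=len(used),
        dropped_snps=dropped,
        perm_sums=perm_sums if keep_perm_sums else None,
    )


def genome_wide_lambda(cohort: CaseControlCohort, max_R: float = 0.33) -> float:
    """Inflation factor over the cohort's independence-filtered SNPs.

    Candidates are ordered by genomic position (not significance, which
    would bias the background median upward), pruned at multiple
    correlation <= ``max_R``, and their allelic chi2 values summarized by
    the median-based genomic-control estimator.
    """
    snps = cohort.genotypes.snps.sort_values(["chrom", "pos"])
    dos_all = cohort.genotypes.dosages[list(snps.index)].to_numpy(dtype=float)
    alt = np.nansum(dos_all, axis=0)
    total = 2.0 * (~np.isnan(dos_all)).sum(axis=0)
    poly = (alt > 0) & (alt < total)
    candidates = [s for s, k in zip(snps.index, poly) if k]
    audit = ld.independence_filter(candidates, cohort.genotypes, max_R=max_R)
    kept = ld.retained_ids(audit)
    dos = cohort.genotypes.dosages[kept].to_numpy(dtype=float)
    chi2 = _allele_chi2_matrix(dos, cohort.status.to_numpy(dtype=float))
    return genomic_inflation(chi2[~np.isnan(chi2)])


def gene_level_association(
    snp_set: SnpSet,
    cohort: CaseControlCohort,
    n_perms: int = 10_000,
    seed: int = 0,
    max_multiple_corr: float = 0.33,
) -> pd.DataFrame:
    """Per-gene sum-of-chi-squared association with a shared permutation null.

    Each source gene's proxies are independently pruned at multiple
    correlation <= ``max_multiple_corr``; one stream of phenotype
    permutations is shared by all genes (a single permuted dataset serves
    every gene), and gene-level empirical p values are Benjamini-Hochberg
    adjusted across genes. Genes with no surviving SNPs appear with a
    ``reason`` and NaN statistics.
    """
    rng = np.random.default_rng(seed)
    status = cohort.status.to_numpy(dtype=float)
    # gene -> usable, pruned dosage columns
    gene_cols: dict[str, tuple[np.ndarray, list[str]]] = {}
    reasons: dict[str, str] = {}
    for gene, grp in snp_set.provenance.groupby("source_gene"):
        members = sorted(
            grp["member"].unique(),
            key=lambda m: (grp.loc[grp["member"] == m, "index_p"].min(), m),
        )
        dos, used, dropped = _usable_set_columns(cohort, members)
        if not used:
            reasons[gene] = "no genotyped polymorphic proxies in cohort"
            continue
        sub = cohort.genotypes.subset_snps(used)
        audit = ld.independence_filter(used, sub, max_R=max_multiple_corr)
        kept = ld.retained_ids(audit)
        if not kept:
            reasons[gene] = "independence filter removed all proxies"
            continue
        gene_cols[gene] = (
            cohort.genotypes.dosages[kept].to_numpy(dtype=float),
            kept,
        )

    genes_tested = sorted(gene_cols)
    obs_sums = {
        g: float(np.nansum(_allele_chi2_matrix(gene_cols[g][0], status)))
        for g in genes_tested
    }
    perm_sums = {g: np.empty(n_perms) for g in genes_tested}
    for b in range(n_perms):
        perm = rng.permutation(status)
        for g in genes_tested:
            perm_sums[g][b] = np.nansum(_allele_chi2_matrix(gene_cols[g][0], perm))

    rows = []
    for g in genes_tested:
        rows.append(
            {
                "gene_id": g,
                "n_snps": len(gene_cols[g][1]),
                "sum_chi2": obs_sums[g],
                "empirical_p": empirical_p(obs_sums[g], perm_sums[g]),
                "reason": "",
            }
        )
    if rows:
        adj = bh_adjust([r["empirical_p"] for r in rows])
        for r, a in zip(rows, adj):
            r["bh_adjusted_p"] = float(a)
    for g, reason in sorted(reasons.items()):
        rows.append(
            {
                "gene_id": g,
                "n_snps": 0,
                "sum_chi2": np.nan,
                "empirical_p": np.nan,
                "bh_adjusted_p": np.nan,
                "reason": reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_snps", "sum_chi2", "empirical_p", "bh_adjusted_p", "reason"],
    ).sort_values("gene_id").reset_index(drop=True)


def classify_effect_direction(eqtl_beta: float, risk_allele: str) -> str:
    """Direction of the risk allele's effect on expression.

    ``eqtl_beta`` is the expression slope per ALT allele; ``risk_allele``
    says whether REF or ALT is the disease risk allele. Invariant under
    simultaneously relabelling the alleles and flipping the slope's sign.
    """
    if eqtl_beta == 0 or np.isnan(eqtl_beta):
        raise ValueError("no direction: beta is zero or undefined")
    if risk_allele not in ("REF", "ALT"):
        raise ValueError("risk_allele must be 'REF' or 'ALT'")
    oriented = eqtl_beta if risk_allele == "ALT" else -eqtl_beta
    return "risk-increases-expression" if oriented > 0 else "risk-decreases-expression"


def catalog_enrichment(
    set_genes_with_hits: int,
    set_genes_total: int,
    background_with_hits: int,
    background_total: int,
) -> tuple[float, float]:
    """Fisher's exact test of catalog-hit enrichment; returns (p, odds ratio)."""
    if not (0 <= set_genes_with_hits <= set_genes_total):
        raise ValueError("inconsistent set counts")
    if not (0 <= background_with_hits <= background_total):
        raise ValueError("inconsistent background counts")
    table = np.array(
        [
            [set_genes_with_hits, set_genes_total - set_genes_with_hits],
            [background_with_hits, background_total - background_with_hits],
        ]
    )
    p = fisher_exact_2x2(table)
    odds = sps.contingency.odds_ratio(table, kind="sample").statistic
    return p, float(odds)


def qq_coordinates(chi2_values) -> pd.DataFrame:
    """Observed vs expected chi2_1 quantiles at probabilities (i - 0.5) / n."""
    obs = np.sort(np.asarray(chi2_values, dtype=float))
    n = obs.size
    expected = sps.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=1)
    return pd.DataFrame({"expected_chi2": expected, "observed_chi2": obs})
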