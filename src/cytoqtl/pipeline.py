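"""Stage orchestration: simulate -> eqtl -> select -> setassoc -> chromatin.

Every stochastic step draws its seed deterministically from the single
configured seed via fixed offsets, so a re-run of the same configuration
reproduces byte-identical result tables. Each stage reads only files
written by earlier stages (or supplied externally) and fails early, naming
the missing artifact, when a dependency is absent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin as chrom_mod
from . import eqtl as eqtl_mod
from . import io as io_mod
from . import ld as ld_mod
from . import setassoc as set_mod
from . import synthdata as synth_mod
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]

# fixed per-stage seed offsets (independent streams from one global seed)
_SEED_OFFSETS = {"simulate": 11, "eqtl": 211, "select": 409, "setassoc": 613, "chromatin": 811}


class PipelineError(RuntimeError):
    pass


def _stage_seed(config: RunConfig, stage: str, extra: int = 0) -> int:
    return (config.seed + _SEED_OFFSETS[stage] + extra) % (2**31 - 1)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path} (produced by the '{producer}' stage)"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "maf_min": config.maf_min,
            "eqtl_fdr_threshold": config.eqtl_fdr_threshold,
            "r2_tag_min": config.r2_tag_min,
            "max_multiple_corr": config.max_multiple_corr,
            "cis_radius_bp": config.cis_radius_bp,
        },
        "stages": {},
    }
    runners = {
        "simulate": _run_simulate,
        "eqtl": _run_eqtl,
        "select": _run_select,
        "setassoc": _run_setassoc,
        "chromatin": _run_chromatin,
    }
    for stage in config.stages:
        report["stages"][stage] = runners[stage](config)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _run_simulate(config: RunConfig) -> dict:
    sc = config.scenario
    seed = _stage_seed(config, "simulate")
    geno = synth_mod.simulate_genotypes(sc, seed)
    io_mod.write_genotypes_vcf(geno, config.resolve("genotypes_vcf"))
    covars = synth_mod.simulate_covariates(sc.n_samples, seed + 1)
    covars.to_csv(config.resolve("covariates_tsv"), sep="\t")
    genes = synth_mod.gene_annotations(sc)
    io_mod.write_genes_bed(genes, config.resolve("genes_bed"))
    for i, ct in enumerate(sc.cell_types):
        expr = synth_mod.simulate_expression(geno, covars, sc, ct, seed + 10 + i)
        io_mod.write_expression_tsv(expr, config.resolve("expression_tsv_pattern", cell_type=ct))
    pool = synth_mod.simulate_genotypes(sc, seed + 100)
    cohort = synth_mod.simulate_case_control(pool, sc, seed + 101)
    io_mod.write_genotypes_vcf(cohort.genotypes, config.resolve("cohort_vcf"))
    io_mod.write_phenotypes_tsv(cohort.status, config.resolve("phenotypes_tsv"))
    track = synth_mod.simulate_coverage(geno.snps, sc, seed + 102)
    io_mod.write_coverage_bed(track, config.resolve("coverage_bed"))
    manifest = pd.DataFrame(
        [
            {"kind": "eqtl", "gene": g, "snp": s, "cell_type": ct, "value": b}
            for g, s, ct, b in sc.eqtl_map
        ]
        + [
            {"kind": "disease", "gene": "", "snp": s, "cell_type": "", "value": orr}
            for s, orr in sc.disease_snps
        ]
        + [
            {"kind": "peak", "gene": "", "snp": s, "cell_type": "", "value": 1.0}
            for s in sc.peak_snps
        ]
    )
    io_mod.write_table_tsv(manifest, config.resolve("manifest_tsv"))
    return {
        "seed": seed,
        "n_samples": sc.n_samples,
        "n_genes": sc.n_genes,
        "n_snps": geno.n_snps,
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "coverage_reads": track.total_mapped_reads,
    }


def _inputs_for_eqtl(config: RunConfig):
    geno = io_mod.load_genotypes_vcf(_require(config.resolve("genotypes_vcf"), "simulate"))
    covars = io_mod.load_covariates_tsv(_require(config.resolve("covariates_tsv"), "simulate"))
    genes = io_mod.load_genes_bed(_require(config.resolve("genes_bed"), "simulate"))
    return geno, covars, genes


def _run_eqtl(config: RunConfig) -> dict:
    geno, covars, genes = _inputs_for_eqtl(config)
    out = Path(config.out_dir)
    tables, expr_by_ct = [], {}
    info: dict = {"cell_types": {}, "n_perms": config.n_perms_eqtl}
    for i, ct in enumerate(config.scenario.cell_types):
        path = _require(config.resolve("expression_tsv_pattern", cell_type=ct), "simulate")
        expr = io_mod.load_expression_tsv(path, ct)
        expr_by_ct[ct] = expr
        mapping = eqtl_mod.map_cis_eqtls(
            expr,
            geno,
            covars,
            genes,
            cis_radius_bp=config.cis_radius_bp,
            maf_min=config.maf_min,
            fdr_threshold=config.eqtl_fdr_threshold,
            n_perms=config.n_perms_eqtl,
            seed=_stage_seed(config, "eqtl", extra=i),
        )
        io_mod.write_table_tsv(mapping.table, out / f"eqtl_{ct}.tsv")
        tables.append(mapping.table)
        info["cell_types"][ct] = {
            "n_rows": int(len(mapping.table)),
            "n_significant": int(mapping.table["significant"].sum()),
            "skipped_genes": mapping.skipped_genes,
        }
    combined = pd.concat(tables, ignore_index=True)
    io_mod.write_table_tsv(combined, out / "eqtl_all.tsv")
    best, matrix = eqtl_mod.best_snp_per_gene(
        combined, fdr_floor=1.0 / config.n_perms_eqtl
    )
    io_mod.write_table_tsv(best, out / "best_eqtls.tsv")
    matrix.to_csv(out / "best_eqtl_matrix.tsv", sep="\t", float_format="%.10g")
    sizes = eqtl_mod.selection_sizes(combined, expr_by_ct, geno, covars)
    io_mod.write_table_tsv(sizes, out / "selection_sizes.tsv")
    conc = []
    for ct in config.scenario.cell_types:
        conc.append(
            eqtl_mod.subgroup_concordance(combined, expr_by_ct[ct], geno, covars, "status")
        )
    io_mod.write_table_tsv(pd.concat(conc, ignore_index=True), out / "concordance.tsv")
    info["n_significant_total"] = int(combined["significant"].sum())
    info["n_genes_with_eqtl"] = int(
        combined.loc[combined["significant"], "gene_id"].nunique()
    )
    return info


def _run_select(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    best = pd.read_csv(_require(out / "best_eqtls.tsv", "eqtl"), sep="\t")
    geno = io_mod.load_genotypes_vcf(_require(config.resolve("genotypes_vcf"), "simulate"))
    genes = io_mod.load_genes_bed(_require(config.resolve("genes_bed"), "simulate"))
    cohort_geno = io_mod.load_genotypes_vcf(_require(config.resolve("cohort_vcf"), "simulate"))
    sig = best[best["significant"]]
    snp_set = set_mod.build_snp_set(
        sig,
        ld_panel=geno,
        cohort_snps=cohort_geno.snp_ids,
        genes=genes,
        r2_tag_min=config.r2_tag_min,
        max_multiple_corr=config.max_multiple_corr,
        mhc_region=config.mhc_region,
    )
    tag_rows = []
    for index_snp in sorted(sig["snp_id"].unique()):
        tags = ld_mod.tag_snps(index_snp, geno, r2_min=config.r2_tag_min)
        for proxy, r2 in tags.proxies.items():
            tag_rows.append({"index_snp": index_snp, "proxy_snp": proxy, "r2": r2})
    io_mod.write_table_tsv(pd.DataFrame(tag_rows), out / "tagsets.tsv")
    io_mod.write_table_tsv(snp_set.filter_audit, out / "independent_set.tsv")
    io_mod.write_table_tsv(snp_set.provenance, out / "snp_set.tsv")
    return {
        "n_index_snps": int(sig["snp_id"].nunique()),
        "n_members": len(snp_set.members),
        "n_genes": len(snp_set.genes()),
    }


def _load_snp_set(out: Path) -> set_mod.SnpSet:
    prov = pd.read_csv(_require(out / "snp_set.tsv", "select"), sep="\t")
    audit = pd.read_csv(_require(out / "independent_set.tsv", "select"), sep="\t")
    return set_mod.SnpSet(
        members=sorted(prov["member"].unique()), provenance=prov, filter_audit=audit
    )


def _run_setassoc(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    snp_set = _load_snp_set(out)
    cohort = io_mod.load_case_control(
        _require(config.resolve("cohort_vcf"), "simulate"),
        _require(config.resolve("phenotypes_tsv"), "simulate"),
    )
    seed = _stage_seed(config, "setassoc")
    res = set_mod.set_association(
        snp_set,
        cohort,
        n_perms=config.n_perms_set,
        seed=seed,
        genome_max_R=config.max_multiple_corr,
    )
    io_mod.write_table_tsv(
        pd.DataFrame(
            [
                {
                    "lambda_genome": res.lambda_genome,
                    "lambda_set": res.lambda_set,
                    "lambda_1000_set": res.lambda_1000_set,
                    "sum_chi2": res.sum_chi2,
                    "empirical_p": res.empirical_p,
                    "p_reported": res.p_string,
                    "n_perms": res.n_perms,
                    "n_snps": res.n_snps_used,
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                    "seed": res.seed,
                }
            ]
        ),
        out / "set_assoc.tsv",
    )
    gene_table = set_mod.gene_level_association(
        snp_set,
        cohort,
        n_perms=config.n_perms_set,
        seed=seed + 1,
        max_multiple_corr=config.max_multiple_corr,
    )
    io_mod.write_table_tsv(gene_table, out / "gene_assoc.tsv")

    # qq coordinates for the set and the thinned genome-wide background
    dos, used, _ = set_mod._usable_set_columns(cohort, snp_set.members)
    status = cohort.status.to_numpy(dtype=float)
    chi2_set = set_mod._allele_chi2_matrix(dos, status)
    io_mod.write_table_tsv(
        set_mod.qq_coordinates(chi2_set[~np.isnan(chi2_set)]), out / "qq_set.tsv"
    )
    snps_sorted = cohort.genotypes.snps.sort_values(["chrom", "pos"])
    audit = ld_mod.independence_filter(
        list(snps_sorted.index), cohort.genotypes, max_R=config.max_multiple_corr
    )
    kept = ld_mod.retained_ids(audit)
    chi2_gen = set_mod._allele_chi2_matrix(
        cohort.genotypes.dosages[kept].to_numpy(dtype=float), status
    )
    io_mod.write_table_tsv(
        set_mod.qq_coordinates(chi2_gen[~np.isnan(chi2_gen)]), out / "qq_genome.tsv"
    )

    directions = _effect_directions(out, cohort)
    io_mod.write_table_tsv(directions, out / "directions.tsv")
    return {
        "seed": seed,
        "lambda_set": res.lambda_set,
        "lambda_genome": res.lambda_genome,
        "lambda_1000_set": res.lambda_1000_set,
        "empirical_p": res.empirical_p,
        "n_genes_tested": int((gene_table["reason"] == "").sum()),
    }


def _effect_directions(out: Path, cohort) -> pd.DataFrame:
    """Classify each significant best eQTL by its risk allele's expression effect.

    The risk allele of a SNP is the allele at higher frequency in cases
    than in controls within this cohort.
    """
    best = pd.read_csv(_require(out / "best_eqtls.tsv", "eqtl"), sep="\t")
    sig = best[best["significant"]]
    status = cohort.status.to_numpy(dtype=float)
    rows = []
    for _, r in sig.iterrows():
        snp = r["snp_id"]
        if snp not in cohort.genotypes.snps.index or r["beta_all"] == 0:
            continue
        g = cohort.genotypes.dosages[snp].to_numpy(dtype=float)
        keep = ~np.isnan(g)
        f_case = g[keep & (status == 1)].mean() / 2
        f_ctrl = g[keep & (status == 0)].mean() / 2
        risk = "ALT" if f_case >= f_ctrl else "REF"
        rows.append(
            {
                "gene_id": r["gene_id"],
                "cell_type": r["cell_type"],
                "snp_id": snp,
                "beta_alt": r["beta_all"],
                "risk_allele": risk,
                "direction": set_mod.classify_effect_direction(r["beta_all"], risk),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "cell_type", "snp_id", "beta_alt", "risk_allele", "direction"],
    )
    # a SNP shared by several genes/cell types is counted once
    return df.drop_duplicates(subset="snp_id").reset_index(drop=True)


def _run_chromatin(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    track = io_mod.load_coverage_bed(_require(config.resolve("coverage_bed"), "simulate"))
    geno = io_mod.load_genotypes_vcf(_require(config.resolve("genotypes_vcf"), "simulate"))
    best = pd.read_csv(_require(out / "best_eqtls.tsv", "eqtl"), sep="\t")
    all_tested = pd.read_csv(_require(out / "eqtl_all.tsv", "eqtl"), sep="\t")
    seed = _stage_seed(config, "chromatin")

    pool_ids = sorted(all_tested["snp_id"].unique())
    pool = geno.snps.loc[pool_ids]
    cpm = chrom_mod.cpm_at_snps(track, pool)
    io_mod.write_table_tsv(
        cpm.rename_axis("snp_id").reset_index(), out / "cpm_per_snp.tsv"
    )

    sig_snps = sorted(best.loc[best["significant"], "snp_id"].unique())
    results = []
    if sig_snps:
        basic = chrom_mod.sampling_null_enrichment(
            sig_snps, pool, track, n_iter=config.n_iter_null, seed=seed
        )
        expanded = set()
        for snp in sig_snps:
            tags = ld_mod.tag_snps(snp, geno, r2_min=config.r2_tag_min)
            expanded.update(s for s in tags.proxy_snp_ids if s in pool.index)
        ld_exp = chrom_mod.sampling_null_enrichment(
            sorted(expanded), pool, track, n_iter=config.n_iter_null, seed=seed + 1
        )
        for name, r in (("eqtl", basic), ("ld_expanded", ld_exp)):
            results.append(
                {
                    "variant": name,
                    "observed_mean_cpm": r.observed_mean_cpm,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "empirical_p": r.empirical_p,
                    "n_iter": r.n_iter,
                    "n_snps": r.n_snps,
                    "seed": seed,
                }
            )
    io_mod.write_table_tsv(pd.DataFrame(results), out / "enrichment.tsv")

    # best SNP per gene regardless of significance, one cell type at a time
    corr_rows = []
    for ct, grp in best.groupby("cell_type"):
        if len(grp) < 3:
            continue
        try:
            rho, p = chrom_mod.strength_vs_acetylation(grp, geno.snps, track)
        except ValueError:
            continue
        corr_rows.append({"cell_type": ct, "rho": rho, "p": p})
    io_mod.write_table_tsv(pd.DataFrame(corr_rows), out / "acetyl_correlation.tsv")
    return {
        "seed": seed,
        "n_pool_snps": len(pool),
        "n_eqtl_snps": len(sig_snps),
        "enrichment_p": results[0]["empirical_p"] if results else None,
    }
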