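"""Readers and writers for the standard formats the pipeline exchanges.

Genotypes travel as VCF (read through cyvcf2), coverage as BED/bedGraph,
gene annotations as 4-column BED, and expression/covariate/phenotype tables
as TSV. Internal coordinates are 1-based inclusive; BED's 0-based half-open
intervals are converted on read and write.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import CaseControlCohort, CoverageTrack, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "load_genotypes_vcf",
    "write_genotypes_vcf",
    "load_coverage_bed",
    "write_coverage_bed",
    "load_genes_bed",
    "write_genes_bed",
    "load_expression_tsv",
    "write_expression_tsv",
    "load_covariates_tsv",
    "load_phenotypes_tsv",
    "write_phenotypes_tsv",
    "write_table_tsv",
    "load_case_control",
]

# cyvcf2 gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}
_SNP_ALLELES = {"A", "C", "G", "T"}


def load_genotypes_vcf(
    path: str | Path, sample_subset: list[str] | None = None
) -> GenotypeMatrix:
    """Read biallelic SNP dosages from a VCF.

    Dosage is the ALT-allele count per sample (0/1/2, NaN for missing
    calls). Multiallelic and non-SNP records are skipped with a logged
    count. Requesting absent samples raises with the missing ids listed.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises plain OSError on bad files
        raise ValueError(f"malformed VCF {path!r}: {exc}") from exc
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in all_samples]
        if missing:
            raise KeyError(f"requested samples absent from VCF: {missing}")
    keep_idx = (
        None
        if sample_subset is None
        else [all_samples.index(s) for s in sample_subset]
    )
    samples = all_samples if sample_subset is None else list(sample_subset)

    meta_rows, dosage_cols, n_skipped = [], [], 0
    seen = set()
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or var.ALT[0] not in _SNP_ALLELES:
            n_skipped += 1
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise ValueError(f"duplicate SNP id {snp_id!r} at record {i + 1}")
        seen.add(snp_id)
        gt = var.gt_types
        if keep_idx is not None:
            gt = gt[keep_idx]
        dosage_cols.append(
            np.array([_GT_TO_DOSAGE[int(t)] for t in gt], dtype=float)
        )
        meta_rows.append(
            {
                "snp_id": snp_id,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)
    if not meta_rows:
        raise ValueError(f"no usable biallelic SNP records in {path!r}")
    snps = pd.DataFrame(meta_rows).set_index("snp_id").sort_values(["chrom", "pos"])
    dosages = pd.DataFrame(
        np.column_stack(dosage_cols),
        index=samples,
        columns=pd.Index([r["snp_id"] for r in meta_rows], name="snp_id"),
    )
    return GenotypeMatrix(dosages=dosages, snps=snps)


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages back to VCF with unphased GT calls."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for snp_id, row in geno.snps.iterrows():
            col = geno.dosages[snp_id].to_numpy(dtype=float)
            calls = "\t".join(
                "./." if np.isnan(d) else gt_of[d] for d in col
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def load_coverage_bed(path: str | Path) -> CoverageTrack:
    """Read BED/bedGraph intervals with counts into a CoverageTrack.

    BED coordinates (0-based half-open) become 1-based inclusive
    internally. The track's total count is the sum of interval counts.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, count = parts[0], int(parts[1]), int(parts[2]), parts[3]
            count = int(float(count))
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            records.append((chrom, start + 1, end, count))
    return CoverageTrack.from_records(records)


def write_coverage_bed(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            starts, ends, counts = track.intervals[chrom]
            for s, e, c in zip(starts, ends, counts):
                fh.write(f"{chrom}\t{int(s) - 1}\t{int(e)}\t{int(c)}\n")


def load_genes_bed(path: str | Path) -> pd.DataFrame:
    """Gene annotations from 4-column BED: chrom, start, end, gene_id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
        comment="#",
    )
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start_bp": df["start0"] + 1,
            "end_bp": df["end"],
        }
    ).set_index("gene_id")
    if (out["start_bp"] > out["end_bp"]).any():
        raise ValueError("gene with start > end")
    return out


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, row in genes.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start_bp']) - 1}\t{int(row['end_bp'])}\t{gene_id}\n"
            )


def load_expression_tsv(path: str | Path, cell_type: str) -> ExpressionMatrix:
    """Expression TSV: genes as rows, sample ids as the header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df.T, cell_type=cell_type)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.T.to_csv(path, sep="\t", float_format="%.10g")


def load_covariates_tsv(path: str | Path) -> pd.DataFrame:
    """Covariate TSV: sample, status, sex, age, batch."""
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return df


def load_phenotypes_tsv(path: str | Path) -> pd.Series:
    """Phenotype TSV: sample, case (0/1)."""
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if "case" not in df.columns:
        raise ValueError("phenotype table needs a 'case' column")
    if not set(df["case"].unique()) <= {0, 1}:
        raise ValueError("case column must be 0/1")
    return df["case"]


def write_phenotypes_tsv(status: pd.Series, path: str | Path) -> None:
    out = status.rename("case").rename_axis("sample")
    out.to_csv(path, sep="\t")


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Result-table writer with fixed float formatting (determinism contract)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def load_case_control(
    vcf_path: str | Path, phenotype_path: str | Path
) -> CaseControlCohort:
    geno = load_genotypes_vcf(vcf_path)
    status = load_phenotypes_tsv(phenotype_path)
    missing = [s for s in geno.samples if s not in status.index]
    if missing:
        raise KeyError(f"samples without phenotype: {missing[:5]}")
    return CaseControlCohort(genotypes=geno, status=status.loc[geno.samples])
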