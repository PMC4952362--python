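"""Synthetic cohort generator.

Emulates the data the analysis stages consume: biallelic SNP dosages with
block LD structure, normalized expression with additive genotype and
covariate effects under Gaussian noise (per cell type), binary disease
phenotypes from a logistic model on selected SNPs, and read-coverage tracks
with localized peaks. All generators are deterministic under a fixed seed
and their files parse through the package's own readers unchanged.

The LD model is a haplotype-copying chain: within a block, each haplotype
allele either copies the allele at the previous SNP (probability
``ld_rho``) or is drawn fresh at that SNP's allele frequency. Because every
fresh draw uses a frequency inside ``maf_range``, marginal frequencies stay
a convex combination of in-range values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CaseControlCohort, CoverageTrack, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SimScenario",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_case_control",
    "simulate_coverage",
    "gene_annotations",
    "demo_scenario",
]

_GENE_LENGTH_BP = 10_000
_GENE_GAP_BP = 50_000
_READ_LENGTH_BP = 100
_PEAK_SD_BP = 60
_PEAK_READ_FRACTION = 0.5
_MAX_POOL_REGENERATIONS = 200


@dataclass
class SimScenario:
    """Parameters of one synthetic study.

    ``eqtl_map`` entries are (gene_id, snp_id, cell_type, beta) with beta in
    expression units per ALT allele; ``disease_snps`` entries are
    (snp_id, odds_ratio) for the logistic phenotype model.
    """

    n_samples: int = 200
    n_genes: int = 20
    snps_per_gene_region: int = 8
    maf_range: tuple[float, float] = (0.1, 0.45)
    ld_block_size: int = 4
    ld_rho: float = 0.7
    cis_radius_bp: int = 100_000
    cell_types: tuple[str, ...] = ("CD4_T", "CD8_T", "CD14_mono", "CD16_neut")
    eqtl_map: list = field(default_factory=list)
    covariate_effects: dict = field(
        default_factory=lambda: {"status": 0.3, "sex": 0.2, "age": 0.005, "batch": 0.15}
    )
    noise_sd: float = 1.0
    disease_snps: list = field(default_factory=list)
    n_cases: int = 1000
    n_controls: int = 1000
    peak_snps: list = field(default_factory=list)
    library_size: int = 200_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if any(orr <= 0 for _, orr in self.disease_snps):
            raise ValueError("odds ratios must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.n_samples < 1 or self.n_genes < 1 or self.snps_per_gene_region < 1:
            raise ValueError("counts must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["cell_types"] = list(self.cell_types)
        d["eqtl_map"] = [list(e) for e in self.eqtl_map]
        d["disease_snps"] = [list(e) for e in self.disease_snps]
        d["peak_snps"] = list(self.peak_snps)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "cell_types" in d:
            d["cell_types"] = tuple(d["cell_types"])
        if "eqtl_map" in d:
            d["eqtl_map"] = [tuple(e) for e in d["eqtl_map"]]
        if "disease_snps" in d:
            d["disease_snps"] = [tuple(e) for e in d["disease_snps"]]
        return cls(**d)


def _gene_ids(scenario: SimScenario) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, scenario.n_genes + 1)]


def _snp_layout(scenario: SimScenario) -> pd.DataFrame:
    """Deterministic SNP coordinates: each gene's cis window holds its SNPs."""
    rows = []
    span = 2 * scenario.cis_radius_bp + _GENE_LENGTH_BP
    snp_idx = 0
    for gi, gene in enumerate(_gene_ids(scenario)):
        region_start = 1 + gi * (span + _GENE_GAP_BP)
        gene_start = region_start + scenario.cis_radius_bp
        gene_end = gene_start + _GENE_LENGTH_BP - 1
        lo = max(1, gene_start - scenario.cis_radius_bp)
        hi = gene_end + scenario.cis_radius_bp
        positions = np.linspace(lo + 100, hi - 100, scenario.snps_per_gene_region)
        for p in positions:
            rows.append(
                {
                    "snp_id": f"rs{100000 + snp_idx}",
                    "chrom": "chr1",
                    "pos": int(round(p)),
                    "ref": "A",
                    "alt": "G",
                    "gene_region": gene,
                }
            )
            snp_idx += 1
    df = pd.DataFrame(rows).set_index("snp_id")
    return df.sort_values(["chrom", "pos"])


def gene_annotations(scenario: SimScenario) -> pd.DataFrame:
    """Gene spans (1-based inclusive) matching the SNP layout."""
    span = 2 * scenario.cis_radius_bp + _GENE_LENGTH_BP
    rows = []
    for gi, gene in enumerate(_gene_ids(scenario)):
        region_start = 1 + gi * (span + _GENE_GAP_BP)
        start = region_start + scenario.cis_radius_bp
        rows.append(
            {
                "gene_id": gene,
                "chrom": "chr1",
                "start_bp": start,
                "end_bp": start + _GENE_LENGTH_BP - 1,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _simulate_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, block_size: int, rho: float
) -> np.ndarray:
    """Haplotype-copying chain within blocks of ``block_size`` SNPs."""
    m = freqs.size
    H = np.empty((n_hap, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n_hap) < freqs[j]
        if j % block_size == 0:
            H[:, j] = fresh
        else:
            copy = rng.random(n_hap) < rho
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_genotypes(scenario: SimScenario, seed: int) -> GenotypeMatrix:
    """Biallelic SNP dosages with block LD for ``scenario.n_samples`` samples."""
    rng = np.random.default_rng(seed)
    snps = _snp_layout(scenario)
    lo, hi = scenario.maf_range
    freqs = rng.uniform(lo, hi, size=len(snps))
    H = _simulate_haplotypes(
        rng, 2 * scenario.n_samples, freqs, scenario.ld_block_size, scenario.ld_rho
    )
    dosages = H[0::2] + H[1::2]
    samples = [f"S{i:04d}" for i in range(1, scenario.n_samples + 1)]
    dos = pd.DataFrame(dosages.astype(float), index=samples, columns=snps.index)
    return GenotypeMatrix(dosages=dos, snps=snps.drop(columns=["gene_region"]))


def simulate_covariates(n_samples: int, seed: int) -> pd.DataFrame:
    """Per-sample covariates: disease status, sex, age, batch."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    return pd.DataFrame(
        {
            "status": rng.binomial(1, 0.4, n_samples),
            "sex": rng.binomial(1, 0.5, n_samples),
            "age": np.round(rng.uniform(20, 70, n_samples), 1),
            "batch": rng.binomial(1, 0.5, n_samples),
        },
        index=pd.Index(samples, name="sample"),
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    scenario: SimScenario,
    cell_type: str,
    seed: int,
) -> ExpressionMatrix:
    """Expression = intercept + covariate effects + beta * dosage + noise.

    Only (gene, snp, cell_type) entries of ``scenario.eqtl_map`` matching
    ``cell_type`` contribute a genotype term; all other genes are pure
    covariates-plus-noise.
    """
    rng = np.random.default_rng(seed)
    samples = genotypes.samples
    cov = covariates.loc[samples]
    n = len(samples)
    genes = _gene_ids(scenario)
    base = np.zeros((n, len(genes)))
    for cname, slope in scenario.covariate_effects.items():
        if cname in cov.columns:
            base += slope * cov[cname].to_numpy(dtype=float)[:, None]
    values = 5.0 + base + rng.normal(0.0, scenario.noise_sd, size=(n, len(genes)))
    gidx = {g: i for i, g in enumerate(genes)}
    for gene, snp, ct, beta in scenario.eqtl_map:
        if ct != cell_type:
            continue
        if gene not in gidx:
            raise KeyError(f"eqtl_map references unknown gene {gene!r}")
        if snp not in genotypes.snps.index:
            raise KeyError(f"eqtl_map references unknown SNP {snp!r}")
        values[:, gidx[gene]] += beta * genotypes.dosages[snp].to_numpy(dtype=float)
    df = pd.DataFrame(values, index=samples, columns=genes)
    return ExpressionMatrix(values=df, cell_type=cell_type)


def _solve_intercept(scores: np.ndarray, target_frac: float) -> float:
    """Bisection for the logistic intercept matching an expected case fraction."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(1.0 / (1.0 + np.exp(-(mid + scores)))))
        if frac < target_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_case_control(
    genotypes: GenotypeMatrix, scenario: SimScenario, seed: int
) -> CaseControlCohort:
    """Exact-count case-control cohort from a logistic disease model.

    Disease probability per sample is logit^-1(alpha + sum log(OR) * dosage)
    with alpha tuned by bisection so the expected case fraction matches
    n_cases / (n_cases + n_controls). Individuals are drawn from the supplied
    genotype pool (regenerated with fresh seeds when exhausted) until exactly
    n_cases cases and n_controls controls accrue.
    """
    for snp, _ in scenario.disease_snps:
        if snp not in genotypes.snps.index:
            raise KeyError(f"disease SNP {snp!r} not in genotype matrix")
    rng = np.random.default_rng(seed)
    target = scenario.n_cases / (scenario.n_cases + scenario.n_controls)

    def scores_of(geno: GenotypeMatrix) -> np.ndarray:
        s = np.zeros(geno.n_samples)
        for snp, orr in scenario.disease_snps:
            s += np.log(orr) * geno.dosages[snp].to_numpy(dtype=float)
        return s

    pool = genotypes
    alpha = _solve_intercept(scores_of(pool), target)

    case_rows, ctrl_rows = [], []
    for regen in range(_MAX_POOL_REGENERATIONS + 1):
        scores = scores_of(pool)
        probs = 1.0 / (1.0 + np.exp(-(alpha + scores)))
        is_case = rng.random(pool.n_samples) < probs
        dos = pool.dosages.to_numpy(dtype=float)
        for i in range(pool.n_samples):
            if is_case[i] and len(case_rows) < scenario.n_cases:
                case_rows.append(dos[i])
            elif not is_case[i] and len(ctrl_rows) < scenario.n_controls:
                ctrl_rows.append(dos[i])
        if len(case_rows) == scenario.n_cases and len(ctrl_rows) == scenario.n_controls:
            break
        pool = simulate_genotypes(scenario, seed=int(rng.integers(0, 2**31 - 1)))
    else:
        raise RuntimeError(
            "could not reach requested case/control counts after "
            f"{_MAX_POOL_REGENERATIONS} pool regenerations"
        )

    n_total = scenario.n_cases + scenario.n_controls
    samples = [f"C{i:05d}" for i in range(1, n_total + 1)]
    dosage_arr = np.vstack(case_rows + ctrl_rows)
    status = pd.Series(
        [1] * scenario.n_cases + [0] * scenario.n_controls, index=samples, name="case"
    )
    dos = pd.DataFrame(dosage_arr, index=samples, columns=genotypes.snps.index)
    return CaseControlCohort(
        genotypes=GenotypeMatrix(dosages=dos, snps=genotypes.snps), status=status
    )


def simulate_coverage(
    snps: pd.DataFrame, scenario: SimScenario, seed: int
) -> CoverageTrack:
    """Fixed-length reads: uniform background plus Gaussian peaks at peak SNPs.

    Exactly ``scenario.library_size`` reads are emitted. When peak SNPs are
    configured, a fixed fraction of reads is centred on them (Gaussian
    offsets); the rest land uniformly over the SNP-covered span.
    """
    rng = np.random.default_rng(seed)
    total = scenario.library_size
    chrom = str(snps["chrom"].iloc[0])
    span_lo = int(snps["pos"].min()) - 5000
    span_hi = int(snps["pos"].max()) + 5000
    peak_pos = snps.loc[[s for s in scenario.peak_snps if s in snps.index], "pos"]
    n_peak = int(round(_PEAK_READ_FRACTION * total)) if len(peak_pos) else 0
    n_bg = total - n_peak

    starts = rng.integers(max(1, span_lo), span_hi, size=n_bg)
    if n_peak:
        centres = rng.choice(peak_pos.to_numpy(), size=n_peak)
        offs = rng.normal(0, _PEAK_SD_BP, size=n_peak)
        pstarts = np.maximum(1, (centres + offs - _READ_LENGTH_BP // 2).astype(np.int64))
        starts = np.concatenate([starts, pstarts])
    starts = np.sort(starts)
    records = [
        (chrom, int(s), int(s) + _READ_LENGTH_BP - 1, 1) for s in starts
    ]
    return CoverageTrack.from_records(records, total=total)


def demo_scenario(seed: int = 0) -> SimScenario:
    """A compact end-to-end scenario with planted eQTLs and disease effects.

    A third of the genes carry a cis-eQTL (beta = 0.8) in one or more cell
    types; three of those eQTL SNPs also carry disease odds ratios of 1.3,
    and coverage peaks are planted at the eQTL SNPs. The remaining gene
    regions provide the null genomic background for inflation statistics.
    """
    rng = np.random.default_rng(seed)
    sc = SimScenario(
        n_samples=150,
        n_genes=30,
        snps_per_gene_region=10,
        n_cases=1000,
        n_controls=1000,
    )
    snps = _snp_layout(sc)
    genes = _gene_ids(sc)
    eqtl_map = []
    eqtl_snps = []
    for gi, gene in enumerate(genes):
        if gi % 3 != 0:
            continue
        region = snps[snps["gene_region"] == gene]
        snp = str(rng.choice(region.index))
        cts = list(sc.cell_types[: 1 + int(rng.integers(0, len(sc.cell_types)))])
        for ct in cts:
            eqtl_map.append((gene, snp, ct, 0.8))
        eqtl_snps.append(snp)
    disease = [(s, 1.3) for s in eqtl_snps[:3]]
    sc.eqtl_map = eqtl_map
    sc.disease_snps = disease
    sc.peak_snps = eqtl_snps
    return sc
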