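"""In-memory containers shared across pipeline stages.

All genomic coordinates held in these containers are 1-based inclusive
(the VCF convention); BED input/output is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "CaseControlCohort",
    "CoverageTrack",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage table with per-SNP metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id with one column per SNP id.
        Entries are ALT-allele counts in {0, 1, 2}; missing calls are NaN.
    snps
        DataFrame indexed by SNP id with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``, sorted by (chrom, pos).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snps.index):
            # keep dosage columns aligned with the (chrom, pos)-sorted metadata
            self.dosages = self.dosages[list(self.snps.index)]

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self, snp_ids: list[str] | None = None) -> pd.Series:
        """Minor allele frequency per SNP over non-missing samples."""
        d = self.dosages if snp_ids is None else self.dosages[snp_ids]
        p_alt = d.mean(axis=0) / 2.0
        return pd.concat([p_alt, 1.0 - p_alt], axis=1).min(axis=1)

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        missing = [s for s in samples if s not in self.dosages.index]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing}")
        return GenotypeMatrix(self.dosages.loc[samples], self.snps)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        missing = [s for s in snp_ids if s not in self.snps.index]
        if missing:
            raise KeyError(f"SNPs absent from genotype matrix: {missing}")
        return GenotypeMatrix(self.dosages[snp_ids], self.snps.loc[snp_ids])

    def snps_in_window(self, chrom: str, lo_bp: int, hi_bp: int) -> list[str]:
        m = self.snps
        hit = (m["chrom"] == chrom) & (m["pos"] >= lo_bp) & (m["pos"] <= hi_bp)
        return list(m.index[hit])


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized expression values for one cell type."""

    values: pd.DataFrame
    cell_type: str

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CaseControlCohort:
    """Genotyped case-control cohort: dosages plus a binary phenotype."""

    genotypes: GenotypeMatrix
    status: pd.Series  # 1 = case, 0 = control, indexed by sample id

    def __post_init__(self) -> None:
        if list(self.status.index) != self.genotypes.samples:
            self.status = self.status.loc[self.genotypes.samples]

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())


@dataclass
class CoverageTrack:
    """Read-coverage intervals with counts, queryable at single positions.

    Intervals are stored 1-based inclusive per chromosome. Overlapping
    intervals are allowed; counts sum on query. ``total_mapped_reads`` is
    the library size used for counts-per-million scaling.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, counts)
    total_mapped_reads: int = 0

    @classmethod
    def from_records(
        cls, records: list[tuple[str, int, int, int]], total: int | None = None
    ) -> "CoverageTrack":
        """Build from (chrom, start_1based, end_1based, count) records."""
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, s, e, c in records:
            by_chrom.setdefault(chrom, []).append((s, e, c))
        intervals = {}
        grand = 0
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            counts = np.array([r[2] for r in rows], dtype=np.int64)
            intervals[chrom] = (starts, ends, counts)
            grand += int(counts.sum())
        return cls(intervals=intervals, total_mapped_reads=grand if total is None else total)

    def query(self, chrom: str, pos: int) -> int:
        """Summed count of all intervals overlapping a 1-bp position."""
        if chrom not in self.intervals:
            return 0
        starts, ends, counts = self.intervals[chrom]
        hit = (starts <= pos) & (ends >= pos)
        return int(counts[hit].sum())

    def query_many(self, chroms: list[str], positions: np.ndarray) -> np.ndarray:
        return np.array(
            [self.query(c, int(p)) for c, p in zip(chroms, positions)], dtype=np.int64
        )

    @property
    def n_intervals(self) -> int:
        return sum(len(v[0]) for v in self.intervals.values())
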