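"""Run configuration: thresholds, permutation counts, paths and the scenario.

The configuration carries the analysis constants — the 5 % minor-allele
frequency floor, the 10 % permutation-FDR significance threshold with 320
permutations, the 100 kbp cis radius, the r^2 >= 0.8 tagging threshold, the
0.33 multiple-correlation ceiling, 10,000 phenotype permutations for the
set test and 10,000 resampling iterations for the chromatin null — and
round-trips losslessly through a versioned YAML schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthdata import SimScenario

__all__ = ["RunConfig", "SCHEMA_VERSION", "STAGES"]

SCHEMA_VERSION = 1
STAGES = ("simulate", "eqtl", "select", "setassoc", "chromatin")

_DEFAULT_PATHS = {
    "genotypes_vcf": "genotypes.vcf",
    "covariates_tsv": "covariates.tsv",
    "genes_bed": "genes.bed",
    "expression_tsv_pattern": "expression_{cell_type}.tsv",
    "cohort_vcf": "cohort.vcf",
    "phenotypes_tsv": "phenotypes.tsv",
    "coverage_bed": "coverage.bed",
    "manifest_tsv": "scenario_manifest.tsv",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    cis_radius_bp: int = 100_000
    maf_min: float = 0.05
    eqtl_fdr_threshold: float = 0.10
    n_perms_eqtl: int = 320
    n_perms_set: int = 10_000
    n_iter_null: int = 10_000
    r2_tag_min: float = 0.8
    max_multiple_corr: float = 0.33
    mhc_region: tuple[str, int, int] = ("chr6", 25_000_000, 34_000_000)
    out_dir: str = "cytoqtl_out"
    stages: tuple[str, ...] = STAGES
    paths: dict = field(default_factory=lambda: dict(_DEFAULT_PATHS))
    scenario: SimScenario = field(default_factory=SimScenario)

    def __post_init__(self) -> None:
        for name in ("maf_min", "eqtl_fdr_threshold", "r2_tag_min", "max_multiple_corr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_perms_eqtl", "n_perms_set", "n_iter_null"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cis_radius_bp < 0:
            raise ValueError("cis_radius_bp must be >= 0")
        if len(self.mhc_region) != 3:
            raise ValueError("mhc_region must be (chrom, start_bp, end_bp)")
        self.mhc_region = (str(self.mhc_region[0]), int(self.mhc_region[1]), int(self.mhc_region[2]))
        unknown_stages = set(self.stages) - set(STAGES)
        if unknown_stages:
            raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
        unknown_paths = set(self.paths) - set(_DEFAULT_PATHS)
        if unknown_paths:
            raise ValueError(f"unknown path keys: {sorted(unknown_paths)}")
        merged = dict(_DEFAULT_PATHS)
        merged.update(self.paths)
        self.paths = merged

    def resolve(self, key: str, **fmt) -> Path:
        return Path(self.out_dir) / self.paths[key].format(**fmt)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["mhc_region"] = list(self.mhc_region)
        d["stages"] = list(self.stages)
        d["scenario"] = self.scenario.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {version}")
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mhc_region" in d:
            d["mhc_region"] = tuple(d["mhc_region"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "scenario" in d and not isinstance(d["scenario"], SimScenario):
            d["scenario"] = SimScenario.from_dict(d["scenario"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(data)
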