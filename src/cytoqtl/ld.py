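"""Linkage-disequilibrium computation, proxy tagging and independence filtering.

LD is measured as the squared Pearson correlation of allele dosages (the
composite-LD estimator for unphased data). Tagging collects all SNPs with
r^2 at or above a threshold around an index SNP; independence filtering is
a greedy pass that retains a candidate only while its multiple correlation
against the already-retained dosages stays at or below a ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["TagSet", "ld_r2", "tag_snps", "independence_filter", "multiple_correlation"]

# absolute slack on inclusive r^2 / multiple-R comparisons, so thresholds like
# 0.8 that are not exactly representable in binary behave inclusively
_EPS = 1e-12


@dataclass
class TagSet:
    """An index SNP with its r^2-qualified proxies (index included at r^2=1)."""

    index_snp_id: str
    proxies: pd.Series  # snp_id -> r^2, includes the index itself

    @property
    def proxy_snp_ids(self) -> list[str]:
        return list(self.proxies.index)


def _pairwise_complete(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors, in [0, 1]."""
    a, b = _pairwise_complete(dosages_a, dosages_b)
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("monomorphic input: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return min(float(r * r), 1.0)


def tag_snps(
    index_snp: str,
    geno: GenotypeMatrix,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
) -> TagSet:
    """All SNPs within ``window_bp`` of the index with r^2 >= ``r2_min``.

    The threshold is inclusive; the index SNP always tags itself with
    r^2 = 1. Matches a brute-force all-pairs scan exactly.
    """
    if index_snp not in geno.snps.index:
        raise KeyError(f"index SNP {index_snp!r} not in genotype matrix")
    idx_row = geno.snps.loc[index_snp]
    g_index = geno.dosages[index_snp].to_numpy(dtype=float)
    if np.unique(g_index[~np.isnan(g_index)]).size < 2:
        raise ValueError(f"index SNP {index_snp!r} is monomorphic")
    candidates = geno.snps_in_window(
        str(idx_row["chrom"]),
        int(idx_row["pos"]) - window_bp,
        int(idx_row["pos"]) + window_bp,
    )
    hits: dict[str, float] = {index_snp: 1.0}
    for snp in candidates:
        if snp == index_snp:
            continue
        g = geno.dosages[snp].to_numpy(dtype=float)
        try:
            r2 = ld_r2(g_index, g)
        except ValueError:
            continue  # monomorphic candidate cannot tag
        if r2 >= r2_min - _EPS:
            hits[snp] = r2
    return TagSet(index_snp_id=index_snp, proxies=pd.Series(hits, name="r2"))


def multiple_correlation(target, predictors) -> float:
    """Multiple correlation R of a dosage vector on a set of predictors.

    The square root of R^2 from an intercept-included least-squares
    regression of ``target`` on the columns of ``predictors``.
    """
    y = np.asarray(target, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return 0.0
    Xi = np.column_stack([np.ones(y.size), X])
    coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise ValueError("monomorphic target: multiple correlation undefined")
    r2 = 1.0 - float(resid @ resid) / tss
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


def independence_filter(
    snps: list[str],
    geno: GenotypeMatrix,
    max_R: float = 0.33,
) -> pd.DataFrame:
    """Relative-independence filter in the supplied candidate order.

    A greedy pass retains a candidate iff its multiple correlation
    coefficient against all previously retained dosage vectors is
    <= ``max_R`` (the first candidate is always retained). A joint audit
    then re-checks every retained SNP against all the others together;
    while any exceeds the ceiling, the latest-ordered violator is dropped.
    The result therefore satisfies the postcondition that each retained
    SNP's multiple correlation against the other retained SNPs, computed
    jointly, is <= ``max_R``.

    Returns a DataFrame with one row per candidate in input order
    (columns ``snp_id``, ``order``, ``multiple_R``, ``retained``,
    ``removal``); ``removal`` is '' for retained SNPs, 'greedy' for SNPs
    that failed against their predecessors and 'joint_audit' for SNPs
    dropped by the audit. Callers choose the candidate ordering (by
    convention, descending association significance).
    """
    rows = []
    centered: list[np.ndarray] = []  # centered retained dosages
    basis: list[np.ndarray] = []  # orthonormal basis of the retained span
    retained_idx: list[int] = []
    for i, snp in enumerate(snps):
        g = geno.dosages[snp].to_numpy(dtype=float)
        c = g - g.mean()
        denom = float(c @ c)
        if denom <= 0:
            raise ValueError(f"monomorphic candidate {snp!r}")
        if not basis:
            R = 0.0
        else:
            Q = np.column_stack(basis)
            proj = Q.T @ c
            R = float(np.sqrt(min(max(float(proj @ proj) / denom, 0.0), 1.0)))
        keep = R <= max_R + _EPS
        if keep and denom > 0:
            q = c.copy()
            if basis:
                Q = np.column_stack(basis)
                q = q - Q @ (Q.T @ q)
                q = q - Q @ (Q.T @ q)  # re-orthogonalize
            norm = float(np.linalg.norm(q))
            if norm > 1e-10:
                basis.append(q / norm)
            centered.append(c)
            retained_idx.append(i)
        rows.append(
            {
                "snp_id": snp,
                "order": i,
                "multiple_R": R,
                "retained": keep,
                "removal": "" if keep else "greedy",
            }
        )
    table = pd.DataFrame(
        rows, columns=["snp_id", "order", "multiple_R", "retained", "removal"]
    )
    _joint_audit_repair(table, centered, retained_idx, max_R)
    return table


def _joint_audit_repair(
    table: pd.DataFrame,
    centered: list[np.ndarray],
    retained_idx: list[int],
    max_R: float,
) -> None:
    """Drop latest-ordered retained SNPs until the joint audit passes.

    The multiple correlation of each retained SNP on the others comes from
    the inverse correlation matrix: R_i^2 = 1 - 1 / (C^-1)_ii.
    """
    while len(retained_idx) > 2:
        Z = np.column_stack([c / np.linalg.norm(c) for c in centered])
        C = Z.T @ Z
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError:
            diag = np.full(len(retained_idx), np.inf)
        else:
            diag = np.diag(Cinv)
        with np.errstate(divide="ignore"):
            r2 = 1.0 - 1.0 / np.maximum(diag, 1.0)
        R = np.sqrt(np.clip(r2, 0.0, 1.0))
        bad = np.flatnonzero(R > max_R + 1e-9)
        if bad.size == 0:
            return
        drop = int(bad[-1])  # latest in candidate order among violators
        row = retained_idx[drop]
        table.loc[table["order"] == row, ["retained", "removal", "multiple_R"]] = [
            False,
            "joint_audit",
            float(R[drop]),
        ]
        del retained_idx[drop], centered[drop]


def retained_ids(filter_table: pd.DataFrame) -> list[str]:
    """SNP ids flagged as retained by :func:`independence_filter`."""
    return list(filter_table.loc[filter_table["retained"], "snp_id"])
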