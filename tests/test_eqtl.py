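"""Cis-eQTL mapping, best-SNP extraction and exhaustive variable selection."""

import numpy as np
import pandas as pd
import pytest

from cytoqtl.eqtl import (
    best_snp_per_gene,
    define_cis_window,
    exhaustive_selection,
    map_cis_eqtls,
    subgroup_concordance,
)
from cytoqtl.synthdata import (
    SimScenario,
    gene_annotations,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
)


def gene_row(start, end, chrom="chr1"):
    return pd.Series({"chrom": chrom, "start_bp": start, "end_bp": end})


class TestCisWindow:
    def test_symmetric_extension(self):
        assert define_cis_window(gene_row(1_000_000, 1_010_000), 100_000) == (
            "chr1", 900_000, 1_110_000,
        )

    def test_zero_radius_is_gene_span(self):
        assert define_cis_window(gene_row(500, 900), 0) == ("chr1", 500, 900)

    def test_clamped_at_chromosome_start(self):
        assert define_cis_window(gene_row(50_000, 60_000), 100_000) == (
            "chr1", 1, 160_000,
        )


@pytest.fixture(scope="module")
def planted():
    """One strong planted eQTL among 8 genes, one cell type."""
    sc = SimScenario(
        n_samples=200,
        n_genes=8,
        snps_per_gene_region=5,
        eqtl_map=[("GENE0001", "rs100002", "CD4_T", 1.0)],
        noise_sd=1.0,
        ld_rho=0.5,
    )
    geno = simulate_genotypes(sc, seed=10)
    covars = simulate_covariates(sc.n_samples, seed=11)
    expr = simulate_expression(geno, covars, sc, "CD4_T", seed=12)
    genes = gene_annotations(sc)
    return sc, geno, covars, expr, genes


class TestMapCisEqtls:
    def test_planted_eqtl_discovered(self, planted):
        sc, geno, covars, expr, genes = planted
        mapping = map_cis_eqtls(expr, geno, covars, genes, n_perms=100, seed=1)
        hit = mapping.table[
            (mapping.table["gene_id"] == "GENE0001")
            & (mapping.table["snp_id"] == "rs100002")
        ]
        assert len(hit) == 1 and bool(hit["significant"].iloc[0])
        # planted slope recovered in sign and rough magnitude
        assert hit["beta_all"].iloc[0] == pytest.approx(1.0, abs=0.35)

    def test_low_maf_snps_excluded(self, planted):
        sc, geno, covars, expr, genes = planted
        geno2 = geno.subset_snps(geno.snp_ids)
        rare = geno2.dosages.copy()
        # force one SNP to MAF 0.04: 16 carriers of 200 samples
        rare.iloc[:, 0] = 0.0
        rare.iloc[:16, 0] = 1.0
        from cytoqtl.containers import GenotypeMatrix

        geno2 = GenotypeMatrix(dosages=rare, snps=geno2.snps)
        mapping = map_cis_eqtls(expr, geno2, covars, genes, n_perms=20, seed=1)
        assert geno2.snp_ids[0] not in set(mapping.table["snp_id"])

    def test_rows_lie_in_cis_window(self, planted):
        sc, geno, covars, expr, genes = planted
        mapping = map_cis_eqtls(expr, geno, covars, genes, n_perms=20, seed=2)
        for _, row in mapping.table.iterrows():
            chrom, lo, hi = define_cis_window(genes.loc[row["gene_id"]], 100_000)
            pos = int(geno.snps.loc[row["snp_id"], "pos"])
            assert lo <= pos <= hi

    def test_affine_expression_rescaling_preserves_chi2(self, planted):
        sc, geno, covars, expr, genes = planted
        mapping_a = map_cis_eqtls(expr, geno, covars, genes, n_perms=20, seed=3)
        from cytoqtl.containers import ExpressionMatrix

        expr_b = ExpressionMatrix(values=2.5 * expr.values - 7.0, cell_type="CD4_T")
        mapping_b = map_cis_eqtls(expr_b, geno, covars, genes, n_perms=20, seed=3)
        np.testing.assert_allclose(
            mapping_a.table["chi2"], mapping_b.table["chi2"], rtol=1e-9
        )

    def test_discovery_count_monotone_in_thresholds(self, planted):
        """Tightening MAF or FDR thresholds never adds discoveries."""
        sc, geno, covars, expr, genes = planted
        kw = dict(n_perms=50, seed=4)
        base = map_cis_eqtls(expr, geno, covars, genes, maf_min=0.05,
                             fdr_threshold=0.10, **kw)
        higher_maf = map_cis_eqtls(expr, geno, covars, genes, maf_min=0.25,
                                   fdr_threshold=0.10, **kw)
        lower_fdr = map_cis_eqtls(expr, geno, covars, genes, maf_min=0.05,
                                  fdr_threshold=0.02, **kw)
        n_base = base.table["significant"].sum()
        assert higher_maf.table["significant"].sum() <= n_base
        assert lower_fdr.table["significant"].sum() <= n_base

    def test_too_few_samples_raise(self, planted):
        sc, geno, covars, expr, genes = planted
        from cytoqtl.containers import ExpressionMatrix

        tiny = ExpressionMatrix(values=expr.values.iloc[:10], cell_type="CD4_T")
        with pytest.raises(ValueError, match="shared samples"):
            map_cis_eqtls(tiny, geno, covars, genes)

    def test_determinism(self, planted):
        sc, geno, covars, expr, genes = planted
        a = map_cis_eqtls(expr, geno, covars, genes, n_perms=30, seed=9)
        b = map_cis_eqtls(expr, geno, covars, genes, n_perms=30, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestBestSnp:
    def make_table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "snp_id", "cell_type", "chi2", "p", "fdr",
                     "significant", "beta_all"],
        )

    def test_single_snp_gene(self):
        t = self.make_table([["g1", "s1", "ct", 5.0, 0.02, 0.1, False, 0.3]])
        best, _ = best_snp_per_gene(t)
        assert list(best["snp_id"]) == ["s1"]

    def test_tie_broken_by_chi2_then_id(self):
        t = self.make_table([
            ["g1", "s2", "ct", 5.0, 0.02, 0.1, False, 0.3],
            ["g1", "s1", "ct", 5.0, 0.02, 0.1, False, 0.3],
            ["g1", "s3", "ct", 6.0, 0.02, 0.1, False, 0.3],
        ])
        best, _ = best_snp_per_gene(t)
        assert list(best["snp_id"]) == ["s3"]  # larger chi2 wins the p tie
        t2 = self.make_table([
            ["g1", "s2", "ct", 5.0, 0.02, 0.1, False, 0.3],
            ["g1", "s1", "ct", 5.0, 0.02, 0.1, False, 0.3],
        ])
        best2, _ = best_snp_per_gene(t2)
        assert list(best2["snp_id"]) == ["s1"]  # then lexicographic id

    def test_matrix_is_neglog10_fdr(self):
        t = self.make_table([
            ["g1", "s1", "a", 9.0, 0.001, 0.01, True, 0.3],
            ["g1", "s2", "b", 4.0, 0.04, 0.2, False, 0.3],
        ])
        _, mat = best_snp_per_gene(t)
        assert mat.loc["g1", "a"] == pytest.approx(2.0)
        assert mat.loc["g1", "b"] == pytest.approx(-np.log10(0.2))

    def test_strongest_planted_snp_selected(self):
        """The largest-|beta| planted SNP is the best SNP in >=18/20 seeds."""
        wins = 0
        for seed in range(20):
            sc = SimScenario(
                n_samples=500, n_genes=1, snps_per_gene_region=4, ld_rho=0.0,
                eqtl_map=[("GENE0001", "rs100001", "CD4_T", 0.6),
                          ("GENE0001", "rs100003", "CD4_T", 0.2)],
                covariate_effects={},
            )
            geno = simulate_genotypes(sc, seed=seed)
            covars = simulate_covariates(sc.n_samples, seed=seed + 100)
            expr = simulate_expression(geno, covars, sc, "CD4_T", seed=seed + 200)
            genes = gene_annotations(sc)
            mapping = map_cis_eqtls(expr, geno, covars, genes, n_perms=10, seed=seed)
            best, _ = best_snp_per_gene(mapping.table)
            if best["snp_id"].iloc[0] == "rs100001":
                wins += 1
        assert wins >= 18


class TestSubgroupConcordance:
    def test_null_group_slope_within_se(self):
        """A group with no planted effect shows a slope within 3 SE of zero."""
        sc = SimScenario(n_samples=400, n_genes=2, snps_per_gene_region=4,
                         covariate_effects={}, ld_rho=0.0)
        geno = simulate_genotypes(sc, seed=0)
        covars = simulate_covariates(sc.n_samples, seed=1)
        # plant an effect only in status==1 samples by adding it post hoc
        expr = simulate_expression(geno, covars, sc, "CD4_T", seed=2)
        g = geno.dosages["rs100001"]
        mask = (covars["status"] == 1).astype(float)
        expr.values["GENE0001"] = expr.values["GENE0001"] + 0.8 * g * mask
        table = pd.DataFrame(
            [{"gene_id": "GENE0001", "snp_id": "rs100001", "cell_type": "CD4_T",
              "chi2": 10.0, "p": 1e-3, "fdr": 0.01, "significant": True,
              "beta_all": 0.4}]
        )
        out = subgroup_concordance(table, expr, geno, covars, "status")
        g0 = out[out["group"] == 0].iloc[0]
        g1 = out[out["group"] == 1].iloc[0]
        assert abs(g0["beta"]) < 3 * g0["se"]
        assert g1["beta"] > 3 * g1["se"]

    def test_missing_group_column_raises(self, small_genotypes, small_covariates):
        from cytoqtl.containers import ExpressionMatrix

        expr = ExpressionMatrix(
            values=pd.DataFrame(np.zeros((120, 1)), index=small_genotypes.samples,
                                columns=["GENE0001"]),
            cell_type="CD4_T",
        )
        with pytest.raises(KeyError, match="nope"):
            subgroup_concordance(pd.DataFrame(), expr, small_genotypes,
                                 small_covariates, "nope")


class TestExhaustiveSelection:
    def brute_force(self, y, G, ids):
        """Independent subset-enumeration oracle with raw BIC arithmetic."""
        import itertools

        n = len(y)
        best = None
        for r in range(len(ids) + 1):
            for sub in itertools.combinations(range(len(ids)), r):
                X = np.column_stack([np.ones(n)] + [G[:, j] for j in sub])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = max(float(np.sum((y - X @ beta) ** 2)), 1e-300)
                bic = n * np.log(rss / n) + X.shape[1] * np.log(n)
                key = (bic, len(sub), tuple(sorted(ids[j] for j in sub)))
                if best is None or key < (best[0] - 1e-9, *best[1:]) or (
                    abs(key[0] - best[0]) <= 1e-9 * (1 + abs(best[0]))
                    and key[1:] < best[1:]
                ):
                    best = key
        return list(best[2])

    def test_causal_snp_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            G = rng.binomial(2, 0.4, size=(300, 4)).astype(float)
            y = G[:, 1] * 1.0 + rng.normal(size=300)
            ids = ["a", "b", "c", "d"]
            df = pd.DataFrame(G, columns=ids,
                              index=[f"S{i}" for i in range(300)])
            sel = exhaustive_selection(y, df)
            if sel == ["b"]:
                hits += 1
        assert hits >= 18

    def test_all_null_selects_empty(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            G = rng.binomial(2, 0.4, size=(300, 4)).astype(float)
            y = rng.normal(size=300)
            df = pd.DataFrame(G, columns=list("abcd"),
                              index=[f"S{i}" for i in range(300)])
            if exhaustive_selection(y, df) == []:
                empties += 1
        assert empties >= 16

    def test_duplicated_causal_keeps_lexicographic(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, 200).astype(float)
        y = g + rng.normal(size=200)
        df = pd.DataFrame({"zdup": g, "adup": g},
                          index=[f"S{i}" for i in range(200)])
        assert exhaustive_selection(y, df) == ["adup"]

    def test_matches_enumeration_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            G = rng.binomial(2, 0.3, size=(150, 5)).astype(float)
            y = 0.5 * G[:, 0] - 0.4 * G[:, 3] + rng.normal(size=150)
            ids = list("vwxyz")
            df = pd.DataFrame(G, columns=ids, index=[f"S{i}" for i in range(150)])
            assert exhaustive_selection(y, df) == self.brute_force(y, G, ids)

    def test_bound_on_candidates(self):
        df = pd.DataFrame(np.zeros((20, 11)), columns=[f"s{i}" for i in range(11)])
        with pytest.raises(ValueError, match="exhaustive search bound"):
            exhaustive_selection(np.zeros(20), df)
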