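"""SNP-set construction and permutation-based disease association."""

import numpy as np
import pandas as pd
import pytest


from cytoqtl.setassoc import (
    SnpSet,
    build_snp_set,
    catalog_enrichment,
    classify_effect_direction,
    gene_level_association,
    qq_coordinates,
    set_association,
)
from cytoqtl.stats import allelic_chi2
from cytoqtl.synthdata import (
    SimScenario,
    gene_annotations,
    simulate_case_control,
    simulate_genotypes,
)

from conftest import make_genotypes


def best_rows(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "cell_type", "p", "significant"]
    )


@pytest.fixture(scope="module")
def ld_panel():
    sc = SimScenario(n_samples=300, n_genes=4, snps_per_gene_region=10,
                     ld_rho=0.85, ld_block_size=5)
    return sc, simulate_genotypes(sc, seed=21), gene_annotations(sc)


class TestBuildSnpSet:
    def test_basic_set_with_provenance(self, ld_panel):
        sc, geno, genes = ld_panel
        best = best_rows([
            ["GENE0001", "rs100002", "CD4_T", 1e-5, True],
            ["GENE0002", "rs100012", "CD8_T", 1e-4, True],
        ])
        s = build_snp_set(best, geno, geno.snp_ids, genes)
        assert s.members
        assert set(s.provenance["source_gene"]) <= {"GENE0001", "GENE0002"}
        audit_kept = set(s.filter_audit.loc[s.filter_audit["retained"], "snp_id"])
        assert set(s.members) == audit_kept

    def test_mhc_gene_excluded(self, ld_panel):
        sc, geno, genes = ld_panel
        genes2 = genes.copy()
        start = int(genes2.loc["GENE0001", "start_bp"])
        end = int(genes2.loc["GENE0001", "end_bp"])
        best = best_rows([
            ["GENE0001", "rs100002", "CD4_T", 1e-5, True],
            ["GENE0002", "rs100012", "CD8_T", 1e-4, True],
        ])
        s = build_snp_set(best, geno, geno.snp_ids, genes2,
                          mhc_region=("chr1", start - 10, end + 10))
        assert "GENE0001" not in set(s.provenance["source_gene"])

    def test_index_absent_from_chip_enters_via_proxy(self, ld_panel):
        sc, geno, genes = ld_panel
        index = "rs100002"
        proxies = [s for s in geno.snp_ids if s != index]
        best = best_rows([["GENE0001", index, "CD4_T", 1e-5, True]])
        from cytoqtl.ld import tag_snps

        tags = tag_snps(index, geno, r2_min=0.8)
        good_proxies = [s for s in tags.proxy_snp_ids if s != index]
        if not good_proxies:
            pytest.skip("LD draw produced no r2>=0.8 proxy for this index")
        s = build_snp_set(best, geno, proxies, genes)
        assert index not in s.members
        assert set(s.members) <= set(good_proxies)

    def test_duplicate_proxy_counted_once_with_both_provenances(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, 400).astype(float)
        noise = lambda: np.where(rng.random(400) < 0.05, rng.binomial(2, 0.4, 400), g)
        geno = make_genotypes(np.column_stack([g, noise(), noise()]), spacing=100)
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start_bp": [1, 150], "end_bp": [120, 320]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        best = best_rows([
            ["gA", "rs0001", "CD4_T", 1e-6, True],
            ["gB", "rs0002", "CD8_T", 1e-5, True],
        ])
        s = build_snp_set(best, geno, geno.snp_ids, genes)
        # the strongly correlated trio collapses to one member with
        # provenance from both genes
        assert len(s.members) == 1
        assert set(s.provenance["source_gene"]) == {"gA", "gB"}

    def test_empty_input_raises(self, ld_panel):
        sc, geno, genes = ld_panel
        with pytest.raises(ValueError, match="no testable SNPs"):
            build_snp_set(best_rows([]), geno, geno.snp_ids, genes)

    def test_empty_after_chip_intersection_names_step(self, ld_panel):
        sc, geno, genes = ld_panel
        best = best_rows([["GENE0001", "rs100002", "CD4_T", 1e-5, True]])
        with pytest.raises(ValueError, match="chip intersection"):
            build_snp_set(best, geno, ["rs_not_there"], genes)


def null_cohort(n=400, n_snps_genes=(3, 4), seed=0):
    sc = SimScenario(n_samples=n, n_genes=n_snps_genes[0],
                     snps_per_gene_region=n_snps_genes[1],
                     n_cases=n // 2, n_controls=n // 2)
    pool = simulate_genotypes(sc, seed=seed)
    return sc, simulate_case_control(pool, sc, seed=seed + 1)


class TestSetAssociation:
    def test_single_snp_sum_equals_allelic_chi2(self):
        sc, cohort = null_cohort(seed=4)
        snp = cohort.genotypes.snp_ids[0]
        prov = pd.DataFrame(
            [{"member": snp, "source_gene": "g", "source_cell_type": "ct",
              "index_snp": snp, "r2": 1.0, "index_p": 1e-4}]
        )
        s = SnpSet(members=[snp], provenance=prov, filter_audit=pd.DataFrame())
        res = set_association(s, cohort, n_perms=50, seed=0)
        status = cohort.status.to_numpy()
        g = cohort.genotypes.dosages[snp].to_numpy()
        direct = allelic_chi2(g[status == 1], g[status == 0]).chi2
        assert res.sum_chi2 == pytest.approx(direct, rel=1e-9)
        assert res.n_snps_used == 1

    def test_perm_distribution_invariant_to_snp_order(self):
        sc, cohort = null_cohort(seed=5)
        snps = cohort.genotypes.snp_ids[:6]
        def make(members):
            prov = pd.DataFrame(
                [{"member": m, "source_gene": "g", "source_cell_type": "ct",
                  "index_snp": m, "r2": 1.0, "index_p": 1e-4} for m in members]
            )
            return SnpSet(members=members, provenance=prov, filter_audit=pd.DataFrame())
        a = set_association(make(list(snps)), cohort, n_perms=100, seed=7,
                            keep_perm_sums=True)
        b = set_association(make(list(reversed(snps))), cohort, n_perms=100, seed=7,
                            keep_perm_sums=True)
        np.testing.assert_allclose(a.perm_sums, b.perm_sums, rtol=1e-9)
        assert a.sum_chi2 == pytest.approx(b.sum_chi2)

    def test_lambda_1000_fixed_point_identity(self):
        sc, cohort = null_cohort(n=2000, seed=6)  # exactly 1000/1000
        snps = cohort.genotypes.snp_ids[:5]
        prov = pd.DataFrame(
            [{"member": m, "source_gene": "g", "source_cell_type": "ct",
              "index_snp": m, "r2": 1.0, "index_p": 1e-4} for m in snps]
        )
        s = SnpSet(members=list(snps), provenance=prov, filter_audit=pd.DataFrame())
        res = set_association(s, cohort, n_perms=20, seed=0)
        assert res.lambda_1000_set == pytest.approx(res.lambda_set, rel=1e-12)

    def test_p_string_reports_below_resolution(self):
        sc, cohort = null_cohort(seed=8)
        snp = cohort.genotypes.snp_ids[0]
        prov = pd.DataFrame(
            [{"member": snp, "source_gene": "g", "source_cell_type": "ct",
              "index_snp": snp, "r2": 1.0, "index_p": 1e-4}]
        )
        s = SnpSet(members=[snp], provenance=prov, filter_audit=pd.DataFrame())
        res = set_association(s, cohort, n_perms=50, seed=0)
        if res.empirical_p == 0.0:
            assert res.p_string == "<0.02"
        else:
            assert float(res.p_string) == pytest.approx(res.empirical_p)

    def test_empty_set_raises(self):
        sc, cohort = null_cohort(seed=9)
        s = SnpSet(members=[], provenance=pd.DataFrame(), filter_audit=pd.DataFrame())
        with pytest.raises(ValueError, match="empty SNP set"):
            set_association(s, cohort, n_perms=10, seed=0)


class TestGeneLevel:
    def make_set(self, cohort, mapping):
        rows = []
        for gene, members in mapping.items():
            for m in members:
                rows.append({"member": m, "source_gene": gene,
                             "source_cell_type": "ct", "index_snp": m,
                             "r2": 1.0, "index_p": 1e-4})
        prov = pd.DataFrame(rows)
        return SnpSet(members=sorted(prov["member"].unique()), provenance=prov,
                      filter_audit=pd.DataFrame())

    def test_single_gene_adjusted_equals_raw(self):
        sc, cohort = null_cohort(seed=10)
        s = self.make_set(cohort, {"gA": cohort.genotypes.snp_ids[:3]})
        out = gene_level_association(s, cohort, n_perms=200, seed=3)
        assert len(out) == 1
        assert out["bh_adjusted_p"].iloc[0] == pytest.approx(out["empirical_p"].iloc[0])

    def test_gene_level_matches_set_level_for_matching_seed(self):
        sc, cohort = null_cohort(seed=11)
        # SNPs from different gene regions, so the gene-level independence
        # pre-filter keeps both and the two code paths see the same set
        members = [cohort.genotypes.snp_ids[0], cohort.genotypes.snp_ids[8]]
        s = self.make_set(cohort, {"gA": members})
        gene_out = gene_level_association(s, cohort, n_perms=300, seed=5)
        set_out = set_association(s, cohort, n_perms=300, seed=5)
        assert gene_out["empirical_p"].iloc[0] == pytest.approx(set_out.empirical_p)
        assert gene_out["sum_chi2"].iloc[0] == pytest.approx(set_out.sum_chi2)

    def test_gene_without_cohort_snps_reported_missing(self):
        sc, cohort = null_cohort(seed=12)
        s = self.make_set(cohort, {"gA": cohort.genotypes.snp_ids[:2],
                                   "gB": ["rs_absent"]})
        out = gene_level_association(s, cohort, n_perms=50, seed=0)
        missing = out[out["gene_id"] == "gB"]
        assert missing["reason"].iloc[0] != ""
        assert np.isnan(missing["empirical_p"].iloc[0])


class TestDirectionsAndEnrichment:
    def test_direction_classification(self):
        assert classify_effect_direction(0.5, "ALT") == "risk-increases-expression"
        assert classify_effect_direction(0.5, "REF") == "risk-decreases-expression"
        # relabelling invariance: flip allele and slope sign together
        assert classify_effect_direction(-0.5, "REF") == classify_effect_direction(
            0.5, "ALT"
        )

    def test_protective_allele_pattern(self):
        # protective allele associated with increased expression -> the risk
        # (other) allele decreases expression
        beta_per_protective_allele = +0.4
        assert classify_effect_direction(
            beta_per_protective_allele, "REF"
        ) == "risk-decreases-expression"

    def test_zero_beta_raises(self):
        with pytest.raises(ValueError, match="no direction"):
            classify_effect_direction(0.0, "ALT")

    def test_catalog_enrichment_null_and_signal(self):
        p_null, odds = catalog_enrichment(10, 30, 100, 300)
        assert p_null == pytest.approx(1.0)
        p_sig, odds_sig = catalog_enrichment(21, 88, 100, 20_000)
        assert p_sig < 1e-9
        assert odds_sig > 1
        # doubling all counts only strengthens the signal
        p_doubled, _ = catalog_enrichment(42, 176, 200, 40_000)
        assert p_doubled < p_sig * 10

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError, match="inconsistent"):
            catalog_enrichment(31, 30, 100, 300)


class TestQq:
    def test_qq_shapes_and_order(self):
        rng = np.random.default_rng(0)
        v = rng.chisquare(1, 101)
        qq = qq_coordinates(v)
        assert len(qq) == 101
        assert (np.diff(qq["observed_chi2"]) >= 0).all()
        assert (np.diff(qq["expected_chi2"]) > 0).all()
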