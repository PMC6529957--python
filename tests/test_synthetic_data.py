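import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6atrio import (
    SimulationConfig,
    cis_eqtl_scan,
    differential_expression,
    enrichment_test,
    read_eqtl_summary,
    read_expression_matrix,
    read_genotypes,
    read_gwas_summary,
    read_m6a_sites,
    simulate_annotated_gwas,
    simulate_bundle,
    simulate_case_control_expression,
    simulate_eqtl_cohort,
    simulate_genotypes_ld,
    simulate_smr_scenario,
)
from m6atrio.synthetic_data import marginal_ols


class TestAnnotatedGwas:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_snps=500, seed=3)
        a = simulate_annotated_gwas(cfg)
        b = simulate_annotated_gwas(cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_null_construction_indistinguishable(self):
        cfg = SimulationConfig(n_snps=20_000, enrich_frac=0.0, seed=9)
        gwas, _, truth = simulate_annotated_gwas(cfg)
        m6a_p = gwas.loc[truth["is_m6a"].to_numpy(), "p"]
        bg_p = gwas.loc[~truth["is_m6a"].to_numpy(), "p"]
        _, p = stats.ks_2samp(m6a_p, bg_p)
        assert p > 0.01

    def test_zero_effect_mu_is_still_null(self):
        cfg = SimulationConfig(n_snps=20_000, enrich_frac=1.0, effect_mu=0.0, seed=10)
        gwas, _, truth = simulate_annotated_gwas(cfg)
        sig_rate = (gwas["p"] < 0.05).mean()
        assert abs(sig_rate - 0.05) < 0.01

    def test_planted_enrichment_is_detectable(self):
        cfg = SimulationConfig(n_snps=50_000, enrich_frac=0.1, effect_mu=2.5, seed=11)
        gwas, _, truth = simulate_annotated_gwas(cfg)
        m6a = gwas[truth["is_m6a"].to_numpy()]
        bg = gwas[~truth["is_m6a"].to_numpy()]
        res = enrichment_test(m6a, bg, B=200, seed=1)
        assert res.empirical_p < 0.05

    def test_truth_table_marks_enriched_subset_of_m6a(self):
        cfg = SimulationConfig(n_snps=2000, seed=3)
        _, _, truth = simulate_annotated_gwas(cfg)
        assert (truth["is_enriched"] & ~truth["is_m6a"]).sum() == 0


class TestGenotypesLd:
    def test_no_ld_when_rho_zero(self):
        cfg = SimulationConfig(ld_rho=0.0, seed=4)
        g = simulate_genotypes_ld(cfg, n_snps=50, n_samples=2000)
        r = np.corrcoef(g.to_numpy())
        adjacent = np.diag(r, k=1)
        assert np.max(adjacent**2) < 0.01

    def test_ld_decay_with_rho(self):
        cfg = SimulationConfig(ld_rho=0.9, seed=4)
        g = simulate_genotypes_ld(cfg, n_snps=50, n_samples=2000)
        r = np.corrcoef(g.to_numpy())
        assert np.mean(np.diag(r, k=1)) > np.mean(np.diag(r, k=5)) > 0

    def test_maf_recovery(self):
        cfg = SimulationConfig(seed=5)
        mafs = np.array([0.05, 0.1, 0.25, 0.4, 0.5])
        g = simulate_genotypes_ld(cfg, mafs=mafs, n_samples=2000)
        emp = g.mean(axis=1).to_numpy() / 2
        emp = np.minimum(emp, 1 - emp)
        se = np.sqrt(mafs * (1 - mafs) / (2 * 2000))
        assert np.all(np.abs(emp - mafs) < 4 * se + 1e-9)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=6)
        a = simulate_genotypes_ld(cfg, n_snps=20, n_samples=50)
        b = simulate_genotypes_ld(cfg, n_snps=20, n_samples=50)
        pd.testing.assert_frame_equal(a, b)


class TestEqtlCohort:
    def test_planted_beta_recovered(self):
        cfg = SimulationConfig(eqtl_beta=0.8, seed=7)
        g = simulate_genotypes_ld(cfg, n_snps=4, n_samples=200)
        expr, truth = simulate_eqtl_cohort(cfg, g)
        planted = truth[truth["planted"]].iloc[0]
        gene_pos = pd.DataFrame({"chrom": ["1"], "tss": [100]}, index=[planted["gene"]])
        snp_pos = pd.DataFrame({"chrom": ["1"], "pos": [100]}, index=[planted["snp"]])
        out = cis_eqtl_scan(expr, g, gene_pos, snp_pos)
        row = out.iloc[0]
        assert abs(row["beta"] - 0.8) < 3 * row["se"]

    def test_null_genes_give_uniform_p(self):
        cfg = SimulationConfig(eqtl_beta=0.0, seed=8)
        g = simulate_genotypes_ld(cfg, n_snps=100, n_samples=100, mafs=np.full(100, 0.3))
        expr, _ = simulate_eqtl_cohort(cfg, g, planted={})
        stats_df = marginal_ols(g.to_numpy(), expr.values.iloc[0].to_numpy())
        assert stats_df["p"].between(0, 1).all()

    def test_noise_scaling_leaves_beta_unbiased(self):
        cfg = SimulationConfig(eqtl_beta=0.8, seed=9)
        g = simulate_genotypes_ld(cfg, n_snps=2, n_samples=4000)
        expr, truth = simulate_eqtl_cohort(cfg, g)
        planted = truth[truth["planted"]].iloc[0]
        y = expr.values.loc[planted["gene"]].to_numpy()
        dos = g.loc[planted["snp"]].to_numpy()
        res1 = marginal_ols(dos[None, :], y).iloc[0]
        noise = y - 0.8 * dos
        res2 = marginal_ols(dos[None, :], 0.8 * dos + 2 * noise).iloc[0]
        assert res2["se"] == pytest.approx(2 * res1["se"], rel=0.01)
        assert abs(res2["beta"] - 0.8) < 3 * res2["se"]


class TestCaseControlExpression:
    def test_null_significant_fraction_near_alpha(self):
        cfg = SimulationConfig(n_genes=2000, de_delta=0.0, seed=12)
        expr, _ = simulate_case_control_expression(cfg)
        res = differential_expression(expr)
        assert abs(res["significant"].mean() - 0.05) < 0.02

    def test_power_matches_noncentral_t_formula(self):
        cfg = SimulationConfig(n_genes=4000, de_frac=0.5, de_delta=1.5, seed=13)
        expr, truth = simulate_case_control_expression(cfg)
        res = differential_expression(expr, equal_var=True).set_index("gene")
        detected = res.loc[truth[truth["is_de"]]["gene"], "significant"].mean()
        # closed-form two-sample t power, n=20/20, sd=1, delta=1.5
        df = 38
        ncp = 1.5 / np.sqrt(2 / 20)
        tcrit = stats.t.ppf(0.975, df)
        power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        assert detected == pytest.approx(power, abs=0.04)

    def test_label_permutation_collapses_to_null(self):
        cfg = SimulationConfig(n_genes=2000, de_frac=0.5, de_delta=1.5, seed=14)
        expr, _ = simulate_case_control_expression(cfg)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(expr.labels.to_numpy()),
                             index=expr.labels.index)
        from m6atrio import ExpressionMatrix
        res = differential_expression(ExpressionMatrix(expr.values, shuffled))
        assert res["significant"].mean() < 0.10


class TestSmrScenario:
    def test_null_mode_p_smr_uniformish(self):
        cfg = SimulationConfig(seed=15)
        ps = []
        for rep in range(40):
            sc = simulate_smr_scenario(cfg, mode="null", n_gwas=500, n_eqtl=500,
                                       n_panel=200, rng=cfg.rng(100 + rep))
            from m6atrio import run_smr
            res = run_smr(sc["gwas"], sc["eqtl"], sc["panel"])
            if len(res):
                ps.append(res.iloc[0]["p_smr"])
        assert (np.array(ps) < 0.05).mean() < 0.2

    def test_causal_snp_is_top_eqtl(self):
        cfg = SimulationConfig(seed=16)
        sc = simulate_smr_scenario(cfg)
        top = sc["eqtl"].nsmallest(1, "p").iloc[0]["snp"]
        assert top == sc["truth"]["causal_snp"]


class TestBundleRoundTrip:
    def test_bundle_files_load_through_readers(self, tmp_path):
        cfg = SimulationConfig(n_snps=1000, n_genes=50, seed=17)
        files = simulate_bundle(cfg, tmp_path / "bundle")
        gwas = read_gwas_summary(files["gwas"])
        sites = read_m6a_sites(files["m6a"])
        expr = read_expression_matrix(files["expr"], label_map=files["labels"])
        geno = read_genotypes(files["genotypes"])
        eqtl = read_eqtl_summary(files["eqtl"])
        panel = read_genotypes(files["panel"])
        truth = json.load(open(files["truth"]))
        assert len(gwas) == 1000
        assert len(sites) == truth["n_m6a"]
        assert expr.labels.value_counts().to_dict() == {"case": 20, "control": 20}
        assert set(eqtl["snp"]).issubset(set(gwas["snp"]))
        assert geno.shape[1] == cfg.n_samples
        assert panel.shape[0] == len(eqtl)

    def test_bundle_seed_determinism(self, tmp_path):
        cfg = SimulationConfig(n_snps=500, n_genes=20, seed=18)
        f1 = simulate_bundle(cfg, tmp_path / "a")
        f2 = simulate_bundle(cfg, tmp_path / "b")
        for k in ("gwas", "m6a", "expr", "eqtl", "panel"):
            assert open(f1[k]).read() == open(f2[k]).read()
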