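import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from m6atrio import (
    SimulationConfig,
    SummaryPair,
    align_alleles,
    heidi_test,
    ld_correlation,
    run_smr,
    select_heidi_instruments,
    simulate_smr_scenario,
    smr_statistic,
)
from m6atrio.exceptions import InputError


def pair(b_g=0.3, se_g=0.1, b_e=0.5, se_e=0.1, snp="rs1"):
    return SummaryPair(snp=snp, b_gwas=b_g, se_gwas=se_g, b_eqtl=b_e, se_eqtl=se_e)


def gwas_row(snp="rs1", a1="A", a2="G", beta=0.3, se=0.1):
    return pd.Series({"snp": snp, "effect_allele": a1, "other_allele": a2,
                      "beta": beta, "se": se})


def eqtl_row(ea="A", beta=0.5, se=0.1):
    return pd.Series({"snp": "rs1", "gene": "G1", "effect_allele": ea,
                      "beta": beta, "se": se})


class TestAlignAlleles:
    def test_same_effect_allele_unchanged(self):
        p = align_alleles(gwas_row(), eqtl_row(ea="A"))
        assert p.b_eqtl == 0.5

    def test_swapped_alleles_negate_beta(self):
        p = align_alleles(gwas_row(), eqtl_row(ea="G"))
        assert p.b_eqtl == -0.5

    @pytest.mark.parametrize("ea,expected_sign", [
        ("A", +1), ("G", -1),   # direct match / swap
        ("T", +1), ("C", -1),   # strand-complement match / swap
    ])
    def test_four_allele_configurations(self, ea, expected_sign):
        p = align_alleles(gwas_row(a1="A", a2="G"), eqtl_row(ea=ea))
        assert np.sign(p.b_eqtl) == expected_sign

    def test_irreconcilable_pair_excluded(self):
        assert align_alleles(gwas_row(a1="A", a2="G"), eqtl_row(ea="X")) is None

    def test_palindromic_snp_flagged_and_droppable(self):
        g = gwas_row(a1="A", a2="T")
        kept = align_alleles(g, eqtl_row(ea="A"))
        assert kept.ambiguous
        assert align_alleles(g, eqtl_row(ea="A"), drop_ambiguous=True) is None


class TestSmrStatistic:
    def test_equal_z_symmetry(self):
        # z_g = z_e = 3 -> t = 9/2
        _, _, t, _ = smr_statistic(pair(b_g=0.3, se_g=0.1, b_e=0.3, se_e=0.1))
        assert t == pytest.approx(4.5)

    def test_noise_free_instrument_limit(self):
        _, _, t, _ = smr_statistic(pair(b_g=0.3, se_g=0.1, b_e=0.5, se_e=1e-9))
        assert t == pytest.approx(9.0, rel=1e-6)

    def test_worked_example_against_chi2_oracle(self):
        # z_g = 3, z_e = 5 -> t = 225/34
        b_xy, se_xy, t, p = smr_statistic(pair(b_g=0.3, se_g=0.1, b_e=0.5, se_e=0.1))
        assert t == pytest.approx(225 / 34)
        assert p == pytest.approx(float(stats.chi2.sf(225 / 34, 1)))
        assert b_xy == pytest.approx(0.6)
        assert (b_xy / se_xy) ** 2 == pytest.approx(t)

    def test_null_instrument_rejected(self):
        with pytest.raises(InputError):
            smr_statistic(pair(b_e=0.0))

    @settings(max_examples=200, deadline=None)
    @given(z_g=st.floats(-20, 20), z_e=st.floats(-20, 20))
    def test_bounded_by_weaker_z(self, z_g, z_e):
        if abs(z_e) < 1e-6:
            return
        _, _, t, _ = smr_statistic(pair(b_g=z_g * 0.1, se_g=0.1,
                                        b_e=z_e * 0.1, se_e=0.1))
        assert t <= min(z_g**2, z_e**2) + 1e-9

    def test_b_xy_unit_invariance(self):
        # rescaling expression units rescales b_xy inversely; b_xy * scale constant
        a = smr_statistic(pair(b_e=0.5, se_e=0.1))
        b = smr_statistic(pair(b_e=1.0, se_e=0.2))
        assert a[0] * 0.5 == pytest.approx(b[0] * 1.0)
        assert a[2] == pytest.approx(b[2])  # t unchanged


class TestInstrumentSelection:
    def _ld(self, snps, r_with_top):
        n = len(snps)
        m = np.eye(n)
        m[0, 1:] = m[1:, 0] = r_with_top
        return pd.DataFrame(m, index=snps, columns=snps)

    def test_top_snp_always_excluded(self):
        snps = ["top", "a", "b"]
        eqtls = pd.DataFrame({"snp": snps, "p": [1e-9, 1e-5, 1e-5]})
        ld = self._ld(snps, 0.5)
        out = select_heidi_instruments(eqtls, "top", ld)
        assert "top" not in out

    def test_collinear_candidate_excluded(self):
        snps = ["top", "a"]
        eqtls = pd.DataFrame({"snp": snps, "p": [1e-9, 1e-5]})
        ld = self._ld(snps, np.sqrt(0.95))
        assert select_heidi_instruments(eqtls, "top", ld) == []

    def test_weak_ld_candidate_excluded(self):
        snps = ["top", "a"]
        eqtls = pd.DataFrame({"snp": snps, "p": [1e-9, 1e-5]})
        ld = self._ld(snps, np.sqrt(0.04))
        assert select_heidi_instruments(eqtls, "top", ld) == []

    def test_truncation_to_smallest_p(self):
        snps = ["top"] + [f"s{i}" for i in range(30)]
        ps = [1e-12] + list(np.linspace(1e-6, 1e-4, 30))
        eqtls = pd.DataFrame({"snp": snps, "p": ps})
        ld = self._ld(snps, 0.5)
        out = select_heidi_instruments(eqtls, "top", ld, m_max=20)
        assert len(out) == 20
        expected = eqtls.iloc[1:].nsmallest(20, "p")["snp"]
        assert set(out) == set(expected)

    def test_missing_top_snp_rejected(self):
        eqtls = pd.DataFrame({"snp": ["a"], "p": [1e-5]})
        ld = pd.DataFrame(np.eye(1), index=["a"], columns=["a"])
        with pytest.raises(InputError):
            select_heidi_instruments(eqtls, "top", ld)


class TestHeidi:
    def _pairs(self, b_xys, z_e=10.0, se_g=0.1):
        # construct pairs whose ratio estimates are exactly b_xys
        rows = []
        for i, bxy in enumerate(b_xys):
            b_e = 0.5
            rows.append({"snp": f"s{i}", "b_gwas": bxy * b_e, "se_gwas": se_g,
                         "b_eqtl": b_e, "se_eqtl": b_e / z_e})
        return pd.DataFrame(rows).set_index("snp")

    def test_identical_ratios_give_p_one(self):
        pairs = self._pairs([0.4, 0.4, 0.4, 0.4])
        ld = pd.DataFrame(np.eye(4), index=pairs.index, columns=pairs.index)
        t, p, n = heidi_test(pairs, ld, "s0")
        assert t == 0
        assert p == 1
        assert n == 3

    def test_identity_ld_reduces_to_plain_chi_square(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pairs = self._pairs(0.4 + 0.05 * rng.standard_normal(5))
            ld = pd.DataFrame(np.eye(5), index=pairs.index, columns=pairs.index)
            t, p, n = heidi_test(pairs, ld, "s0")
            assert n == 4
            assert p == pytest.approx(float(stats.chi2.sf(t, n)), rel=1e-9)

    def test_zero_instruments_gives_missing_p(self):
        pairs = self._pairs([0.4])
        ld = pd.DataFrame(np.eye(1), index=pairs.index, columns=pairs.index)
        _, p, n = heidi_test(pairs, ld, "s0")
        assert np.isnan(p)
        assert n == 0


class TestRunSmr:
    def test_planted_effect_recovered(self):
        cfg = SimulationConfig(seed=4, causal_gamma=0.5)
        sc = simulate_smr_scenario(cfg, mode="causal")
        res = run_smr(sc["gwas"], sc["eqtl"], sc["panel"])
        assert len(res) == 1
        row = res.iloc[0]
        assert abs(row["b_xy"] - 0.5) < 3 * row["se_xy"]
        assert row["p_smr"] < 1e-6

    def test_gene_without_gwas_records_skipped(self):
        cfg = SimulationConfig(seed=4)
        sc = simulate_smr_scenario(cfg)
        gwas = sc["gwas"].copy()
        gwas["snp"] = "other_" + gwas["snp"]
        res = run_smr(gwas, sc["eqtl"], sc["panel"])
        assert res.empty

    def test_snp_order_invariance(self):
        cfg = SimulationConfig(seed=5)
        sc = simulate_smr_scenario(cfg)
        res1 = run_smr(sc["gwas"], sc["eqtl"], sc["panel"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sc["eqtl"]))
        res2 = run_smr(sc["gwas"].iloc[::-1], sc["eqtl"].iloc[perm], sc["panel"])
        pd.testing.assert_frame_equal(res1, res2)

    def test_missing_beta_rejected(self):
        cfg = SimulationConfig(seed=5)
        sc = simulate_smr_scenario(cfg)
        gwas = sc["gwas"].drop(columns=["beta", "se"])
        with pytest.raises(InputError):
            run_smr(gwas, sc["eqtl"], sc["panel"])

    def test_linkage_architecture_flagged_by_heidi(self):
        cfg = SimulationConfig(seed=6)
        causal = run_smr(*[simulate_smr_scenario(cfg, mode="causal")[k]
                           for k in ("gwas", "eqtl", "panel")])
        linked = run_smr(*[simulate_smr_scenario(cfg, mode="linkage",
                                                 rng=cfg.rng(77))[k]
                           for k in ("gwas", "eqtl", "panel")])
        assert linked.iloc[0]["p_heidi"] < causal.iloc[0]["p_heidi"]
        assert linked.iloc[0]["p_heidi"] < 0.05


class TestLdCorrelation:
    def test_diagonal_is_one_and_symmetric(self):
        cfg = SimulationConfig(seed=2)
        sc = simulate_smr_scenario(cfg)
        ld = ld_correlation(sc["panel"], list(sc["panel"].index[:5]))
        assert np.allclose(np.diag(ld), 1.0)
        assert np.allclose(ld, ld.T)

    def test_missing_snp_rejected(self):
        cfg = SimulationConfig(seed=2)
        sc = simulate_smr_scenario(cfg)
        with pytest.raises(InputError):
            ld_correlation(sc["panel"], ["nope"])
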