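"""Summary-data Mendelian randomization (SMR) with the HEIDI heterogeneity test.

Given per-SNP GWAS summary statistics (b_gwas, se_gwas) and cis-eQTL summary
statistics (b_eqtl, se_eqtl) on the same effect allele, the SMR estimate of
the effect of gene expression on the trait at a single instrument is the Wald
ratio b_xy = b_gwas / b_eqtl.  With z_g = b_gwas/se_gwas and
z_e = b_eqtl/se_eqtl the test statistic is

    T_SMR = z_g^2 * z_e^2 / (z_g^2 + z_e^2),

compared to a 1-df chi-square; T_SMR <= min(z_g^2, z_e^2) always, and the
statistic approaches z_g^2 as the instrument becomes noise-free.

A significant SMR association is compatible with two genetic architectures:
one variant affecting both expression and trait (pleiotropy/causality), or two
distinct variants in linkage.  HEIDI discriminates them: under the
single-variant model every SNP in LD with the top eQTL estimates the same
b_xy, so for each instrument i the difference d_i = b_xy(i) - b_xy(top) is
zero in expectation.  Each d_i is standardised by its first-order delta-method
standard error (including the covariance with the top-SNP ratio induced by
LD), and T_HEIDI = sum z_i^2 is referred to the distribution of a correlated
chi-square sum: the correlation of (z_i, z_j) is approximated by the LD
correlation r_ij of the instruments, and the weighted sum of 1-df chi-squares
implied by the eigenvalues of that matrix is evaluated by two-moment
(Satterthwaite) matching.  P_HEIDI > 0.05 means no detectable heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

logger = logging.getLogger(__name__)

#: eQTL instrument threshold: chi-square(1) > 10, the conventional cutoff.
P_INSTRUMENT = float(stats.chi2.sf(10.0, 1))  # ~1.57e-3

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SmrThresholds:
    """Tunable thresholds for instrument selection and HEIDI."""

    p_instr: float = P_INSTRUMENT
    r2_min: float = 0.05
    r2_max: float = 0.90
    m_max: int = 20
    min_heidi_instruments: int = 3


@dataclass
class SummaryPair:
    """GWAS and eQTL effects for one SNP, aligned to a common effect allele."""

    snp: str
    b_gwas: float
    se_gwas: float
    b_eqtl: float
    se_eqtl: float
    aligned: bool = True
    ambiguous: bool = False  # strand-ambiguous A/T or C/G SNP


def align_alleles(gwas_row, eqtl_row, drop_ambiguous: bool = False) -> SummaryPair | None:
    """Put the eQTL effect on the GWAS effect allele; returns None if irreconcilable.

    The eQTL beta sign is flipped when its effect allele equals the GWAS other
    allele (directly or via strand complement).  Strand-ambiguous SNPs
    (A/T or C/G) are flagged and dropped only when ``drop_ambiguous``.
    """
    snp = gwas_row["snp"] if "snp" in gwas_row else gwas_row.name
    a1 = str(gwas_row["effect_allele"]).upper()
    a2 = str(gwas_row["other_allele"]).upper()
    ea = str(eqtl_row["effect_allele"]).upper()
    ambiguous = a2 == _COMPLEMENT.get(a1)

    if ea == a1:
        sign = 1.0
    elif ea == a2:
        sign = -1.0
    elif ea == _COMPLEMENT.get(a1):
        sign = 1.0
    elif ea == _COMPLEMENT.get(a2):
        sign = -1.0
    else:
        logger.info("align_alleles: irreconcilable alleles for %s (%s/%s vs %s)",
                    snp, a1, a2, ea)
        return None
    if ambiguous and drop_ambiguous:
        logger.info("align_alleles: dropping strand-ambiguous SNP %s", snp)
        return None
    return SummaryPair(
        snp=str(snp),
        b_gwas=float(gwas_row["beta"]), se_gwas=float(gwas_row["se"]),
        b_eqtl=sign * float(eqtl_row["beta"]), se_eqtl=float(eqtl_row["se"]),
        aligned=True, ambiguous=ambiguous,
    )


def smr_statistic(pair: SummaryPair) -> tuple[float, float, float, float]:
    """(b_xy, se_xy, t_smr, p_smr) for one aligned SNP."""
    if not pair.aligned:
        raise InputError("pair must be allele-aligned before testing")
    if pair.b_eqtl == 0:
        raise InputError("instrument has no effect (b_eqtl = 0)")
    z_g = pair.b_gwas / pair.se_gwas
    z_e = pair.b_eqtl / pair.se_eqtl
    if z_e == 0:
        raise InputError("instrument has no effect (z_e = 0)")
    b_xy = pair.b_gwas / pair.b_eqtl
    t_smr = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    p_smr = float(stats.chi2.sf(t_smr, 1))
    se_xy = abs(b_xy) / np.sqrt(t_smr) if t_smr > 0 else np.inf
    return float(b_xy), float(se_xy), float(t_smr), p_smr


def ld_correlation(panel: pd.DataFrame, snps) -> pd.DataFrame:
    """Pearson dosage correlation matrix for ``snps`` from a reference panel."""
    snps = [s for s in snps]
    missing = [s for s in snps if s not in panel.index]
    if missing:
        raise InputError(f"SNP(s) absent from LD panel: {missing[:5]}")
    sub = panel.loc[snps]
    if sub.isna().any().any():
        r = sub.T.corr()  # pairwise-complete
    else:
        r = pd.DataFrame(np.corrcoef(sub.to_numpy()), index=snps, columns=snps)
    return r


def select_heidi_instruments(
    cis_eqtls: pd.DataFrame,
    top_snp: str,
    ld: pd.DataFrame,
    r2_min: float = 0.05,
    r2_max: float = 0.90,
    p_instr: float = P_INSTRUMENT,
    m_max: int = 20,
) -> list[str]:
    """Pick HEIDI instruments around ``top_snp``.

    Candidates (never the top SNP itself) need eQTL p < ``p_instr`` and an LD
    r^2 with the top SNP inside [r2_min, r2_max] (the upper bound guards
    against collinearity); the ``m_max`` smallest eQTL P values are kept.
    """
    if top_snp not in ld.index:
        raise InputError(f"top SNP {top_snp!r} absent from LD matrix")
    cand = cis_eqtls[(cis_eqtls["snp"] != top_snp) & (cis_eqtls["p"] < p_instr)]
    cand = cand[cand["snp"].isin(ld.index)]
    r2 = ld.loc[top_snp, cand["snp"]].to_numpy() ** 2
    cand = cand[(r2 >= r2_min) & (r2 <= r2_max)]
    cand = cand.sort_values(["p", "snp"], kind="mergesort").head(m_max)
    return list(cand["snp"])


def _ratio_cov(pairs: pd.DataFrame, i, j, r_ij: float) -> float:
    """First-order covariance of the Wald ratios at SNPs i and j (shared GWAS
    and shared eQTL cohorts; the two cohorts independent of each other)."""
    bi, bj = pairs.loc[i], pairs.loc[j]
    return r_ij * (
        bi["se_gwas"] * bj["se_gwas"] / (bi["b_eqtl"] * bj["b_eqtl"])
        + bi["b_gwas"] * bj["b_gwas"] * bi["se_eqtl"] * bj["se_eqtl"]
        / (bi["b_eqtl"] ** 2 * bj["b_eqtl"] ** 2)
    )


def heidi_test(pairs: pd.DataFrame, ld: pd.DataFrame, top_snp: str
               ) -> tuple[float, float, int]:
    """(t_heidi, p_heidi, n_used) from aligned summary pairs for top + instruments.

    ``pairs`` is indexed by snp with columns b_gwas, se_gwas, b_eqtl, se_eqtl
    and must contain ``top_snp``; every other row is an instrument.
    """
    instruments = [s for s in pairs.index if s != top_snp]
    if not instruments:
        return 0.0, float("nan"), 0
    b_xy = pairs["b_gwas"] / pairs["b_eqtl"]
    var = (
        pairs["se_gwas"] ** 2 / pairs["b_eqtl"] ** 2
        + pairs["b_gwas"] ** 2 * pairs["se_eqtl"] ** 2 / pairs["b_eqtl"] ** 4
    )
    v_top = float(var.loc[top_snp])

    z = np.empty(len(instruments))
    for k, s in enumerate(instruments):
        d = float(b_xy.loc[s] - b_xy.loc[top_snp])
        c = _ratio_cov(pairs, s, top_snp, float(ld.loc[s, top_snp]))
        v_d = float(var.loc[s]) + v_top - 2.0 * c
        v_d = max(v_d, 1e-3 * (float(var.loc[s]) + v_top))  # guard near-collinear LD
        z[k] = d / np.sqrt(v_d)

    t_heidi = float(np.sum(z**2))
    if t_heidi <= 0:
        return 0.0, 1.0, len(instruments)

    corr = ld.loc[instruments, instruments].to_numpy(dtype=float)
    corr = (corr + corr.T) / 2.0
    lam = np.linalg.eigvalsh(corr)
    lam = lam[lam > 1e-10]
    s1, s2 = lam.sum(), float((lam**2).sum())
    # two-moment match: T ~ scale * chi2(df)
    scale = s2 / s1
    df = s1**2 / s2
    p = float(stats.chi2.sf(t_heidi / scale, df))
    return t_heidi, p, len(instruments)


def run_smr(
    gwas: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    ld_panel: pd.DataFrame,
    thresholds: SmrThresholds | None = None,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """SMR + HEIDI for every gene in ``eqtl_table``.

    Per gene: keep cis-eQTLs with a GWAS record and reconcilable alleles, take
    the smallest-P eQTL passing the instrument threshold as the top SNP,
    compute the SMR statistic, then HEIDI over LD-selected instruments
    (reported only when >= ``min_heidi_instruments`` qualify).  LD comes from
    the reference panel dosages.  Genes with no qualifying instrument, or
    whose top SNP is missing from the panel, are skipped with a log message.
    """
    th = thresholds or SmrThresholds()
    need = {"beta", "se"}
    if not need.issubset(gwas.columns) or gwas[["beta", "se"]].isna().any().any():
        raise InputError("SMR requires GWAS beta and se for all records")
    g = gwas.set_index("snp")

    rows = []
    for gene, sub in sorted(eqtl_table.groupby("gene"), key=lambda kv: kv[0]):
        sub = sub.sort_values(["p", "snp"], kind="mergesort")
        aligned: dict[str, SummaryPair] = {}
        keep_rows = []
        for _, er in sub.iterrows():
            snp = er["snp"]
            if snp not in g.index or snp in aligned:
                continue
            pair = align_alleles(g.loc[snp], er, drop_ambiguous=drop_ambiguous)
            if pair is None:
                continue
            aligned[snp] = pair
            keep_rows.append(er)
        if not keep_rows:
            logger.info("run_smr: gene %s has no usable cis-eQTL; skipped", gene)
            continue
        cis = pd.DataFrame(keep_rows)
        passing = cis[cis["p"] < th.p_instr]
        if passing.empty:
            logger.info("run_smr: gene %s has no instrument with p < %.3g; skipped",
                        gene, th.p_instr)
            continue
        top = passing.iloc[0]["snp"]
        b_xy, se_xy, t_smr, p_smr = smr_statistic(aligned[top])

        p_heidi, n_heidi = float("nan"), 0
        panel_snps = [s for s in cis["snp"] if s in ld_panel.index]
        if top in panel_snps:
            ld = ld_correlation(ld_panel, panel_snps)
            instr = select_heidi_instruments(
                cis, top, ld, r2_min=th.r2_min, r2_max=th.r2_max,
                p_instr=th.p_instr, m_max=th.m_max,
            )
            if len(instr) >= th.min_heidi_instruments:
                pairs = pd.DataFrame(
                    [vars(aligned[s]) for s in [top] + instr]
                ).set_index("snp")
                _, p_heidi, n_heidi = heidi_test(pairs, ld, top)
        else:
            logger.info("run_smr: top SNP %s for gene %s absent from LD panel", top, gene)

        rows.append({"gene": gene, "top_snp": top, "b_xy": b_xy, "se_xy": se_xy,
                     "t_smr": t_smr, "p_smr": p_smr, "p_heidi": p_heidi,
                     "n_heidi": n_heidi})
    cols = ["gene", "top_snp", "b_xy", "se_xy", "t_smr", "p_smr", "p_heidi", "n_heidi"]
    return pd.DataFrame(rows, columns=cols)
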