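"""Case/control differential expression and additive-genotype cis-eQTL tests.

Differential expression compares mean log-scale signals between cases and
controls gene-by-gene with a two-sided two-sample t-test (Welch by default;
``equal_var=True`` gives the pooled-variance Student variant).  The eQTL test
is ordinary least squares of expression on allele dosage (0/1/2) with an
intercept, the standard additive model; cis pairs are SNPs within a window of
the gene's transcription start site on the same chromosome (default 1 Mb).
No covariate adjustment and no within-module multiple-testing correction are
applied; downstream reporting applies Bonferroni where appropriate.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # bp, TSS-to-SNP


def differential_expression(
    expr: ExpressionMatrix, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Per-gene two-sided t-test of case vs control mean expression.

    Returns a frame with gene, mean_case, mean_control, t, p, n_case,
    n_control, significant (p < alpha strictly).  Genes with identical group
    means and no variance get t=0, p=1; genes where the statistic is undefined
    (a zero-variance group at n=2 under Welch) get p=NaN and are logged.
    """
    if expr.labels is None:
        raise InputError("differential_expression requires case/control labels")
    case = expr.values.loc[:, expr.labels == "case"]
    ctrl = expr.values.loc[:, expr.labels == "control"]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InputError("need >= 2 samples per group")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    diff = case.mean(axis=1).to_numpy() - ctrl.mean(axis=1).to_numpy()
    degenerate = (diff == 0) & ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    n_bad = int((~np.isfinite(p)).sum())
    if n_bad:
        logger.info("differential_expression: %d gene(s) with undefined t-test", n_bad)

    return pd.DataFrame({
        "gene": expr.gene_ids,
        "mean_case": case.mean(axis=1).to_numpy(),
        "mean_control": ctrl.mean(axis=1).to_numpy(),
        "t": t,
        "p": p,
        "n_case": case.shape[1],
        "n_control": ctrl.shape[1],
        "significant": p < alpha,
    })


class RegressionResult(NamedTuple):
    beta: float
    se: float
    t: float
    p: float
    n: int
    perfect_fit: bool = False


def regress_additive(dosages, values) -> RegressionResult:
    """OLS of expression on allele dosage with intercept; two-sided slope P.

    Missing pairs are dropped.  Requires >= 3 complete samples and >= 2
    distinct dosage values.  A perfect fit (zero residual variance) reports
    the smallest positive P and sets ``perfect_fit``.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(g) & np.isfinite(y)
    g, y = g[keep], y[keep]
    n = len(g)
    if n < 3:
        raise InputError(f"need >= 3 complete samples, got {n}")
    if len(np.unique(g)) < 2:
        raise InputError("no genotype variance (monomorphic dosages)")

    res = stats.linregress(g, y)
    if res.stderr == 0:
        return RegressionResult(float(res.slope), 0.0, float("inf"),
                                float(np.finfo(float).tiny), n, True)
    t = res.slope / res.stderr
    return RegressionResult(float(res.slope), float(res.stderr), float(t),
                            float(res.pvalue), n)


def cis_eqtl_scan(
    expr: ExpressionMatrix,
    genotypes: pd.DataFrame,
    gene_positions: pd.DataFrame,
    snp_positions: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Additive regression for every (SNP, gene) pair within ``window`` of the TSS.

    ``gene_positions``: indexed by gene with columns chrom, tss.
    ``snp_positions``: indexed by snp with columns chrom, pos.
    Pairs are formed on the same chromosome with |pos - tss| <= window and
    tested on the samples shared between ``expr`` and ``genotypes``.
    """
    shared = [s for s in expr.sample_ids if s in genotypes.columns]
    if not shared:
        raise InputError("no overlapping samples between expression and genotypes")

    gp = gene_positions.loc[gene_positions.index.isin(expr.gene_ids)].copy()
    sp = snp_positions.loc[snp_positions.index.isin(genotypes.index)].copy()
    gp["chrom"] = gp["chrom"].astype(str)
    sp["chrom"] = sp["chrom"].astype(str)
    pairs = (
        gp.reset_index(names="gene")
        .merge(sp.reset_index(names="snp"), on="chrom")
    )
    pairs["distance_to_tss"] = (pairs["pos"] - pairs["tss"]).astype(int)
    pairs = pairs[pairs["distance_to_tss"].abs() <= window]

    rows = []
    vals = expr.values[shared]
    geno = genotypes[shared]
    for gene, snp, dist in pairs[["gene", "snp", "distance_to_tss"]].itertuples(index=False):
        try:
            r = regress_additive(geno.loc[snp], vals.loc[gene])
        except InputError as exc:
            logger.info("cis_eqtl_scan: skipping (%s, %s): %s", snp, gene, exc)
            continue
        rows.append({"snp": snp, "gene": gene, "beta": r.beta, "se": r.se,
                     "t": r.t, "p": r.p, "n": r.n, "distance_to_tss": dist})
    cols = ["snp", "gene", "beta", "se", "t", "p", "n", "distance_to_tss"]
    return pd.DataFrame(rows, columns=cols)


def eqtl_lookup(snps, eqtl_table: pd.DataFrame) -> pd.DataFrame:
    """All rows of an external eQTL summary table whose snp is in ``snps``.

    Used to attach published eQTL evidence to candidate SNPs; duplicates are
    returned as-is (deduplicate with :func:`dedup_min_p` downstream).
    """
    snps = set(snps)
    return eqtl_table[eqtl_table["snp"].isin(snps)].reset_index(drop=True)


def dedup_min_p(eqtl_table: pd.DataFrame, by=("snp", "gene")) -> pd.DataFrame:
    """Keep the minimum-P row per key (the configured downstream dedup rule)."""
    return (
        eqtl_table.sort_values("p", kind="mergesort")
        .drop_duplicates(list(by), keep="first")
        .reset_index(drop=True)
    )
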