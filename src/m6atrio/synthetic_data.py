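"""Seed-deterministic generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study designs the
pipeline targets: genome-wide GWAS summary statistics annotated with an
m6A-SNP list (with an optional planted enrichment of nominal hits among
m6A-SNPs), an LD-structured genotype reference panel, a small eQTL validation
cohort, a 20-case / 20-control expression matrix, and an end-to-end SMR
scenario in which expression mediates a trait effect.  Every generator takes
its randomness from the config seed and returns a machine-readable truth
table recording what was planted.

Models
------
GWAS            : per-SNP z ~ N(0,1) under the null; an enriched subset of
                  m6A-SNPs gets z ~ N(effect_mu, 1) with random sign; two-sided
                  P.  Summary beta = z * se with unit se (P is the only
                  quantity the enrichment stage consumes).
MAF             : uniform on (0.01, 0.5), or drawn from the six-bin histogram
                  583:663:1064:720:628:539 ("binned").
LD genotypes    : two haplotypes per sample; each haplotype thresholds a
                  latent AR(1) Gaussian (corr rho^|i-j|) at the SNP's MAF
                  quantile; dosage = haplotype sum.
eQTL cohort     : expression = eqtl_beta * dosage + N(0,1) for planted pairs.
Case/control    : gene signals N(0,1); a de_frac fraction of genes shifted by
                  de_delta in cases.
SMR scenario    : expression = b_eqtl * g_causal + noise in an eQTL cohort;
                  trait = causal_gamma * expression + noise in an independent
                  GWAS cohort; summary statistics from per-SNP OLS; a third
                  independent cohort is exported as the LD panel.  The
                  "linkage" arm drives the trait through a different SNP in LD
                  with the eQTL variant, the architecture HEIDI must reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ExpressionMatrix,
    write_eqtl_summary,
    write_expression_matrix,
    write_genotypes,
    write_gwas_summary,
    write_m6a_sites,
)

#: Published m6A-SNP confidence-level composition (high, medium, low).
CONFIDENCE_WEIGHTS = (13703, 54222, 284089)
#: Per-bin m6A-SNP counts used for the frequency-matched null (six MAF bins).
BIN_WEIGHTS = (583, 663, 1064, 720, 628, 539)


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults mirror the emulated study designs."""

    n_snps: int = 50_000        # GWAS SNPs (desk-scale stand-in for genome-wide)
    frac_m6a: float = 0.08      # fraction annotated as m6A-SNPs (~4,000 of 50,000)
    enrich_frac: float = 0.10   # fraction of m6A-SNPs given a shifted effect
    effect_mu: float = 2.5      # mean |z| of shifted SNPs (z-score units)
    maf_law: str = "uniform"    # "uniform" on (0.01,0.5) or "binned"
    n_samples: int = 40         # eQTL validation cohort size
    ld_rho: float = 0.8         # adjacent-SNP latent correlation decay
    n_genes: int = 2000         # genes in the case/control expression matrix
    de_frac: float = 0.05       # fraction of genes differentially expressed
    de_delta: float = 1.5       # case-group mean shift (log-signal units)
    n_case: int = 20
    n_control: int = 20
    eqtl_beta: float = 0.8      # expression change per effect-allele copy
    causal_gamma: float = 0.5   # expression -> trait effect
    seed: int = 0

    def rng(self, salt: int) -> np.random.Generator:
        """Independent stream per generator, all derived from the one seed."""
        return np.random.default_rng([int(salt), int(self.seed) % 2**31])


def _draw_maf(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.maf_law == "uniform":
        return rng.uniform(0.01, 0.5, size=n)
    if cfg.maf_law == "binned":
        edges = np.array([0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50])
        w = np.asarray(BIN_WEIGHTS, dtype=float)
        bins = rng.choice(len(w), size=n, p=w / w.sum())
        return rng.uniform(edges[bins], edges[bins + 1])
    raise ValueError(f"unknown maf_law {cfg.maf_law!r}")


def _alleles(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    a1 = rng.integers(0, 4, size=n)
    a2 = (a1 + rng.integers(1, 4, size=n)) % 4
    return bases[a1], bases[a2]


def simulate_annotated_gwas(cfg: SimulationConfig, trait: str = "AIS"
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(gwas, m6a_sites, truth): summary stats, the matching site list, and the
    planted-effect table."""
    rng = cfg.rng(1)
    n = cfg.n_snps
    snp = np.array([f"rs{i + 1}" for i in range(n)])
    chrom = rng.integers(1, 23, size=n).astype(str)
    pos = rng.integers(1, 250_000_000, size=n)
    maf = _draw_maf(cfg, n, rng)
    flip = rng.random(n) < 0.5
    eaf = np.where(flip, maf, 1.0 - maf)
    a1, a2 = _alleles(n, rng)

    is_m6a = np.zeros(n, dtype=bool)
    m6a_idx = rng.choice(n, size=int(round(cfg.frac_m6a * n)), replace=False)
    is_m6a[m6a_idx] = True
    is_enriched = np.zeros(n, dtype=bool)
    n_enriched = int(round(cfg.enrich_frac * len(m6a_idx)))
    if n_enriched:
        is_enriched[rng.choice(m6a_idx, size=n_enriched, replace=False)] = True

    z = rng.standard_normal(n)
    if n_enriched:
        shift = rng.normal(cfg.effect_mu, 1.0, size=n_enriched)
        sign = np.where(rng.random(n_enriched) < 0.5, -1.0, 1.0)
        z[is_enriched] = sign * shift
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    gwas = pd.DataFrame({
        "snp": snp, "chrom": chrom, "pos": pos, "effect_allele": a1,
        "other_allele": a2, "eaf": eaf, "beta": z, "se": np.ones(n), "p": p,
        "maf": maf, "trait": trait,
    })

    mi = np.sort(m6a_idx)
    sites = pd.DataFrame({
        "m6a_id": [f"m6A_ID_{i + 1}" for i in mi],
        "snp": snp[mi],
        "chrom": chrom[mi],
        "site_pos": pos[mi] + rng.integers(-25, 26, size=len(mi)),
        "confidence": rng.choice(
            ["high", "medium", "low"], size=len(mi),
            p=np.asarray(CONFIDENCE_WEIGHTS) / sum(CONFIDENCE_WEIGHTS)),
        "effect": rng.choice(["Gain", "Loss"], size=len(mi)),
    })
    truth = pd.DataFrame({"snp": snp, "is_m6a": is_m6a, "is_enriched": is_enriched,
                          "z": z, "seed": cfg.seed})
    return gwas, sites, truth


def simulate_genotypes_ld(
    cfg: SimulationConfig,
    n_snps: int | None = None,
    n_samples: int | None = None,
    mafs: np.ndarray | None = None,
    snp_ids=None,
    sample_prefix: str = "S",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """SNPs x samples dosage matrix with AR(1)-style LD at decay ``ld_rho``."""
    rng = rng if rng is not None else cfg.rng(2)
    m = n_snps if n_snps is not None else (len(mafs) if mafs is not None else 100)
    n = n_samples if n_samples is not None else cfg.n_samples
    if mafs is None:
        mafs = _draw_maf(cfg, m, rng)
    thresholds = stats.norm.ppf(np.asarray(mafs))

    def haplotypes() -> np.ndarray:
        x = np.empty((m, n))
        x[0] = rng.standard_normal(n)
        rho = cfg.ld_rho
        innov = rng.standard_normal((m - 1, n)) * np.sqrt(max(1.0 - rho**2, 0.0))
        for k in range(1, m):
            x[k] = rho * x[k - 1] + innov[k - 1]
        return (x < thresholds[:, None]).astype(float)

    dosage = haplotypes() + haplotypes()
    ids = snp_ids if snp_ids is not None else [f"snp{k + 1}" for k in range(m)]
    cols = [f"{sample_prefix}{j + 1}" for j in range(n)]
    out = pd.DataFrame(dosage, index=ids, columns=cols)
    out.index.name = "snp"
    return out


def simulate_eqtl_cohort(
    cfg: SimulationConfig,
    genotypes: pd.DataFrame,
    planted: dict[str, str] | None = None,
    n_noise_genes: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """(expression, truth) for the genotyped cohort.

    ``planted`` maps SNP id -> gene id; each planted gene's expression is
    ``eqtl_beta * dosage + N(0,1)``.  By default every other SNP gets a
    planted gene (alternating), the rest pure-noise genes; ``n_noise_genes``
    extra noise genes can be appended.
    """
    rng = rng if rng is not None else cfg.rng(3)
    snps = list(genotypes.index)
    if planted is None:
        planted = {s: f"GENE_{s}" for i, s in enumerate(snps) if i % 2 == 0}
    samples = list(genotypes.columns)
    rows, genes, truth = [], [], []
    for i, s in enumerate(snps):
        gene = planted.get(s, f"GENE_{s}")
        is_planted = s in planted
        noise = rng.standard_normal(len(samples))
        vals = cfg.eqtl_beta * genotypes.loc[s].to_numpy() + noise if is_planted else noise
        genes.append(gene)
        rows.append(vals)
        truth.append({"gene": gene, "snp": s, "planted": is_planted,
                      "beta": cfg.eqtl_beta if is_planted else 0.0})
    for k in range(n_noise_genes):
        genes.append(f"NOISE_{k + 1}")
        rows.append(rng.standard_normal(len(samples)))
        truth.append({"gene": genes[-1], "snp": None, "planted": False, "beta": 0.0})
    values = pd.DataFrame(rows, index=genes, columns=samples)
    values.index.name = "gene"
    return ExpressionMatrix(values=values), pd.DataFrame(truth)


def simulate_case_control_expression(
    cfg: SimulationConfig, rng: np.random.Generator | None = None,
    gene_ids=None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """20-case / 20-control style matrix with a planted DE fraction."""
    rng = rng if rng is not None else cfg.rng(4)
    genes = list(gene_ids) if gene_ids is not None else [
        f"G{i + 1}" for i in range(cfg.n_genes)]
    n_genes = len(genes)
    samples = [f"CASE{j + 1}" for j in range(cfg.n_case)] + \
              [f"CTRL{j + 1}" for j in range(cfg.n_control)]
    vals = rng.standard_normal((n_genes, cfg.n_case + cfg.n_control))
    n_de = int(round(cfg.de_frac * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.empty(0, int)
    vals[de_idx, : cfg.n_case] += cfg.de_delta
    labels = pd.Series(["case"] * cfg.n_case + ["control"] * cfg.n_control,
                       index=samples)
    values = pd.DataFrame(vals, index=genes, columns=samples)
    values.index.name = "gene"
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    truth = pd.DataFrame({"gene": genes, "is_de": is_de,
                          "delta": np.where(is_de, cfg.de_delta, 0.0)})
    return ExpressionMatrix(values=values, labels=labels), truth


def marginal_ols(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorised per-SNP simple regression of ``y`` on each row of ``G``.

    Returns beta, se, p, n per SNP (two-sided t).  Monomorphic SNPs get NaN.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = G.shape[1]
    gc = G - G.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=1)
    sxy = gc @ yc
    syy = float((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    bad = sxx <= 0
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "n": n})


def simulate_smr_scenario(
    cfg: SimulationConfig,
    mode: str = "causal",
    n_region_snps: int = 30,
    n_gwas: int = 5000,
    n_eqtl: int = 1000,
    n_panel: int = 500,
    causal_index: int | None = None,
    linkage_offset: int = 3,
    gene: str = "GENE1",
    trait: str = "AIS",
    rng: np.random.Generator | None = None,
) -> dict:
    """End-to-end SMR inputs for one cis region with known ground truth.

    Three independent cohorts share the region's MAFs and LD structure: an
    eQTL cohort producing the expression summary statistics, a GWAS cohort
    producing the trait summary statistics, and a reference panel for LD.
    Modes: ``causal`` (trait = causal_gamma * expression + noise via the
    shared eQTL variant — the HEIDI null), ``null`` (no expression -> trait
    effect), ``linkage`` (the trait is driven directly by a different SNP
    ``linkage_offset`` positions away — the architecture HEIDI must flag).
    Returns dict(gwas, eqtl, panel, truth).
    """
    if mode not in ("causal", "null", "linkage"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else cfg.rng(5)
    m = n_region_snps
    mafs = rng.uniform(0.1, 0.5, size=m)  # common variants: usable instruments
    snp_ids = [f"rs{k + 1}" for k in range(m)]
    c = causal_index if causal_index is not None else m // 2

    G_e = simulate_genotypes_ld(cfg, mafs=mafs, n_samples=n_eqtl,
                                snp_ids=snp_ids, rng=rng).to_numpy()
    G_g = simulate_genotypes_ld(cfg, mafs=mafs, n_samples=n_gwas,
                                snp_ids=snp_ids, rng=rng).to_numpy()
    panel = simulate_genotypes_ld(cfg, mafs=mafs, n_samples=n_panel,
                                  snp_ids=snp_ids, sample_prefix="P", rng=rng)

    expr_e = cfg.eqtl_beta * G_e[c] + rng.standard_normal(n_eqtl)
    eqtl_stats = marginal_ols(G_e, expr_e)
    eqtl = pd.DataFrame({
        "snp": snp_ids, "gene": gene, "beta": eqtl_stats["beta"],
        "se": eqtl_stats["se"], "p": eqtl_stats["p"], "n": n_eqtl,
        "effect_allele": "A",
    })

    if mode == "causal":
        expr_g = cfg.eqtl_beta * G_g[c] + rng.standard_normal(n_gwas)
        y = cfg.causal_gamma * expr_g + rng.standard_normal(n_gwas)
    elif mode == "null":
        y = rng.standard_normal(n_gwas)
    else:  # linkage
        c2 = min(m - 1, c + linkage_offset)
        y = cfg.causal_gamma * cfg.eqtl_beta * G_g[c2] + rng.standard_normal(n_gwas)
    gwas_stats = marginal_ols(G_g, y)
    gwas = pd.DataFrame({
        "snp": snp_ids, "chrom": "1",
        "pos": (np.arange(m) + 1) * 1000,
        "effect_allele": "A", "other_allele": "G",
        "eaf": mafs, "beta": gwas_stats["beta"], "se": gwas_stats["se"],
        "p": gwas_stats["p"], "maf": mafs, "trait": trait,
    })
    truth = {"mode": mode, "gene": gene, "causal_snp": snp_ids[c],
             "causal_gamma": cfg.causal_gamma if mode != "null" else 0.0,
             "b_eqtl": cfg.eqtl_beta, "seed": cfg.seed}
    return {"gwas": gwas, "eqtl": eqtl, "panel": panel, "truth": truth}


def simulate_bundle(cfg: SimulationConfig, outdir) -> dict:
    """Write the full input bundle for the pipeline into ``outdir``.

    Files: gwas.tsv, m6a.tsv, expr.tsv, labels.tsv, genotypes.tsv,
    eqtl_expr.tsv, gene_positions.tsv, eqtl.tsv, panel.tsv, truth.json.
    The SMR scenario's summary statistics replace the corresponding GWAS rows
    so that the trait association, the eQTL table and the LD panel describe
    one coherent region.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gwas, sites, gwas_truth = simulate_annotated_gwas(cfg)

    # SMR region: reuse GWAS SNP ids so evidence streams join on shared keys.
    scen = simulate_smr_scenario(cfg, mode="causal", rng=cfg.rng(6))
    region_ids = [f"rs{i + 1}" for i in range(len(scen["gwas"]))]
    scen_gwas = scen["gwas"].copy()
    scen_gwas["trait"] = str(gwas["trait"].iloc[0])
    gwas = gwas[~gwas["snp"].isin(region_ids)]
    gwas = pd.concat([scen_gwas, gwas], ignore_index=True)

    # Small genotyped validation cohort over the region SNPs, with planted eQTLs.
    rng = cfg.rng(7)
    cohort = simulate_genotypes_ld(
        cfg, mafs=scen_gwas["maf"].to_numpy(), n_samples=cfg.n_samples,
        snp_ids=region_ids, rng=rng)
    planted = {scen["truth"]["causal_snp"]: scen["truth"]["gene"]}
    expr_cohort, eqtl_truth = simulate_eqtl_cohort(cfg, cohort, planted=planted, rng=rng)
    gene_pos = pd.DataFrame({
        "gene": expr_cohort.gene_ids,
        "chrom": "1",
        "tss": [int(scen_gwas.set_index("snp").loc[s, "pos"]) + 500
                for s in region_ids],
    })

    # Case/control matrix whose gene set includes the region genes.
    cc_genes = list(expr_cohort.gene_ids) + [f"G{i + 1}" for i in range(cfg.n_genes)]
    expr_cc, de_truth = simulate_case_control_expression(cfg, gene_ids=cc_genes)

    files = {
        "gwas": outdir / "gwas.tsv", "m6a": outdir / "m6a.tsv",
        "expr": outdir / "expr.tsv", "labels": outdir / "labels.tsv",
        "genotypes": outdir / "genotypes.tsv", "eqtl_expr": outdir / "eqtl_expr.tsv",
        "gene_positions": outdir / "gene_positions.tsv",
        "eqtl": outdir / "eqtl.tsv", "panel": outdir / "panel.tsv",
    }
    write_gwas_summary(gwas, files["gwas"])
    write_m6a_sites(sites, files["m6a"])
    write_expression_matrix(expr_cc, files["expr"], labels_path=files["labels"])
    write_genotypes(cohort, files["genotypes"])
    write_expression_matrix(expr_cohort, files["eqtl_expr"])
    gene_pos.to_csv(files["gene_positions"], sep="\t", index=False)
    write_eqtl_summary(scen["eqtl"], files["eqtl"])
    write_genotypes(scen["panel"], files["panel"])

    truth = {
        "config": asdict(cfg),
        "smr": scen["truth"],
        "n_m6a": int(gwas_truth["is_m6a"].sum()),
        "n_enriched": int(gwas_truth["is_enriched"].sum()),
        "n_de_planted": int(de_truth["is_de"].sum()),
        "eqtl_planted": eqtl_truth[eqtl_truth["planted"]]["snp"].tolist(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    files["truth"] = outdir / "truth.json"
    return {k: str(v) for k, v in files.items()}
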