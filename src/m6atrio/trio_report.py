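"""Integrate trait, eQTL, differential-expression and SMR/HEIDI evidence into a
per-SNP evidence table and a ranked causal-gene prioritisation.

A "trio" candidate is a trait-associated m6A-SNP linked to a gene whose
expression it perturbs (eQTL), with the gene differentially expressed in
cases and supported by SMR with no HEIDI heterogeneity.  FULL evidence means
all four conditions hold; PARTIAL means some nonempty subset does.  A
transcription of the published 15-SNP evidence table ships as a packaged
fixture so the report logic is testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

TRIO_COLS = [
    "snp", "chrom", "pos", "maf", "gene", "mutation_type",
    "p_trait", "p_trait_replication", "p_eqtl", "p_de", "p_smr", "p_heidi",
    "m6a_id", "m6a_pos", "m6a_effect", "trait",
]


@dataclass(frozen=True)
class EvidenceThresholds:
    """Significance levels for each evidence stream."""

    alpha_trait: float = 0.05
    alpha_de: float = 0.05
    alpha_smr: float = 0.05   # typically Bonferroni-derived, see bonferroni_threshold
    alpha_heidi_min: float = 0.05  # HEIDI pass means p_heidi > this


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if m < 1:
        raise ConfigurationError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def load_table1() -> pd.DataFrame:
    """The packaged published evidence table (15 m6A-SNPs across four traits)."""
    path = resources.files("m6atrio.data").joinpath("table1.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def build_trio_table(
    candidates: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
    de: pd.DataFrame | None = None,
    smr: pd.DataFrame | None = None,
    sort: bool = True,
) -> pd.DataFrame:
    """One evidence row per (trait, SNP) candidate; missing streams stay NaN.

    ``candidates``: annotated significant SNPs (snp, chrom, pos, maf, p,
    trait, m6a_id, site_pos, effect).  ``gene_map``: snp -> gene
    (+ mutation_type); a SNP mapping to several genes yields one row per gene
    with a warning.  Evidence joins: ``eqtl`` by (snp, gene) taking the
    minimum P per key, ``de`` by gene, ``smr`` by gene (and trait when both
    sides carry one).  Evidence keyed by SNPs/genes absent from the
    candidates is ignored (left-join semantics).
    """
    rows = candidates.rename(columns={
        "p": "p_trait", "site_pos": "m6a_pos", "effect": "m6a_effect",
    }).copy()
    if gene_map is not None:
        dup = gene_map["snp"].duplicated(keep=False)
        if dup.any():
            logger.warning("build_trio_table: SNP(s) with conflicting gene "
                           "assignments: %s", sorted(set(gene_map.loc[dup, "snp"]))[:5])
        rows = rows.merge(gene_map, on="snp", how="left")
    if "gene" not in rows.columns:
        rows["gene"] = pd.NA
    if eqtl is not None and not eqtl.empty:
        best = (eqtl.sort_values("p", kind="mergesort")
                .drop_duplicates(["snp", "gene"], keep="first"))
        rows = rows.merge(best[["snp", "gene", "p"]].rename(columns={"p": "p_eqtl"}),
                          on=["snp", "gene"], how="left")
    if de is not None and not de.empty:
        rows = rows.merge(de[["gene", "p"]].rename(columns={"p": "p_de"}),
                          on="gene", how="left")
    if smr is not None and not smr.empty:
        keys = ["gene", "trait"] if ("trait" in smr.columns and "trait" in rows.columns) else ["gene"]
        rows = rows.merge(
            smr[keys + ["p_smr", "p_heidi"]].drop_duplicates(keys),
            on=keys, how="left",
        )
    for col in TRIO_COLS:
        if col not in rows.columns:
            rows[col] = np.nan
    rows = rows[TRIO_COLS]
    if sort:
        rows = rows.assign(_ck=rows["chrom"].map(_chrom_key)).sort_values(
            ["trait", "_ck", "pos"], kind="mergesort").drop(columns="_ck")
    return rows.reset_index(drop=True)


def prioritize_causal_genes(rows: pd.DataFrame, th: EvidenceThresholds | None = None
                            ) -> pd.DataFrame:
    """Rank genes by evidence class.

    FULL: eQTL evidence present AND p_de < alpha_de AND p_smr < alpha_smr AND
    p_heidi > alpha_heidi_min.  PARTIAL: any nonempty subset of those four
    conditions.  NONE otherwise.  Ranking: FULL first, then p_smr ascending,
    ties broken by p_trait.  Per-gene P values aggregate across rows by
    minimum (strongest evidence).
    """
    th = th or EvidenceThresholds()
    if rows.empty:
        return pd.DataFrame(columns=["gene", "evidence_class", "has_eqtl", "de_sig",
                                     "smr_sig", "heidi_pass", "p_smr", "p_trait"])
    agg = rows.groupby("gene").agg(
        p_trait=("p_trait", "min"), p_eqtl=("p_eqtl", "min"),
        p_de=("p_de", "min"), p_smr=("p_smr", "min"), p_heidi=("p_heidi", "max"),
    )
    out = pd.DataFrame({
        "gene": agg.index,
        "has_eqtl": agg["p_eqtl"].notna().to_numpy(),
        "de_sig": (agg["p_de"] < th.alpha_de).to_numpy(),
        "smr_sig": (agg["p_smr"] < th.alpha_smr).to_numpy(),
        "heidi_pass": (agg["p_heidi"] > th.alpha_heidi_min).to_numpy(),
        "p_smr": agg["p_smr"].to_numpy(),
        "p_trait": agg["p_trait"].to_numpy(),
    })
    conds = out[["has_eqtl", "de_sig", "smr_sig", "heidi_pass"]].to_numpy()
    n_true = conds.sum(axis=1)
    out["evidence_class"] = np.select(
        [n_true == 4, n_true > 0], ["FULL", "PARTIAL"], default="NONE")
    order = out["evidence_class"].map({"FULL": 0, "PARTIAL": 1, "NONE": 2})
    out = out.assign(_o=order).sort_values(
        ["_o", "p_smr", "p_trait", "gene"], kind="mergesort",
        na_position="last").drop(columns="_o")
    cols = ["gene", "evidence_class", "has_eqtl", "de_sig", "smr_sig",
            "heidi_pass", "p_smr", "p_trait"]
    return out[cols].reset_index(drop=True)


def _chrom_key(c) -> int:
    s = str(c).removeprefix("chr")
    if s.isdigit():
        return int(s)
    return {"X": 23, "Y": 24, "MT": 25, "M": 25}.get(s.upper(), 26)


def prepare_manhattan(annotated: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Plot-ready table (chrom, pos, neg_log10_p, is_m6a) sorted genomically.

    Chromosomes order 1..22 numerically, then X, Y, MT, then others.
    """
    df = annotated
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str).to_numpy(),
        "pos": df["pos"].to_numpy(),
        "neg_log10_p": -np.log10(df["p"].to_numpy()),
        "is_m6a": df.get("is_m6a", pd.Series(False, index=df.index)).to_numpy(),
    })
    out = out.assign(_ck=out["chrom"].map(_chrom_key)).sort_values(
        ["_ck", "pos"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)


def write_trio_table(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False)
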