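"""Readers and writers for every flat-file table the pipeline touches.

All tables are desk-scale delimited text (tab or comma; anything else needs an
explicit ``sep``).  Bulk tables are returned as :class:`pandas.DataFrame` with
canonical column names so downstream modules never see source dialects.

Canonical columns
-----------------
GWAS summary      : snp, chrom, pos, effect_allele, other_allele, eaf, beta,
                    se, p, trait, maf
m6A site list     : m6a_id, snp, chrom, site_pos, confidence, effect
eQTL summary      : snp, gene, beta, se, p, n[, effect_allele]
genotypes         : SNPs x samples dosage matrix (0/1/2, NaN = missing)

Positions are 1-based throughout.  MAF is derived as ``min(eaf, 1 - eaf)`` at
load time and takes precedence over any MAF column in the source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Default column mapping for GWAS summary statistics (canonical -> file header).
GWAS_DIALECT = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "trait": "TRAIT",
}

#: Default column mapping for an m6A-SNP site list.
M6A_DIALECT = {
    "m6a_id": "m6A_ID",
    "snp": "SNP",
    "chrom": "CHR",
    "site_pos": "POS",
    "confidence": "CONFIDENCE",
    "effect": "EFFECT",
}

#: Default column mapping for eQTL summary statistics.
EQTL_DIALECT = {
    "snp": "SNP",
    "gene": "GENE",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
    "effect_allele": "A1",
}

CONFIDENCE_LEVELS = ("high", "medium", "low")
M6A_EFFECTS = ("Gain", "Loss")


def _sniff_sep(path) -> str:
    """Auto-detect tab vs comma from the header line; default to tab."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def _read_table(path, sep=None) -> pd.DataFrame:
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file: {path}") from exc
    return df


def _remap(df: pd.DataFrame, dialect: dict, required: tuple, path) -> pd.DataFrame:
    missing = [dialect[k] for k in required if dialect.get(k) not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing}; present: {list(df.columns)}"
        )
    present = {v: k for k, v in dialect.items() if v in df.columns}
    return df[list(present)].rename(columns=present)


def read_gwas_summary(path, dialect=None, trait: str | None = None, sep=None) -> pd.DataFrame:
    """Load GWAS summary statistics into the canonical frame.

    Rows violating the record invariants (p outside (0, 1], eaf outside (0, 1),
    se <= 0 when beta is present) are dropped with a logged count.  beta/se may
    be absent entirely — enrichment needs only P; the SMR stage re-validates.
    """
    dialect = {**GWAS_DIALECT, **(dialect or {})}
    df = _remap(_read_table(path, sep), dialect, ("snp", "p", "eaf"), path)
    if df.empty:
        raise InputError(f"no data rows in {path}")

    for col in ("pos", "eaf", "beta", "se", "p"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    n0 = len(df)
    ok = df["p"].gt(0) & df["p"].le(1) & df["eaf"].gt(0) & df["eaf"].lt(1)
    ok &= df["snp"].notna() | (df.get("chrom", pd.Series(index=df.index)).notna())
    if "beta" in df.columns and "se" in df.columns:
        has_beta = df["beta"].notna()
        ok &= ~has_beta | df["se"].gt(0)
    df = df[ok].reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_gwas_summary: dropped %d invalid row(s) from %s", dropped, path)
    if df.empty:
        raise InputError(f"no valid records in {path}")

    df["maf"] = np.minimum(df["eaf"], 1.0 - df["eaf"])
    if trait is not None:
        df["trait"] = trait
    elif "trait" not in df.columns:
        df["trait"] = "TRAIT"
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df


def write_gwas_summary(df: pd.DataFrame, path, dialect=None) -> None:
    dialect = {**GWAS_DIALECT, **(dialect or {})}
    out = df[[c for c in dialect if c in df.columns]].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


def read_m6a_sites(path, dialect=None, sep=None) -> pd.DataFrame:
    """Load an m6A-SNP site list; casing of effect/confidence is normalised.

    An effect label outside {Gain, Loss} (case-insensitively) raises
    :class:`InputError` naming the offending row.
    """
    dialect = {**M6A_DIALECT, **(dialect or {})}
    df = _remap(_read_table(path, sep), dialect, ("m6a_id", "snp", "effect"), path)
    if df.empty:
        return df
    df["effect"] = df["effect"].str.strip().str.capitalize()
    bad = ~df["effect"].isin(M6A_EFFECTS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputError(
            f"{path}: unknown m6A effect label {df['effect'].iloc[i]!r} in data row {i}"
        )
    if "confidence" in df.columns:
        df["confidence"] = df["confidence"].str.strip().str.lower()
        badc = ~df["confidence"].isin(CONFIDENCE_LEVELS)
        if badc.any():
            i = int(np.flatnonzero(badc.to_numpy())[0])
            raise InputError(
                f"{path}: unknown confidence level "
                f"{df['confidence'].iloc[i]!r} in data row {i}"
            )
    if "site_pos" in df.columns:
        df["site_pos"] = pd.to_numeric(df["site_pos"], errors="coerce").astype("Int64")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df


def write_m6a_sites(df: pd.DataFrame, path, dialect=None) -> None:
    dialect = {**M6A_DIALECT, **(dialect or {})}
    out = df[[c for c in dialect if c in df.columns]].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with optional case/control labels."""

    values: pd.DataFrame  # genes x samples, float
    labels: pd.Series | None = field(default=None)  # sample -> 'case'|'control'

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __post_init__(self):
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                missing = list(self.labels.index[self.labels.isna()])
                raise InputError(f"labels missing for sample(s): {missing}")
            bad = ~self.labels.isin(["case", "control"])
            if bad.any():
                raise InputError(
                    f"labels must be 'case'/'control'; got {sorted(set(self.labels[bad]))}"
                )


def read_labels(path, sep=None) -> pd.Series:
    """Two-column (sample, case|control) label file -> Series indexed by sample."""
    df = _read_table(path, sep)
    if df.shape[1] < 2:
        raise InputError(f"{path}: label file needs two columns (sample, label)")
    s = pd.Series(df.iloc[:, 1].str.strip().str.lower().values, index=df.iloc[:, 0].values)
    return s


def read_expression_matrix(path, label_map=None, dedup: str = "max-mean", sep=None) -> ExpressionMatrix:
    """Load a genes x samples table (first column = gene ids).

    Duplicate gene ids are collapsed by ``dedup``: ``max-mean`` keeps the row
    with the highest mean signal (the usual probe-collapse rule), ``first``
    keeps the first occurrence.  ``label_map`` may be a path to a label file or
    a mapping sample -> case/control; it must cover every sample.
    """
    df = _read_table(path, sep)
    gene_col = df.columns[0]
    genes = df[gene_col]
    mat = df.drop(columns=[gene_col])
    for col in mat.columns:
        vals = pd.to_numeric(mat[col], errors="coerce")
        src_na = mat[col].isna()
        bad = vals.isna() & ~src_na
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: non-numeric expression value {mat[col].iloc[i]!r} "
                f"at gene {genes.iloc[i]!r}, sample {col!r}"
            )
        mat[col] = vals
    mat.index = genes.values
    mat.index.name = "gene"

    if mat.index.has_duplicates:
        n_dup = int(mat.index.duplicated().sum())
        if dedup == "max-mean":
            order = mat.mean(axis=1).groupby(level=0).transform("max") == mat.mean(axis=1)
            mat = mat[order]
            mat = mat[~mat.index.duplicated(keep="first")]
        elif dedup == "first":
            mat = mat[~mat.index.duplicated(keep="first")]
        else:
            raise ConfigurationError(f"unknown dedup policy {dedup!r}")
        logger.info("read_expression_matrix: collapsed %d duplicate gene row(s)", n_dup)

    labels = None
    if label_map is not None:
        if isinstance(label_map, (str, bytes)) or hasattr(label_map, "__fspath__"):
            labels = read_labels(label_map)
        else:
            labels = pd.Series(label_map)
    return ExpressionMatrix(values=mat, labels=labels)


def write_expression_matrix(expr: ExpressionMatrix, path, labels_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if labels_path is not None and expr.labels is not None:
        expr.labels.rename("label").to_csv(labels_path, sep="\t", index_label="sample")


def read_genotypes(path, fmt: str = "dosage-tsv", sep=None) -> pd.DataFrame:
    """Load genotypes as a SNPs x samples dosage matrix.

    ``dosage-tsv``: first column SNP id, remaining columns per-sample dosages in
    {0, 1, 2}, empty/NA = missing.  ``vcf``: standard VCF 4.x with GT; only
    biallelic records are retained (multiallelic records are skipped with a
    log message) and dosage counts the alternate allele.
    """
    if fmt == "dosage-tsv":
        df = _read_table(path, sep)
        snp_col = df.columns[0]
        mat = df.drop(columns=[snp_col]).apply(pd.to_numeric, errors="coerce")
        mat.index = df[snp_col].values
        mat.index.name = "snp"
        valid = mat.isna() | mat.isin([0, 1, 2])
        if not valid.all().all():
            col = valid.all(axis=0).idxmin()
            raise InputError(f"{path}: dosage outside {{0,1,2,missing}} in column {col!r}")
        return mat
    if fmt == "vcf":
        return _read_vcf_dosages(path)
    raise ConfigurationError(f"unknown genotype format {fmt!r}")


def _read_vcf_dosages(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, ids = [], []
        n_multi = 0
        for v in vcf:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            dos = np.empty(len(samples))
            for j, gt in enumerate(v.genotypes):
                a = gt[:-1]  # last element is the phasing flag
                dos[j] = np.nan if any(al < 0 for al in a) else float(sum(al > 0 for al in a))
            ids.append(v.ID or f"{v.CHROM}:{v.POS}")
            rows.append(dos)
    except InputError:
        raise
    except Exception as exc:  # cyvcf2 raises bare Exceptions on malformed input
        raise InputError(f"malformed VCF {path}: {exc}") from exc
    if n_multi:
        logger.info("read_genotypes: skipped %d multiallelic VCF record(s)", n_multi)
    mat = pd.DataFrame(rows, index=ids, columns=samples)
    mat.index.name = "snp"
    return mat


def write_genotypes(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="SNP")


def read_eqtl_summary(path, dialect=None, sep=None) -> pd.DataFrame:
    """Load eQTL summary statistics (snp, gene, beta, se, p, n[, effect_allele])."""
    dialect = {**EQTL_DIALECT, **(dialect or {})}
    df = _remap(_read_table(path, sep), dialect, ("snp", "gene", "beta", "se", "p"), path)
    for col in ("beta", "se", "p", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    n0 = len(df)
    ok = df["p"].gt(0) & df["p"].le(1) & df["se"].gt(0)
    df = df[ok].reset_index(drop=True)
    if n0 - len(df):
        logger.info("read_eqtl_summary: dropped %d invalid row(s) from %s", n0 - len(df), path)
    return df


def write_eqtl_summary(df: pd.DataFrame, path, dialect=None) -> None:
    dialect = {**EQTL_DIALECT, **(dialect or {})}
    out = df[[c for c in dialect if c in df.columns]].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)
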