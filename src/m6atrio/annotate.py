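"""Intersect GWAS summary statistics with an m6A-SNP site list.

The join adds is_m6a / m6a_id / site_pos / confidence / effect columns to the
canonical GWAS frame.  When one SNP matches several sites, the
highest-confidence site wins (high > medium > low; ties broken by the
lexicographically smallest m6a_id) — the site list pools all confidence levels
by default, mirroring how the source database export is used.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

_CONF_RANK = {"high": 0, "medium": 1, "low": 2}

#: Window (bp) around the m6A site coordinate used for positional matching.
#: The modification site sits near, not on, the SNP (tens of bp in practice).
POSITION_WINDOW = 50

ANNOT_COLS = ["is_m6a", "m6a_id", "site_pos", "confidence", "effect"]


def _best_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """One row per SNP id: highest confidence, then smallest m6a_id."""
    s = sites.copy()
    s["_rank"] = s.get("confidence", pd.Series("low", index=s.index)).map(_CONF_RANK)
    s = s.sort_values(["snp", "_rank", "m6a_id"], kind="mergesort")
    return s.drop_duplicates("snp", keep="first").drop(columns="_rank")


def annotate_m6a(
    gwas: pd.DataFrame,
    sites: pd.DataFrame,
    match_mode: str = "rsid-then-position",
    pos_window: int = POSITION_WINDOW,
) -> pd.DataFrame:
    """Annotate every GWAS record with its m6A site, if any.

    Every input record is returned exactly once.  ``match_mode`` is one of
    ``rsid``, ``position`` or ``rsid-then-position`` (default; positional
    fallback covers rsID-version drift).  Positional matching pairs a SNP with
    any site on the same chromosome within ``pos_window`` bp of the site
    coordinate.  Idempotent: annotating an annotated frame changes nothing.
    """
    if match_mode not in ("rsid", "position", "rsid-then-position"):
        raise ConfigurationError(f"unknown match_mode {match_mode!r}")
    if gwas.empty:
        raise ConfigurationError("annotate_m6a requires a non-empty GWAS frame")

    out = gwas.drop(columns=[c for c in ANNOT_COLS if c in gwas.columns]).copy()
    out = out.reset_index(drop=True)
    for col in ("m6a_id", "confidence", "effect"):
        out[col] = pd.Series(pd.NA, index=out.index, dtype="object")
    out["site_pos"] = pd.Series(pd.NA, index=out.index, dtype="Int64")

    if not sites.empty:
        if match_mode in ("rsid", "rsid-then-position"):
            best = _best_sites(sites).set_index("snp")
            hit = out["snp"].map(best["m6a_id"])
            m = hit.notna()
            out.loc[m, "m6a_id"] = hit[m]
            for col in ("site_pos", "confidence", "effect"):
                if col in best.columns:
                    out.loc[m, col] = out.loc[m, "snp"].map(best[col])
        if match_mode in ("position", "rsid-then-position"):
            needed = ("chrom", "pos")
            if any(c not in out.columns or out[c].isna().all() for c in needed) or \
               any(c not in sites.columns for c in ("chrom", "site_pos")):
                if match_mode == "position":
                    raise ConfigurationError("position matching requires chrom/pos on both sides")
            else:
                unmatched = out["m6a_id"].isna()
                if unmatched.any():
                    cand = out.loc[unmatched, ["snp", "chrom", "pos"]].reset_index()
                    s = sites.copy()
                    s["_rank"] = (
                        s["confidence"].map(_CONF_RANK) if "confidence" in s.columns else 2
                    )
                    pairs = cand.merge(
                        s, on="chrom", suffixes=("", "_site")
                    )
                    pairs = pairs[
                        (pairs["pos"] - pairs["site_pos"]).abs() <= pos_window
                    ]
                    if not pairs.empty:
                        pairs = pairs.sort_values(
                            ["index", "_rank", "m6a_id"], kind="mergesort"
                        ).drop_duplicates("index", keep="first")
                        idx = pairs["index"].to_numpy()
                        for col in ("m6a_id", "site_pos", "confidence", "effect"):
                            if col in pairs.columns:
                                out.loc[idx, col] = pairs[col].to_numpy()

    out["is_m6a"] = out["m6a_id"].notna()
    return out


def filter_nominal(annotated: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep records with p strictly below ``alpha`` (P < 0.05 convention)."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    return annotated[annotated["p"] < alpha].reset_index(drop=True)


def write_annotated(annotated: pd.DataFrame, path) -> None:
    """Write the annotated table: GWAS columns + IS_M6A/M6A_ID/M6A_POS/CONFIDENCE/EFFECT."""
    from .io_formats import GWAS_DIALECT

    ren = {**GWAS_DIALECT, "maf": "MAF", "trait": "TRAIT", "is_m6a": "IS_M6A",
           "m6a_id": "M6A_ID", "site_pos": "M6A_POS",
           "confidence": "CONFIDENCE", "effect": "EFFECT"}
    out = annotated[[c for c in ren if c in annotated.columns]].rename(columns=ren)
    out.to_csv(path, sep="\t", index=False)
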