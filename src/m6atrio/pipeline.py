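"""End-to-end orchestration: annotate -> enrichment -> DE -> eQTL -> SMR -> trio report.

The pipeline is configured by a flat key/value mapping (YAML on disk; every
CLI flag overrides its key).  Each stage writes a TSV into the output
directory; a manifest records the package version, seed, input checksums and
row counts, the stage outputs produced, and any stages skipped because their
inputs were not configured.  Re-running with an identical config and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_m6a, filter_nominal, write_annotated
from .enrichment import BinScheme, enrichment_test, write_enrichment_results
from .exceptions import ConfigurationError, StageError
from .expression_assoc import cis_eqtl_scan, differential_expression, eqtl_lookup
from .io_formats import (
    read_eqtl_summary,
    read_expression_matrix,
    read_genotypes,
    read_gwas_summary,
    read_m6a_sites,
)
from .smr import SmrThresholds, run_smr
from .trio_report import build_trio_table, write_trio_table

logger = logging.getLogger(__name__)

DEFAULTS = {
    "alpha": 0.05,
    "alpha_de": 0.05,
    "B": 1000,
    "matched": True,
    "match_mode": "rsid-then-position",
    "bins": "0.01,0.05,0.10,0.20,0.30,0.40,0.50",
    "seed": 0,
    "smr_p_instr": None,   # None -> module default (chi2 > 10)
    "cis_window": 1_000_000,
    "output_dir": "m6atrio_out",
}

_INPUT_KEYS = ("gwas", "m6a", "expr", "labels", "genotypes", "eqtl_expr",
               "gene_positions", "eqtl", "panel")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a flat key/value mapping")
    return cfg


def run_pipeline(config: dict) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest.

    ``config`` keys: input paths (gwas, m6a, expr, labels, genotypes,
    eqtl_expr, gene_positions, eqtl, panel) plus the parameters in
    ``DEFAULTS``.  A stage whose inputs are absent is skipped and noted; a
    stage that fails aborts with :class:`StageError` (partial outputs are
    retained).
    """
    cfg = {**DEFAULTS, **config}
    if "gwas" not in cfg or "m6a" not in cfg:
        raise ConfigurationError("config must provide at least 'gwas' and 'm6a' paths")
    for key in _INPUT_KEYS:
        if key in cfg and not Path(cfg[key]).exists():
            raise ConfigurationError(f"input path for {key!r} does not exist: {cfg[key]}")
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg["alpha"])
    seed = int(cfg["seed"])
    scheme = BinScheme(tuple(float(x) for x in str(cfg["bins"]).split(",")))

    manifest = {
        "version": __version__, "seed": seed, "config": {k: str(v) for k, v in cfg.items()},
        "inputs": {}, "outputs": {}, "skipped": [],
    }
    for key in _INPUT_KEYS:
        if key in cfg:
            manifest["inputs"][key] = {"path": str(cfg[key]), "sha256": _sha256(cfg[key])}

    def record(name, path, n_rows):
        manifest["outputs"][name] = {"path": str(path), "rows": int(n_rows)}

    # --- annotate ---------------------------------------------------------
    try:
        gwas = read_gwas_summary(cfg["gwas"])
        sites = read_m6a_sites(cfg["m6a"])
        annotated = annotate_m6a(gwas, sites, match_mode=cfg["match_mode"])
        path = outdir / "annotated.tsv"
        write_annotated(annotated, path)
        record("annotate", path, len(annotated))
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # --- enrichment (per trait) ------------------------------------------
    try:
        results = []
        for i, (trait, sub) in enumerate(sorted(annotated.groupby("trait"))):
            inrange = sub[(sub["maf"] >= scheme.edges[0]) & (sub["maf"] <= scheme.edges[-1])]
            res = enrichment_test(
                inrange[inrange["is_m6a"]], inrange[~inrange["is_m6a"]],
                alpha=alpha, B=int(cfg["B"]), scheme=scheme,
                matched=bool(cfg["matched"]), seed=seed + i, trait=trait,
            )
            results.append(res)
        path = outdir / "enrichment.tsv"
        write_enrichment_results(results, path)
        record("enrich", path, len(results))
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    # --- differential expression -----------------------------------------
    if "expr" in cfg and "labels" in cfg:
        try:
            expr = read_expression_matrix(cfg["expr"], label_map=cfg["labels"])
            de = differential_expression(expr, alpha=float(cfg["alpha_de"]))
            path = outdir / "de.tsv"
            de.to_csv(path, sep="\t", index=False)
            record("de", path, len(de))
        except Exception as exc:
            raise StageError("de", exc) from exc
    else:
        de = None
        manifest["skipped"].append("de")

    # --- eQTL: cohort scan and/or summary lookup -------------------------
    eqtl_evidence = None
    if all(k in cfg for k in ("eqtl_expr", "genotypes", "gene_positions")):
        try:
            cohort_expr = read_expression_matrix(cfg["eqtl_expr"])
            genotypes = read_genotypes(cfg["genotypes"])
            gene_pos = pd.read_csv(cfg["gene_positions"], sep="\t").set_index("gene")
            snp_pos = annotated.set_index("snp")[["chrom", "pos"]]
            scan = cis_eqtl_scan(cohort_expr, genotypes, gene_pos, snp_pos,
                                 window=int(cfg["cis_window"]))
            path = outdir / "eqtl_scan.tsv"
            scan.to_csv(path, sep="\t", index=False)
            record("eqtl", path, len(scan))
            eqtl_evidence = scan
        except Exception as exc:
            raise StageError("eqtl", exc) from exc
    elif "eqtl" in cfg:
        try:
            table = read_eqtl_summary(cfg["eqtl"])
            sig = filter_nominal(annotated, alpha)
            eqtl_evidence = eqtl_lookup(sig["snp"], table)
            path = outdir / "eqtl_scan.tsv"
            eqtl_evidence.to_csv(path, sep="\t", index=False)
            record("eqtl", path, len(eqtl_evidence))
        except Exception as exc:
            raise StageError("eqtl", exc) from exc
    else:
        manifest["skipped"].append("eqtl")

    # --- SMR + HEIDI ------------------------------------------------------
    smr_results = None
    if "eqtl" in cfg and "panel" in cfg:
        try:
            eqtl_table = read_eqtl_summary(cfg["eqtl"])
            panel = read_genotypes(cfg["panel"])
            th = SmrThresholds() if cfg["smr_p_instr"] is None else SmrThresholds(
                p_instr=float(cfg["smr_p_instr"]))
            smr_results = run_smr(gwas, eqtl_table, panel, thresholds=th)
            path = outdir / "smr.tsv"
            smr_results.to_csv(path, sep="\t", index=False)
            record("smr", path, len(smr_results))
        except Exception as exc:
            raise StageError("smr", exc) from exc
    else:
        manifest["skipped"].append("smr")

    # --- trio report ------------------------------------------------------
    try:
        sig = filter_nominal(annotated[annotated["is_m6a"]], alpha)
        gene_map = None
        if eqtl_evidence is not None and not eqtl_evidence.empty:
            # assign each SNP its best-supported local gene
            gene_map = (eqtl_evidence.sort_values("p", kind="mergesort")
                        .drop_duplicates("snp", keep="first")[["snp", "gene"]])
        trio = build_trio_table(sig, gene_map=gene_map, eqtl=eqtl_evidence,
                                de=de, smr=smr_results)
        path = outdir / "trio.tsv"
        write_trio_table(trio, path)
        record("trio", path, len(trio))
    except Exception as exc:
        raise StageError("trio", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
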