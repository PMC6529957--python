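"""Resampling test for over-representation of m6A-SNPs among nominal GWAS hits.

The observed statistic is the fraction of m6A-SNPs with trait P < alpha.  The
null is built by drawing B sets of non-m6A-SNPs of the same size — either
freely from the whole background (``matched=False``) or matched to the m6A
set's minor-allele-frequency distribution across six MAF bins
(``matched=True``), so that allele-frequency differences cannot drive the
result.  The empirical P value uses the add-one estimator
``(1 + #{null >= observed}) / (B + 1)`` and is one-sided (over-representation).
The 95% interval reported is the 2.5th–97.5th percentile range of the null
proportions.

Because bins are disjoint and draws are without replacement within a draw, the
number of significant SNPs in a matched draw is exactly a sum of independent
per-bin hypergeometric counts; ``enrichment_test`` samples that count law
directly, which is distribution-identical to materialising SNP sets and far
cheaper.  ``draw_matched_null_set`` materialises an explicit set when the SNPs
themselves are wanted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: MAF bin edges: (0.01,0.05], (0.05,0.10], (0.10,0.20], (0.20,0.30],
#: (0.30,0.40], (0.40,0.50].  The first bin is closed at 0.01 so that the
#: smallest admissible MAF is binnable.
DEFAULT_BIN_EDGES = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass(frozen=True)
class BinScheme:
    """Ordered MAF break points defining half-open bins (lo, hi]."""

    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ConfigurationError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        e = self.edges
        return [f"{e[i]*100:g}–{e[i+1]*100:g}%" for i in range(self.n_bins)]

    def assign(self, maf) -> np.ndarray:
        """Vectorised bin assignment; raises on MAF outside the covered range."""
        m = np.atleast_1d(np.asarray(maf, dtype=float))
        e = np.asarray(self.edges)
        idx = np.searchsorted(e, m, side="left") - 1
        idx[np.isclose(m, e[0])] = 0  # closed lower edge of the first bin
        bad = (idx < 0) | (idx >= self.n_bins) | (m > e[-1])
        if bad.any():
            raise InputError(
                f"MAF value(s) outside ({e[0]}, {e[-1]}]: {m[bad][:5]} "
                "(records should have been filtered upstream)"
            )
        return idx


def assign_maf_bin(maf: float, scheme: BinScheme | None = None) -> int:
    """Index of the half-open bin containing ``maf`` (scalar convenience)."""
    scheme = scheme or BinScheme()
    return int(scheme.assign(maf)[0])


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment test (one trait, one matching mode)."""

    trait: str
    n_m6a: int
    n_sig: int
    observed_prop: float
    alpha: float
    B: int
    null_props: np.ndarray
    ci_low: float
    ci_high: float
    empirical_p: float
    bin_counts: np.ndarray
    matched: bool
    seed: int | None = None

    def to_row(self) -> dict:
        return {
            "trait": self.trait, "n_m6a": self.n_m6a, "n_sig": self.n_sig,
            "observed_prop": self.observed_prop, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "empirical_p": self.empirical_p,
            "B": self.B, "matched": self.matched, "seed": self.seed,
        }


def draw_matched_null_set(
    background: pd.DataFrame, bin_counts, rng: np.random.Generator,
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Sample one MAF-matched null set of non-m6A SNPs, without replacement.

    ``bin_counts[k]`` SNPs are drawn from bin k of ``background``; a bin with
    insufficient background raises, naming the bin — no silent shortfall.
    """
    scheme = scheme or BinScheme()
    bin_counts = np.asarray(bin_counts, dtype=int)
    bins = scheme.assign(background["maf"].to_numpy())
    picks = []
    for k, need in enumerate(bin_counts):
        pool = np.flatnonzero(bins == k)
        if need > len(pool):
            raise InputError(
                f"background bin {scheme.labels[k]} has {len(pool)} SNPs; "
                f"{need} required"
            )
        if need:
            picks.append(rng.choice(pool, size=need, replace=False, shuffle=False))
    idx = np.concatenate(picks) if picks else np.empty(0, dtype=int)
    return background.iloc[idx]


def enrichment_test(
    m6a_set: pd.DataFrame,
    background: pd.DataFrame,
    alpha: float = 0.05,
    B: int = 1000,
    scheme: BinScheme | None = None,
    matched: bool = True,
    seed: int | None = 0,
    trait: str | None = None,
) -> EnrichmentResult:
    """Test whether the m6A set's significant fraction exceeds chance.

    ``m6a_set`` and ``background`` are canonical GWAS frames (must be
    disjoint).  Draws are independent across the B sets and without
    replacement within a set.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if m6a_set.empty:
        raise InputError("empty m6A set")
    overlap = set(m6a_set["snp"]) & set(background["snp"])
    if overlap:
        raise InputError(f"m6A set and background overlap: {sorted(overlap)[:5]}")
    scheme = scheme or BinScheme()
    rng = np.random.default_rng(seed)

    n = len(m6a_set)
    n_sig = int((m6a_set["p"].to_numpy() < alpha).sum())
    observed = n_sig / n

    bg_sig = background["p"].to_numpy() < alpha
    if matched:
        m6a_bins = scheme.assign(m6a_set["maf"].to_numpy())
        bin_counts = np.bincount(m6a_bins, minlength=scheme.n_bins)
        bg_bins = scheme.assign(background["maf"].to_numpy())
        null_counts = np.zeros(B, dtype=int)
        for k in range(scheme.n_bins):
            pool = bg_bins == k
            N_k = int(pool.sum())
            K_k = int(bg_sig[pool].sum())
            need = int(bin_counts[k])
            if need == 0:
                continue
            if need > N_k:
                raise InputError(
                    f"background bin {scheme.labels[k]} has {N_k} SNPs; {need} required"
                )
            null_counts += rng.hypergeometric(K_k, N_k - K_k, need, size=B)
    else:
        bin_counts = np.array([n])
        N, K = len(background), int(bg_sig.sum())
        if n > N:
            raise InputError(f"background has {N} SNPs; {n} required")
        null_counts = rng.hypergeometric(K, N - K, n, size=B)

    null_props = null_counts / n
    empirical_p = (1 + int((null_counts >= n_sig).sum())) / (B + 1)
    ci_low, ci_high = np.percentile(null_props, [2.5, 97.5])
    if trait is None:
        trait = str(m6a_set["trait"].iloc[0]) if "trait" in m6a_set.columns else "TRAIT"
    return EnrichmentResult(
        trait=trait,
        n_m6a=n, n_sig=n_sig, observed_prop=observed, alpha=alpha, B=B,
        null_props=null_props, ci_low=float(ci_low), ci_high=float(ci_high),
        empirical_p=empirical_p, bin_counts=bin_counts, matched=matched, seed=seed,
    )


def maf_gof_test(counts_a, counts_b) -> tuple[float, float]:
    """Chi-square goodness of fit of ``counts_a`` against the bin proportions
    implied by ``counts_b`` (df = bins - 1).  Scale-invariant in ``counts_b``."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("count vectors must share the bin scheme")
    if np.any(b <= 0):
        raise InputError("reference counts must all be > 0")
    expected = b / b.sum() * a.sum()
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; chi-square approximation is weak",
                      stacklevel=2)
    stat, p = stats.chisquare(a, expected)
    return float(stat), float(p)


def write_enrichment_results(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame([r.to_row() for r in results]).to_csv(path, sep="\t", index=False)
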