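# m6atrio

Integrative prioritisation of causal genes from GWAS summary statistics via
m6A-SNP annotation — for statistical geneticists who want the whole evidence
chain (variant → RNA-methylation site → expression → trait) as one tested,
reproducible pipeline.

N6-methyladenosine (m6A) is a reversible RNA modification; an **m6A-SNP** is a
variant predicted to create ("Gain") or destroy ("Loss") an m6A site.  If such
variants act on disease risk by perturbing transcript regulation, they should
be over-represented among trait-associated SNPs, and the genes they regulate
should show expression evidence.  `m6atrio` implements that reasoning for
GWAS summary statistics (the motivating application is ischemic stroke and
its subtypes) as five statistical stages:

1. **Annotation** — join summary statistics to an m6A-SNP list (rsID with
   positional fallback) and flag nominal hits at *P* < 0.05.
2. **Enrichment** — compare the observed significant fraction of m6A-SNPs to
   *B* resampled sets of non-m6A-SNPs, optionally matched to the m6A set's
   minor-allele-frequency distribution over six MAF bins; report the
   percentile interval of the null proportions and the one-sided empirical
   *P* = (1 + #{null ≥ observed}) / (*B* + 1), plus a chi-square
   goodness-of-fit comparison of the MAF distributions.
3. **Expression association** — per-gene case/control *t*-tests of expression
   and additive-dosage OLS for cis-eQTLs (SNPs within 1 Mb of the TSS), with
   lookup-mode joining of external eQTL summary tables.
4. **SMR + HEIDI** — summary-data Mendelian randomization.  With
   z_g = b_GWAS/se_GWAS and z_e = b_eQTL/se_eQTL at the top cis-eQTL,

       b_xy  = b_GWAS / b_eQTL
       T_SMR = z_g² z_e² / (z_g² + z_e²)   ~  χ²(1)

   and HEIDI tests whether SNPs in LD with the top eQTL estimate a common
   b_xy (single shared causal variant) or heterogeneous ratios (linkage of
   distinct variants), using an LD reference panel.
5. **Trio report** — merge all evidence into a per-SNP table and rank genes:
   FULL evidence = eQTL signal + differential expression + SMR significance +
   HEIDI pass; the published 15-SNP evidence table ships as a packaged
   fixture.

Every input can also be **simulated** with planted ground truth
(`m6atrio.synthetic_data`), so the whole pipeline is testable offline at desk
scale.

## Worked example

```python
from m6atrio import (SimulationConfig, simulate_annotated_gwas, annotate_m6a,
                     enrichment_test, load_table1, prioritize_causal_genes,
                     EvidenceThresholds)

cfg = SimulationConfig(n_snps=50_000, seed=42)   # 8% m6A-SNPs, 10% with shifted effects
gwas, sites, truth = simulate_annotated_gwas(cfg)
ann = annotate_m6a(gwas, sites)
res = enrichment_test(ann[ann.is_m6a], ann[~ann.is_m6a], B=1000, matched=True, seed=42)
print(f"m6A-SNPs: {res.n_m6a}, nominal hits: {res.n_sig} ({100*res.observed_prop:.2f}%)")
print(f"null 95% interval: [{100*res.ci_low:.2f}%, {100*res.ci_high:.2f}%], "
      f"empirical P = {res.empirical_p:.4f}")

ranked = prioritize_causal_genes(load_table1(), EvidenceThresholds(alpha_smr=0.05))
print(ranked.head(4).to_string(index=False))
```

prints

```
m6A-SNPs: 4001, nominal hits: 464 (11.60%)
null 95% interval: [4.45%, 5.72%], empirical P = 0.0010
  gene evidence_class  has_eqtl  de_sig  smr_sig  heidi_pass    p_smr  p_trait
  IRF6           FULL      True    True     True        True 0.000364 0.000127
 NDST1           FULL      True    True     True        True 0.008470 0.000399
KCNJ11        PARTIAL      True   False     True       False 0.000721 0.000025
 RBM18        PARTIAL      True   False     True       False 0.002440 0.000075
```

The simulated m6A set carries planted effects, so its 11.6% nominal-hit rate
falls far above the matched null interval around 5% (empirical *P* at the
resolution floor 1/(B+1)).  On the packaged evidence table, *IRF6* and
*NDST1* are the two genes with the complete causal chain — trait association,
cis-eQTL, differential expression, significant SMR and a passing HEIDI test —
and rank first.

The same stages are scriptable from a shell:

```sh
m6atrio simulate --out bundle --seed 1
m6atrio enrich --gwas bundle/gwas.tsv --m6a bundle/m6a.tsv --out enrich.tsv --sets 1000 --matched
m6atrio run-all --config config.yaml
```

## Layout

```
src/m6atrio/
  io_formats.py        readers/writers (GWAS, m6A list, expression, genotypes, eQTL)
  annotate.py          m6A-SNP annotation and nominal filtering
  enrichment.py        MAF-binned matched resampling null, GOF test
  expression_assoc.py  case/control t-tests, additive cis-eQTL OLS, eQTL lookup
  smr.py               SMR statistic, instrument selection, HEIDI
  trio_report.py       evidence integration, gene ranking, Manhattan prep
  synthetic_data.py    seed-deterministic generators with truth tables
  pipeline.py, cli.py  orchestration and the `m6atrio` command
```
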