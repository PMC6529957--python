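# Methods

This note records the statistical models `m6atrio` implements, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Annotation

GWAS records are joined to the m6A-SNP list by rsID; records left unmatched
can fall back to positional matching (same chromosome, within ±50 bp of the
m6A site coordinate).  The window exists because the methylation site does
not coincide with the SNP coordinate — in practice they differ by tens of
base pairs — so exact-position matching on the site column would never fire.
When one SNP matches several sites, the highest-confidence site is attached
(high > medium > low, ties broken by the lexicographically smallest site id);
all three confidence levels are carried and none is filtered by default.
Nominal significance is strict: *P* < α with α = 0.05.

MAF is always derived as min(eaf, 1 − eaf) at load time; an explicit MAF
column in a source file is never trusted when an effect-allele frequency is
present, because the two can silently disagree after allele flips.

## Enrichment against a frequency-matched resampling null

The statistic is the fraction of m6A-SNPs with trait *P* < α.  The null
resamples *B* (default 1000) same-sized sets of non-m6A-SNPs, either freely
("unmatched") or bin-matched to the m6A set's MAF histogram over the six
half-open bins (0.01, 0.05], (0.05, 0.10], (0.10, 0.20], (0.20, 0.30],
(0.30, 0.40], (0.40, 0.50].  The first bin is treated as closed at 0.01 so
the smallest admissible MAF (association panels conventionally filter at
MAF ≥ 0.01) is binnable.  Matching on frequency controls the main selection
artefact — m6A-SNPs sit in transcribed regions and have a different frequency
spectrum than the genome-wide background; no LD- or position-matched null is
attempted.

Reported quantities: the 2.5th–97.5th percentile interval of the *B* null
proportions and the one-sided add-one empirical *P*
(1 + #{null ≥ observed}) / (*B* + 1), which never returns 0 and has
resolution 1/(B+1).  Because the bins are disjoint and each draw is without
replacement, the number of significant SNPs in a matched draw is exactly a
sum of independent per-bin hypergeometric variables; `enrichment_test`
samples that count law directly (the explicit set sampler
`draw_matched_null_set` exists for when the SNP identities are needed, and
the two routes are verified against full enumeration in the tests).  A
chi-square goodness-of-fit comparison of per-bin counts (reference counts
normalised to proportions, df = bins − 1) checks whether the m6A and non-m6A
MAF distributions differ; expected cells below 1 trigger a warning rather
than an error.

Calibration, measured by the acceptance tests on 200 genome-scale null
replicates (50,000 SNPs, 8% m6A, B = 200): type-I error at the 0.05 level and
coverage of the 95% percentile interval are both near nominal.  The interval
is a null-distribution band, not a confidence interval for the observed
proportion; coverage under the null is the relevant check.

## Expression association

Differential expression is a per-gene two-sided two-sample *t*-test of case
vs control mean signals.  Welch's unequal-variance form is the default — the
safer choice when group variances are unknown — with `equal_var=True`
available for pooled-variance replication.  Genes with identical groups
report t = 0, *P* = 1; a zero-variance group that makes the statistic
undefined yields a missing *P*, logged, never a fabricated value.  No
multiple-testing correction is applied at this stage (raw *P* < 0.05 is the
convention for the small two-group designs emulated here); Bonferroni control
is applied downstream where families of tests are defined.

The eQTL model is y = μ + β·g + ε with g ∈ {0, 1, 2} copies of the effect
allele — the standard additive coding — fit by OLS; the slope's two-sided
*t*-test gives the *P* value.  Cis pairs are SNP–gene combinations on the
same chromosome with |pos − TSS| ≤ 1 Mb.  A perfect fit (zero residual)
reports the smallest positive float and a `perfect_fit` flag rather than
*P* = 0.  No covariate adjustment (age, sex, ancestry PCs) is performed;
this is an extension point, not an oversight — the small validation-cohort
design being emulated reports none.

## SMR and HEIDI

At the top cis-eQTL (smallest eQTL *P* passing the instrument threshold), the
Wald ratio b_xy = b_GWAS / b_eQTL estimates the effect of expression on the
trait, and

    T_SMR = z_g² z_e² / (z_g² + z_e²),   z_g = b_GWAS/se_GWAS,  z_e = b_eQTL/se_eQTL

is referred to χ²(1); se_xy = |b_xy| / √T_SMR.  T_SMR ≤ min(z_g², z_e²), so
the test can never be more significant than its weaker input, and it
approaches z_g² as the instrument becomes noise-free.  The instrument
threshold defaults to χ²(1) > 10 (*P* < 1.57 × 10⁻³), the conventional cutoff
for this test family.

HEIDI asks whether other SNPs in LD with the top eQTL estimate the same
b_xy.  Instruments are cis-eQTLs with *P* below the instrument threshold and
LD r² with the top SNP in [0.05, 0.90] — the lower bound discards
uninformative SNPs, the upper bound guards against collinearity — truncated
to the 20 smallest eQTL *P* values.  For each instrument,
d_i = b_xy(i) − b_xy(top) is standardised by its first-order delta-method
variance, *including* the covariance between the instrument and top-SNP
ratios induced by LD (omitting that term is badly conservative for high-LD
instruments).  T_HEIDI = Σ z_i² is referred to a correlated chi-square sum:
the correlation of (z_i, z_j) is approximated by the instruments' LD
correlation r_ij, and the implied weighted sum of independent 1-df
chi-squares is evaluated by two-moment (Satterthwaite) matching on the
eigenvalues of that matrix.  With identity LD this reduces exactly to a
plain χ²(m) tail.  The approximation's adequacy is demonstrated empirically:
under a single-shared-variant null the rejection rate at 0.05 sits inside
binomial bounds over 200 replicates, and under a two-variant linkage
architecture it rejects nearly always.  A mild residual inflation is expected
and observed (winner's-curse selection of the top SNP plus the first-order
expansion); users should read *P*_HEIDI as a screening statistic, with
*P*_HEIDI > 0.05 meaning "no detectable heterogeneity".  HEIDI requires at
least 3 qualifying instruments to report a *P* value; below that it is
missing, not imputed.

Allele alignment flips the eQTL beta when its effect allele matches the GWAS
other allele, directly or via strand complement; strand-ambiguous (A/T, C/G)
SNPs are flagged and kept by default (droppable by flag); irreconcilable
pairs are excluded with a log message.  LD is the Pearson dosage correlation
from the reference panel (pairwise-complete when dosages are missing).

Pipeline-level significance mirrors the evidence-table convention: Bonferroni
over the genes tested (*P* < 0.05/k) for SMR, HEIDI pass = *P* > 0.05.

## Trio integration

`build_trio_table` is a pure left-join of evidence streams onto the (trait,
SNP) candidates: eQTL evidence by (snp, gene) with minimum-*P* deduplication,
differential expression by gene, SMR by gene (and trait when present).  Gene
classes: FULL = eQTL evidence present AND *P*_DE < α_DE AND *P*_SMR < α_SMR
AND *P*_HEIDI > 0.05; PARTIAL = any nonempty subset; ranking is FULL first,
then ascending *P*_SMR, ties by trait *P*.  A missing HEIDI value fails the
FULL criterion by design — absence of a heterogeneity check is not a pass.
The packaged `table1.tsv` fixture transcribes the published 15-SNP evidence
table; its `p_heidi` column carries the two values printed in the source's
prose (0.11 and 0.65) and is otherwise missing.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical shape* of the study designs, not
their biology:

- **GWAS**: per-SNP z-scores, N(0,1) null, enriched m6A subset shifted to
  |z| ~ N(2.5, 1) with random sign.  Defaults: 50,000 SNPs with 8% m6A
  (≈ 4,000 m6A-SNPs, the size of the emulated annotated set; the genome-wide
  8-million-SNP background is represented at desk scale), 10% of m6A-SNPs
  enriched.  MAF uniform on (0.01, 0.5) by default, or drawn from the
  six-bin histogram 583:663:1064:720:628:539 ("binned").
- **LD**: haplotypes threshold a latent AR(1) Gaussian (corr ρ^|i−j|,
  ρ = 0.8) at each SNP's MAF quantile.  This gives realistic monotone LD
  decay for testing LD-aware statistics at a fraction of the cost of a
  coalescent simulation; it does not reproduce real LD-block structure,
  allele-frequency spectra, or recombination hotspots.
- **Expression**: case/control matrices are 20 + 20 samples (the emulated
  series size) over 2,000 genes with 5% of genes shifted by 1.5 SD in cases;
  the eQTL cohort is 40 samples (the emulated validation cohort) with
  expression = 0.8·dosage + N(0,1) at planted pairs.  No probe-level
  normalisation artefacts, batch effects, or correlated co-expression are
  simulated — passing tests demonstrate the statistics are correct under the
  stated model, not that real microarray data meet its assumptions.
- **SMR scenario**: three independent cohorts (eQTL n = 1,000, GWAS
  n = 5,000, panel n = 500) share one 30-SNP region; expression is driven by
  a central causal variant (b = 0.8) and the trait either inherits a mediated
  effect (γ = 0.5), is pure noise, or is driven directly by a variant 3
  positions away (the linkage arm).  Cohort sizes are deliberate scale-downs
  of the consortium datasets being emulated, chosen so instrument z-scores
  (top ≈ 14) sit in the strong-instrument regime where the delta-method
  expansion is accurate.

Every generator derives its randomness from `SimulationConfig.seed` through
per-generator seed sequences, emits a truth table, and round-trips through
the `io_formats` readers.

## Numerical and design choices

- Empirical *P* uses the add-one estimator; tails are compared on integer
  counts, never on floating-point proportions, so ties are exact.
- Half-open MAF bins make the scheme exhaustive and non-overlapping; the
  published bin labels are ambiguous at the edges, and the half-open
  convention is the unique reading that partitions (0.01, 0.50].
- HEIDI guards the delta-method variance of d_i from below at 10⁻³ of the
  uncorrected variance (near-collinear instruments with noisy LD estimates
  can otherwise produce non-positive variances); the r² ≤ 0.9 selection bound
  makes the guard rarely active.
- Eigenvalues below 10⁻¹⁰ are dropped before Satterthwaite matching.
- Top-eQTL and instrument ordering ties break on (P, snp id), making
  `run_smr` invariant to input row order.
- Degenerate inputs fail loudly: monomorphic dosages, empty m6A sets,
  insufficient background bins, and top SNPs missing from the LD panel all
  raise or skip with named log messages; nothing is silently truncated.

## Problem sizes in the shipped experiments

The acceptance experiments use 200 replicates for rate estimates (binomial
99% bounds around 0.05 give the acceptance band [0.014, 0.10]), 50 replicates
for SMR effect recovery, B = 200 null sets inside each calibration replicate,
and 2,000 genes/SNPs for null-uniformity KS checks.  These sizes give
Monte-Carlo error small enough for the stated bands while keeping the full
suite fast on a single CPU.

## Known limitations

- SMR here is single-instrument (top eQTL); no multi-SNP SMR, mediation, or
  trans analyses.
- HEIDI's null approximation is first-order; with weak instruments
  (z_e² ≲ 10) it inflates, which the instrument threshold largely prevents
  but does not eliminate.
- The enrichment null matches frequency only — not LD, gene density, or
  genomic annotation — matching the analysis it re-implements.
- Flat-file IO only (headered TSV/CSV, VCF 4.x); no PLINK binary filesets,
  tabix indexes, or .besd stores.
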