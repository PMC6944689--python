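# lncscout

Discovery pipeline for **subtype-specific long non-coding RNAs in basal-like
breast cancer**, built for transcriptomics analysts who want the full chain —
candidate prioritization, survival stratification, gene-set enrichment,
cis-neighborhood analysis, and pharmacogenomic screening — as tested, reusable
code rather than a collection of notebook snippets. A synthetic cohort
generator with a machine-readable truth ledger makes every stage verifiable:
effects are planted, then recovered.

## What it computes

**Candidate screen.** From a patient count matrix (genes × samples with PAM50
subtype labels BL/HER2/LA/LB/NL plus normal tissue), a gene passes iff it is

- of lncRNA biotype,
- overexpressed in BL vs normal tissue *and* vs each other tumor subtype
  (ratio of size-factor-normalized means > 1.5, pseudocount 0.5),
- not low-abundance (baseMean = mean of normalized counts ≥ 0.5, with
  size factors sf_s = median_g counts_gs / geomean_g, the median-of-ratios
  estimator),
- expressed (FPKM > 1) in ≥ 10% of BL patients but in < 15% of patients of
  every other tumor subtype,
- expressed in ≥ 2 BL cell lines.

Normal-like samples are excluded from all contrasts. Every gene keeps its full
metric record and per-filter pass/fail flag for audit.

**Survival.** Kaplan–Meier product-limit curves per expression group
(median or top-q/bottom-q split) and the two-group log-rank test,
χ² = (ΣO − ΣE)² / ΣV with hypergeometric variance at each event time,
plus Benjamini–Hochberg adjustment across candidates.

**Enrichment.** Self-implemented GSEA: samples are contrasted by the focal
lncRNA's expression (top vs bottom quartile), genes ranked by signal-to-noise
(μ₁−μ₂)/(σ₁+σ₂) with σ floored at max(0.2·|μ|, 0.2), and each gene set scored
by the weighted Kolmogorov–Smirnov running sum (hits += |metric|^p / N_R,
misses −= 1/(N−k); ES = signed maximum deviation). Significance comes from
phenotype or gene-set permutations with plus-one smoothing, NES by same-sign
null normalization, FDR by the pooled-null NES comparison. A per-subtype
Mann–Whitney test (exact enumeration for small pooled sizes) covers
single-gene subtype enrichment.

**Cis-neighborhood.** Genes intersecting a ±1 Mb window around the focal gene
(0-based half-open intervals), Pearson/Spearman co-expression on
log2(FPKM+1), and a promoter-methylation comparison: share of CpG beta values
above 0.3 per group plus a Mann–Whitney test on per-sample mean beta.

**Drug screen.** Cell lines ranked by biomarker expression; per compound the
geometric-mean IC50 ratio of top-4 vs bottom-4 lines (< 0.25 passes), a Welch
t-test on log10 IC50 of the top/bottom 6, and the Pearson correlation of
expression with log10 IC50 over all lines, BH-adjusted across ratio-passing
compounds. Hits are ratio-passing compounds with negative correlation at
q ≤ 0.1.

**Simulator.** Negative-binomial counts (mean/size parameterization) over six
sample classes with log-normal library depths; planted BL-restricted lncRNAs
(40% of BL patients expressing at 20-fold), single-violation decoy genes for
every filter, a co-expressed protein-coding neighbor 13 kb downstream of the
focal lncRNA, an expressor-coupled "responsive" gene module, expression-linked
exponential survival, class-hypomethylated beta values, and compounds whose
log-IC50 falls with expression. Ground truth is written as JSON.

## Worked example

```sh
lncscout simulate --preset demo --seed 7 --out-dir demo_data
lncscout run --data-dir demo_data --out-dir demo_out --seed 3 --nperm 50
```

prints

```
{"focal_gene": "PLANTED01", "n_passing_candidates": 3}
```

and writes one table per stage under `demo_out/`. The screen recovers the
three planted candidates (and no decoy). `survival.tsv` shows the focal
candidate splitting the cohort's outcomes (the simulated hazard follows its
expression):

```
gene_id     n_high  n_low  chi_square   p_value      bh_q
PLANTED01   34      34     9.064        0.00261      0.00782
PLANTED03   34      34     0.00697      0.933        0.933
PLANTED02   34      34     0.647        0.421        0.632
```

`gsea.tsv` ranks the planted responsive module first (ES 0.991, NES 1.68,
permutation p 0.036); `cis.tsv` finds the planted neighbor 13 kb away with
r = 0.932 (p ≈ 8e-38); `drugscreen.tsv` calls exactly the three planted
sensitive compounds as hits, e.g. compound_28 with IC50 ratio 0.067,
r = −0.867, q = 3.0e-4. A `manifest.json` records the seed, every threshold
and the SHA-256 of every output, so a rerun with the same seed is
byte-identical.

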