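# Methods

## Scope and model of the data

The package operates on bulk RNA-seq gene-level counts for breast-tumor
cohorts labeled with PAM50 intrinsic subtypes (BL, HER2, LA, LB, normal-like)
plus adjacent normal tissue, FPKM matrices for patients and cell lines, a gene
annotation with biotype and coordinates, a clinical survival table, gene sets
(GMT), CpG-probe beta values and a cell line × compound IC50 table. Alignment
and counting are upstream of the package: counts are inputs.

All genomic intervals are handled 0-based half-open internally; GTF input and
output converts from/to the 1-based inclusive convention at the boundary. A
gene neighbors a focal gene when its interval intersects
[focal.start − w, focal.end + w) on the same chromosome (gene-body anchoring;
a TSS-anchored mode exists because "a window around a gene" is ambiguous —
gene-body anchoring is symmetric under strand and is the default we report).

## Normalization and screen statistics

Size factors are median-of-ratios: the reference set is genes with strictly
positive counts in every sample, and sf_s is the median over that set of
counts_gs / geometric-mean_g. baseMean is the mean of size-factor-normalized
counts over all samples. FPKM is counts·10⁹/(length·N_s) with N_s defaulting
to the column sum, since true mapped-read totals do not exist for synthetic
data. Fold-changes are ratios of group means of normalized counts with a
pseudocount ε = 0.5 on both numerator and denominator; ε guards the
subtype-exclusive genes the screen is designed to find (reference group mean
can be exactly zero) and is configurable. "Expressed" means strictly
FPKM > threshold (default 1), so boundary values are excluded; prevalence is
the fraction of a class's samples expressed.

The screen applies the filters conjunctively and keeps every intermediate
metric. Two conventions are worth stating because the boundary cases matter:
baseMean uses ≥ 0.5 (the exclusion rule is "< 0.5 is removed", so the boundary
survives) and the other-subtype prevalence cut is strict (< 15%). The
10%-of-patients filter uses the same FPKM > 1 definition of expressed as the
15% filter — an explicit assumption, since only the latter carries a stated
threshold. Fold-change contrasts are computed against normal tissue and
against each other tumor subtype separately (a pooled-others mode exists);
normal-like samples are excluded from every contrast. Passing genes are
ranked by descending fold-change versus normal purely to make output
deterministic.

Note on monotonicity: tightening any of the five pass/fail cutoffs (min
fold-change, min baseMean, min target prevalence, max other-subtype
prevalence, min expressing cell lines) can only shrink the passing set, and
the suite asserts this over random perturbations. The `expressed_fpkm`
parameter is *not* monotone by construction: raising it lowers prevalence in
the target class (stricter) and in the other subtypes (more lenient), so it is
excluded from that property.

## Survival

The high/low split defaults to the median with "high" strictly above it — the
least-parameterized rule; a symmetric-quantile mode (top q vs bottom q, middle
unassigned) covers first-vs-fourth-quartile designs. The Kaplan–Meier
estimator and the two-group log-rank test are implemented directly (observed
minus hypergeometric-expected events with the standard variance, χ² referred
to 1 df); at tied times events are processed before censorings. The test is
cross-checked against lifelines in the suite. At n = 100 with 20% uniform
censoring the measured type-I error at α = 0.05 is ≈ 0.057 (6000 replicates) —
the usual mild anticonservatism of the asymptotic χ² at moderate sample size —
and power at a hazard ratio of 3 with n = 200 is ≈ 1.0. Benjamini–Hochberg
adjustment (via statsmodels) is provided for multi-candidate reporting.

## Enrichment

The enrichment statistic is the weighted running sum over a ranked list:
hits increment by |metric|^p normalized to the set's total weight, misses
decrement by 1/(N−k), ES is the signed maximum deviation. Default weight
p = 1; p = 0 is kept because it admits analytic checks (top-loaded set gives
ES = 1 exactly) and the suite also verifies ES against an independently coded
brute-force enumeration to 1e−12. If every hit's metric is zero at p > 0 the
statistic falls back to unweighted steps rather than dividing by zero.
Rankings break ties by gene id, so results are deterministic.

Significance: phenotype permutation by default (n_perm = 1000; 200 in
desk-scale runs), gene-set permutation for tiny cohorts.
p = (1 + #{same-sign |ES_π| ≥ |ES|}) / (1 + #same-sign permutations); NES
divides ES by the mean |ES_π| of its same-sign null; FDR compares pooled
same-sign null NES with the observed NES distribution (classic procedure,
clipped to [0,1]). The plus-one smoothing puts a floor of 1/(n_perm+1) under
p when every permutation shares the observed sign; with a same-sign subset the
floor is correspondingly higher. On null data the permutation p of random
sets is uniform (KS-checked in the suite).

The per-subtype test of a single gene is a one-vs-rest Mann–Whitney U:
exact enumeration when the pooled size is ≤ 12 and tie-free (the exact path is
validated against full enumeration of all group assignments for every
n1, n2 ≤ 8), otherwise the normal approximation with tie correction.

## Drug screen

IC50s are averaged on the log scale (geometric means): compound potencies span
orders of magnitude, and the ratio of geometric means equals the exponentiated
difference of mean log10 IC50, making the ratio scale-invariant. The ratio
filter uses the top/bottom 4 expression-ranked lines and a strict < 0.25 cut;
the group test is a Welch t on the top/bottom 6 (both k's are parameters with
those defaults, mirroring the mixed design of the screen this reproduces);
the correlation stage is Pearson over all measured lines with p from the
t-transform. BH adjustment runs across the compounds that passed the ratio
filter. The default hit rule is ratio-pass ∧ r < 0 ∧ q ≤ 0.1; a `group_alpha`
parameter additionally gates on the Welch p for analysts who prefer the
stricter cascade. Missing (line, compound) pairs are dropped per compound,
never imputed.

A caveat the simulation study makes visible: with 14 lines the top/bottom-4
ratio statistic and the all-lines correlation share most of their noise
(contrast–correlation alignment ≈ 0.9), so null compounds that survive the
ratio filter carry selection-inflated negative correlations, and the
conditional false-positive rate of the correlation stage among ratio-passers
exceeds the nominal q. The *unconditional* all-null hit rate stays low
(≈ 1% per compound at the defaults). This is a property of the published
cascade design at this panel size, not of the implementation.

## The synthetic cohort generator

The generator defines the study conditions; its defaults are fixed once.

Counts are negative binomial in the mean/size parameterization (size =
"dispersion", default 5, i.e. squared biological CV of 0.2 — homogeneous
within-subtype bulk tissue) with mean x_g · m_gs · length_g · depth_s / 10⁹.
x_g is a gene's FPKM-scale expression (background log-normal, median 16,
log-sd 1.5, rescaled so Σ x·length/10⁹ = 1, which makes column-sum FPKM
recover x); depth_s is log-normal (median 10⁷ reads, log-sd 0.25); gene
lengths are uniform on [200, 20000] bp (planted genes on [2000, 20000]).
Sample classes follow the desk preset 40 BL / 20 HER2 / 80 LA / 40 LB /
10 NL / 20 normal; a full-scale preset mirrors a 131/64/404/170 tumor split,
and a small demo preset backs the bundled end-to-end example.

Planted candidates are lncRNAs with baseline 0.2 FPKM whose "expressor"
samples get a 20-fold multiplier: 40% of BL patients and 5% of the other
tumor-subtype patients (normal tissue never expresses them). Expressor status
is assigned per (gene, class) to an exact count, round(fraction·n), drawn
without replacement — prevalence semantics are unchanged, but the planted
prevalence is pinned at its nominal value so recovery experiments measure the
screen rather than binomial noise in the truth (with per-sample Bernoulli
draws at 20 HER2 patients, a planted gene would trip the <15% filter in ~7.5%
of cohorts by luck alone, per gene and subtype). Decoy genes copy the planted
profile except for one engineered violation each — wrong biotype, normal
tissue co-expression, one subtype matched in mean but not prevalence, a short
near-silent gene that passes prevalence at tiny absolute counts (fails
baseMean), 5%-of-BL expression at high fold (fails prevalence only), 25%-of-LA
expression at modest fold (fails the 15% cut only), or support in a single
cell line — with effect sizes chosen far from every other filter boundary.

The focal gene's protein-coding neighbor sits exactly 13 kb downstream and is
generated by a Gaussian copula on the focal gene's realized log2(FPKM+1)
(latent correlation = the 0.9 target, log-normal expression around 8 FPKM,
Poisson counting noise), which reproduces the target Pearson correlation on
the log scale to within ~0.01 of attenuation. The responsive gene module
(default 25 protein-coding genes at 10 FPKM) gets a 3-fold multiplier in
exactly the focal gene's expressor samples; gene sets consist of this module
plus random sets drawn from the genes with *no* planted coupling, so random
sets are genuinely null. Survival times are exponential with hazard
h₀·HR^{I(high)} (h₀ = 1/1000 days⁻¹), censoring uniform on (0, c) with c
solved so the expected censored fraction matches the requested rate (exact
under HR = 1). Methylation betas are Beta-distributed with mean 0.55
(concentration 10), reduced by 0.30 in the hypomethylated class. Drug
response is log10 IC50 = a + slope·z(expression) + ε with a ~ U(−0.5, 1.5) µM
(decades), slope −0.5 and ε ~ N(0, 0.375) for sensitive compounds — i.e. a
population expression–IC50 correlation of −0.8 — and slope exactly 0 for
nulls. All randomness derives from one root seed through named substreams, so
identical configs reproduce byte-identical tables and any single table can be
regenerated in isolation.

What the generator does *not* emulate: isoform structure, batch effects,
copy-number variation, read-level noise, co-regulation among planted
candidates, or correlated compound panels. Passing tests therefore
demonstrate that the statistics recover the effects they target at realistic
effect sizes and noise — not robustness to those real-data complications.

## Problem sizes and numerical choices

The suite's simulation studies use the desk preset (2000 genes, 210 samples,
50 cohorts for recovery checks), 2000 replicates for log-rank null
calibration, 200 gene sets × 200 permutations for enrichment calibration, and
200 screens × 30 compounds for the drug-screen study; the acceptance script
uses slightly smaller replicate counts. These sizes give binomial standard
errors well inside the asserted margins. Tolerances: ES vs brute force at
1e−12 (identical arithmetic up to float re-association); hand-arithmetic
examples at ≤ 1e−4 or exact; calibration bands as stated per check.
Degenerate inputs are explicit errors (constant vector for a median split, no
all-positive reference gene for size factors, empty groups) or warned-and-
reported-missing (constant vectors in correlations, compounds with too few
measured lines).

## Known limitations

- The log-rank χ² is asymptotic; at n ≲ 50 per arm its type-I error runs a
  few tenths of a percent above nominal.
- GSEA results are not bit-comparable to other GSEA software (metric variant,
  permutation scheme and tie handling all differ between tools); the
  implementation is validated against enumeration and calibration instead.
- The drug-screen cascade's ratio pre-filter induces selection bias in the
  downstream correlation test at small panel sizes (see above); the package
  reports every stage so users can weigh the evidence per compound.
- FPKM uses column sums as library sizes unless totals are supplied.
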