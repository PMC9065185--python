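# Methods

This note records the models, parameter choices and numerical conventions
behind `isofunnel`, and what the synthetic-data experiments do and do not
demonstrate.

## Quantification

FPKM uses the sum of all transcript counts in a sample as the library
total; a count-matrix pipeline has no separate "mapped reads" figure, so
the definition is self-contained. Isoform fractions (FR) are stored in
percent, so ΔFR is in percentage points with range [−100, 100]. A
gene-sample cell with zero total FPKM yields *undefined* fractions (NaN),
never 0: imputing 0 would manufacture usage shifts out of missingness.
Undefined values are excluded from condition means, and a transcript with
an all-undefined condition is excluded from switch testing entirely.
Defined per-gene fractions sum to 100 within 1e-6 per sample.

## Switch detection

ΔFR is the exact subtraction of condition-mean fractions, treated minus
control. Significance defaults to a Welch t test on the per-sample
fractions. A permutation test (absolute difference of group means,
exhaustive over label assignments when there are at most 10,000, sampled
with a seed otherwise) is implemented and exposed, but at the 3-vs-3
design the exhaustive two-sided permutation p has granularity
2/20 = 0.1 and can never clear α = 0.05; a distribution-free test is
simply unavailable at this depth of replication, so the t test is the
default. States: PS-on for ΔFR > 0 at p < α, PS-off for ΔFR < 0 at
p < α, otherwise none; a *gene* is called switched when any isoform has a
state, and both per-isoform and gene-level labels are emitted because
usage conservation makes one isoform's fall another's rise.

Class codes are assigned most-specific-first (`=`, `k`, `j`, `e`,
`other`): `=` for an identical intron chain with exonic overlap, `k` when
the reference's intron chain is a contiguous subchain of the query's and
the query spans the reference, `j` for a multi-exon query sharing at
least one junction, `e` for a single-exon query overlapping a reference
intron and an adjacent exon. Within this pipeline (annotation-only, no
assembly) each isoform is classified against its gene's longest isoform,
which serves as the reference structure and is itself `=`. The volcano
highlight threshold is |ΔFR| > 80 percentage points, i.e. the 0.8
threshold of the fractional scale.

## Differential expression

Genes with one or more zero counts are excluded before anything else.
Size factors are median-of-ratios (RLE), rescaled to geometric mean 1.
The Wald test works on normalized counts `y = c/s`:

- log2FC is the plain ratio of group means; a 0.5 pseudocount engages
  only when a group mean is zero (possible on unfiltered edge inputs).
  This keeps log2FC *exactly* invariant to a per-sample count rescaling,
  which the geometric-mean-1 convention would otherwise break through the
  pseudocount at the 1e-2 level.
- Dispersion is method-of-moments: per-gene values
  `(pooled within-group var − pooled mean) / pooled mean²` are combined
  across genes by a 12.5%-trimmed mean, floored at 1e-8. With three
  replicates per group a purely per-gene estimate has ~4 degrees of
  freedom, and a normal-referenced Wald statistic built on it rejects at
  ~0.11–0.12 under the null at α = 0.05; pooling across genes restores a
  near-nominal rate (measured ≈ 0.065) while staying moment-based, with
  no shrinkage machinery. A `dispersion_mode="per_gene"` escape hatch
  keeps the unpooled estimator available.
- The standard error is the delta method on the NB variance
  `(μ + αμ²)/n` per group; z is referred to the standard normal.

Selection uses the printed cutoffs — |FC| > 2 at **raw** p < 0.05 — with
the BH-adjusted p reported alongside. Row z-scoring uses the sample
standard deviation (ddof = 1); constant rows become zeros and are
flagged. Clustering is complete linkage on Euclidean distances via
`scipy.cluster.hierarchy`; scipy's deterministic tie handling is accepted
as the tie-break rule, and merge heights are verified against an O(n³)
reference implementation.

## Survival

Kaplan-Meier estimation and the log-rank test are delegated to
`lifelines` (censored subjects remain at risk at their own tied time, the
standard convention); the median is the smallest event time with
S(t) ≤ 0.5, read off the curve with a 1e-12 tolerance so that products
landing exactly on one half are not lost to round-off. The best-cutoff
scan tries every unique observed expression value inside the 20th–80th
percentile window (the common guard against extreme, tiny groups; the
original web toolkit's grid is unpublished), splits at expression >
cutoff, and keeps the cutoff with the smallest log-rank p, ties resolving
to the lower cutoff. Direction compares the two KM curves at the last
time both groups reach. No multiplicity correction is applied across
scanned cutoffs — matching how such toolkits report p — and the
resulting optimism is *measured* instead: under a null hazard the scan's
minimum p is stochastically much smaller than uniform, while a fixed
pre-specified cutoff gives a uniform p (asserted by a KS test in the
suite). Eligibility implements the "FPKM above 1" rule as *median cohort
FPKM > 1*; the phrase does not say which summary is meant, so the
summary is switchable (`eligibility="any"`). Overall-survival association
truncates follow-up at a 5-year horizon (administrative censoring).

## The funnel

Stage order: exposure DEGs (up/down) ∩ cohort DEG list, then ∩ the
switch-gene set, then the survival filter, then the membrane flag.
Direction concordance with the cohort list is enforced when that list
carries direction and skipped otherwise (the original selection's rule is
unstated; requiring concordance is the conservative reading). The
survival filter keeps upregulated genes only with a significant
high-worse association and downregulated genes only with high-better,
dropping FPKM-ineligible genes with a log entry. Membrane annotation is a
user-supplied flag table; a missing flag counts as False and is logged.
Over-representation is the one-sided hypergeometric tail with BH across
collections; the universe defaults to all genes in the count matrix.

## Synthetic data

The generator's defaults are the study conditions: 3 replicates per
condition, genes with 1–5 isoforms (weights 0.35/0.30/0.20/0.10/0.05),
Dirichlet usage sorted so the first isoform is dominant, NB dispersion
α = 0.05, ~1 M counted fragments per library (CV 10%), 6% DE genes at
|log2FC| = 3, 6% switch genes at 60 percentage points of moved usage, a
200-subject cohort with hazard ratio 4. Where the source study reports no
value (library sizes, dispersions, cohort hazard scale) the defaults are
stated choices of plausible bulk-RNA-seq and cohort magnitudes, not
inferences.

Expected transcript counts are usage- and length-weighted but normalized
by the gene's usage-weighted length, `μ_i ∝ a_g · u_i ℓ_i / Σ_k u_k ℓ_k`,
which makes two things exact at once: the gene's expected total count is
invariant to usage redistribution (switching only moves reads between
isoforms), and the FPKM-derived fraction recovers the planted usage.
Sampling is gamma-Poisson with one gamma factor per gene-sample shared by
the gene's isoforms, so gene totals are exactly NB(μ, α) — the Wald
stage's model — while isoform fractions carry only count-level noise, the
shared factor cancelling in ratios. Switch genes whose drawn dominant
usage is too small to give up the full magnitude have it raised above
`magnitude + 5%` before planting, so the planted ΔFR is exactly
−magnitude in expectation. The survival cohort is exponential
proportional hazards with a binary threshold covariate (baseline median
900 days, cutoff at the median of the lognormal expression distribution,
censoring at 5 years) — the simplest model the best-cutoff scan can
provably recover. A single global seed fans out to per-stage substreams
(annotation / counts / survival / assays / funnel), so each stage is
reproducible in isolation; identical configs give byte-identical files.

The qPCR table plants a ΔΔCt of −1.29 (a ≈2.45-fold induction, the
magnitude seen for the candidate gene's qPCR validation) with 0.15-cycle
well noise; the cytotoxicity table plants Δcytotoxicity = +20 points.
With noise set to 0 both are recovered exactly. Under 1-cycle Ct noise
the per-replicate RQ is lognormal around the planted fold change, so the
*median* recovered RQ is the unbiased summary the test asserts (the mean
is inflated by `exp(σ²ln²2/2)`).

What the generator does **not** emulate: positional/GC bias, variable
effective lengths, multi-mapping ambiguity, batch effects, correlated
gene-gene expression, non-proportional hazards, or covariate structure in
the cohort. Passing tests therefore demonstrate the correctness and
calibration of the statistics under their own model assumptions, not
robustness to real-data artifacts. Cohort-scale results of the original
study (its DEG and event counts, its specific log-rank p) are
data-dependent on an undeposited dataset and are deliberately not
asserted anywhere; the machinery that would produce them is verified on
fixtures and planted-truth simulations instead.

## Problem sizes in the checks

The statistical suites run at 2,000 null genes × 20 seeds (type-I error
and FDR), 500 genes × 20 seeds (planted recovery), 100 cohorts of 200
subjects (cutoff recovery) and 500 null cohorts (uniformity);
`scripts/acceptance.py` uses 10 expression seeds and 40 cohorts. These
sizes give Monte-Carlo error well inside the asserted margins while
keeping a laptop run in minutes.
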