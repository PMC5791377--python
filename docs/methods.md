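# Methods notes

This note records the modeling choices behind her2scape: what each statistic
assumes, what the synthetic-cohort generator does and does not emulate, and
the numerical conventions used throughout.

## Copy-number conventions

All coordinates are 1-based inclusive (SEG convention), in files and in
memory. Gene-level copy number is the base-pair-length-weighted mean of the
total CN of overlapping segments; genes with no overlapping segment are
missing (NaN) and are excluded per sample from downstream fractions rather
than imputed. When genes tile the segments exactly, this projection
preserves the per-sample genome-wide mean CN to numerical precision.

Ploidy travels with the copy-number table, not the sample metadata, because
cohorts profiled with targeted panels have no ploidy estimate; their samples
carry NaN ploidy and all ploidy-dependent calls become NA with a warning
recommending the total-copies scheme.

Ploidy-corrected copy number is reported on the ×2 scale (a diploid gene in
a diploid genome maps to 2), so the amplification cutoff is the literal
value 4. All cutoffs in the package are inclusive (≥).

## Bimodal overexpression thresholds

`fit_bimodal_threshold` fits two-component univariate Gaussian mixtures by
EM under two families — equal variance and unequal variance — and keeps the
family with the lower BIC (the family can also be forced). EM is initialized
deterministically: means at the 25th/75th percentiles, equal weights, the
pooled variance for both components; tolerance 1e-8, at most 1000
iterations. The threshold is the smallest point between the two component
means where the posterior membership probabilities are equal. For equal
variances this is the weight-adjusted midpoint; for unequal variances it is
the root of a closed-form quadratic restricted to the open interval between
the means. This rule was chosen over the density minimum because it is well
defined for unequal variances and reduces to the midpoint in the symmetric
case. Fits whose component means are within one (larger) standard deviation
of each other, or that fail to converge, are flagged low-confidence;
non-converged fits get a NaN threshold.

At zero noise the generator produces point masses, for which a mixture fit
is ill-posed; the regional-control analysis is therefore designed so that
its recovery does not hinge on the exact threshold position (see below).

## Concordance and McNemar

Scheme comparisons use the 2×2 agreement table (concordance, precision,
recall). The McNemar test is exact two-sided binomial on the discordant
counts when b + c < 25 and chi-square without continuity correction above —
the exact variant where it matters, the asymptotic one where the correction
is negligible.

## Chromosomal instability

CIN is the count of autosomal segments with distinct copy levels: adjacent
same-chromosome segments whose CN differs by at most 1e-6 are merged before
counting, making the statistic invariant to splitting segments into
equal-CN pieces. Breaks per kb per chromosome is (merged count − 1) divided
by the covered length in kb. Chromosome labels that are not purely numeric
(X, Y) are excluded.

## 17q event classes

Per sample, from total gene copy number on the q arm: arm-level
amplification when ≥ 80% of genes have CN ≥ 5; gain when ≥ 80% fall in
[2.5, 5); diploid when > 50% are below 2.5; precedence in that order.
Samples matching no rule are assigned the modal CN bin with a `*` flag —
an explicit artifact decision, surfaced in the output rather than hidden.
The thresholds are applied to total copies.

## Amplicon boundaries and co-amplification

The boundary analysis defines "amplified" as total CN ≥ 5 per gene, while
the genome-wide co-amplification screen uses the ploidy-corrected rule
(relcn ≥ 4); both are flags, because the two analyses answer different
questions (how far does the amplicon extend in amplified tumors vs. which
loci co-occur with amplification against the genome background). Spans are
maximal contiguous runs above the fraction threshold containing the anchor;
bp extents are inclusive differences + 1. The screen defaults to plain
Fisher exact + BH FDR; an optional Cochran–Mantel–Haenszel mode stratified
on instability (e.g. CIN tertiles) is exposed for separating
co-amplification from a shared instability background. Region merging
allows a configurable number of interior non-significant genes
(default 0).

## AR-ness

Z-scoring uses the n−1 standard-deviation denominator and is always
per cohort (per input table), across the ER-negative tumors only.
A strictly positive score calls a tumor AR-driven; a score of exactly zero
is negative. Signature genes on chromosome 17 are excluded at construction
time so amplicon dosage cannot leak into the score. The packaged default
signature file is a **synthetic stand-in** with the correct structure
(14 induced / 31 suppressed genes, none on chromosome 17): the authoritative
published gene list lives in supplementary material not distributed here,
so real analyses should rebuild the signature from MSigDB C2 GMT sources
with `build_signature` (membership in ≥ 2 of the positive source sets;
positive/negative collisions dropped from both sides with a warning).

## Differential expression

Per-gene ordinary least squares with two-sided t-tests on the contrast
coefficient replaces precision-weighted empirical-Bayes moderation — a
deliberate simplification: the package's guarantees are framed as recovery
of planted effects on synthetic cohorts, not reproduction of specific cohort
gene lists, and plain OLS keeps the estimator transparent. Fold change is
reported as the difference of group mean log2 expression, so "fold change
> 2" means |log2 FC| > 1. Categorical covariates are one-hot encoded with a
dropped reference level; rank-deficient designs raise an error naming the
collinear columns. Multi-cohort hit selection follows an at-least-one-cohort
rule.

## Regional control and methylation

Non-amplified overexpressors are samples above the overexpression threshold
without amplification under the ploidy scheme. The regional-control flag
requires all three closest neighbors (PGAP3, MIEN1, GRB7) to exceed +1 log2
unit relative expression (vs. the per-gene median of anchor-diploid samples,
per cancer stratum with ≥ 5 reference samples) while no distal neighbor
(MED1, CDK12, NR1D1, TOP2A) does — distinguishing a regional pattern from
arm-level elevation. Because the decision is made on this neighbor/distal
pattern, recovery of planted regional-control samples is robust to where the
mixture threshold lands between the expression modes.

The methylation test restricts probes to the gene bodies of ERBB2 and its
closest neighbors or at most 2 kb upstream of their TSS (strand-aware
distances are assumed provided by the probe map), then runs tie-corrected
Kruskal–Wallis across the four HER2A × overexpression groups with BH FDR.
Probes whose values are identical across all samples carry no group signal
and are assigned p = 1 rather than NaN. An empty group degrades to a test
across the remaining groups, with a notice.

## Prevalence arithmetic

Percentages and case estimates round half away from zero. Case estimates
use the rounded prevalence percentage by default; a per-row flag allows the
unrounded fraction, because published tables occasionally mix the two
conventions and the summed column is only reproducible with the convention
each row actually used.

## The synthetic cohort generator

The generator emulates, per tumor: ploidy drawn from a two-component
mixture (means 2.0 and 3.6, clipped to [1.8, 4.5]) representing diploid and
genome-doubled tumors; a focal amplicon around ERBB2 planted in 12% of
tumors at total CN max(5.2, 2·ploidy·U(1.05, 2.5)) capped at 20 — always
covering the 5-gene core (PNMT, PGAP3, ERBB2, MIEN1, GRB7), extending to
the 9-gene broad span (CDK12…CASC3) in an exact-count 70% subset of
amplified tumors, with geometric per-side breakpoint dispersion beyond the
broad span; q-arm gains (relative CN U(2.5, 3.2)) in 15% of tumors;
Poisson-rate instability breakpoints with ±U(0.3, 1.2) CN jitter, at a
1.5-fold higher rate in amplified tumors; a 3-gene trans co-amplified
region carried by 30% of amplified vs 2% of other tumors; and germline
CN artifact loci present in 8% of normals.

Expression follows `mu_g + beta_g·log2(max(relcn, 0.5)/2) + subtype effect
+ AR program + regional shift + N(0, noise_sd)` with noise_sd 0.5 —
a typical residual spread for log-scale bulk expression. Amplicon genes
have dosage slope 1; ERBB2 itself uses slope 2, reflecting the
super-proportional expression response of the amplified driver that gives
real cohorts their strongly bimodal HER2 distribution. The AR program
shifts the 14 positive signature genes by +0.5 log2 units (one default
noise sd) and the 31 negative genes by −0.5 in the 35% of ER-negative
tumors planted as AR-driven; the shift is an absolute quantity so that
zero-noise cohorts still carry a recoverable program. Regional-control
tumors (4% of non-amplified) gain +2.5 log2 units on ERBB2/PGAP3/MIEN1/GRB7
and lose 2.5 M-value units on the qualifying CpG probes of those genes.

Two construction guarantees keep truth labels exact: non-amplified tumors'
anchor neighborhoods are kept free of instability jitter and arm gains are
capped below the amplification cutoff, so at zero noise every planted
amplified tumor has relcn ≥ 4 and every other tumor is below it; and the
broad-amplicon extension uses an exact-count subset so planted per-gene
amplified fractions sit strictly between the 0.6 and 0.8 boundary
thresholds at any cohort size.

What the generator does **not** emulate: real hg19 coordinates and gene
density, linkage between loci, subclonality and tumor purity, batch and
platform effects, count-level noise models, and survival times. Passing the
recovery suites therefore demonstrates the pipeline's correctness on data
satisfying its model assumptions, not robustness to every artifact of real
cohorts.

## Problem sizes used in the test suite

Recovery checks run on 500-tumor cohorts over 20 seeds (the calling,
amplicon, co-amplification, AR-ness and dosage screens), with the null
differential-expression calibration at 5000 genes × 200 samples over 10
seeds and oracle-equivalence checks covering every 2×2 table up to n = 40,
all discordant-pair splits up to 24, 1000 random p-value vectors and 100
random rank-test instances. These sizes give stable pass/fail behavior for
the stated tolerances while keeping the default suite comfortably fast.

## Known limitations

- The centromere-corrected scheme estimates the centromere denominator from
  p-arm gene CN means; acrocentric-like annotations with no p-arm genes are
  rejected rather than approximated.
- The mixture threshold is undefined (NaN, flagged) when EM does not
  converge or when no posterior-equality point lies between the means, as
  happens for extremely unbalanced weights.
- Cytoband labels are not computed; region tables report first/last genes.
- The bundled AR-ness signature is a structural stand-in (see above), not
  the published gene list.
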