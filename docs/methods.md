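# Methods

## Model and procedure

The pipeline treats repeat expression as counts over RepeatMasker
subfamilies. A subfamily's count in a library is the sum over its genomic
loci of the number of aligned reads overlapping each locus by ≥ 1 bp
(bedtools-coverage semantics; a read spanning k loci contributes k times,
strand ignored). Counts are assumed negative-binomial with variance
μ + d·μ², where d is a single common dispersion shared by all subfamilies
and Θ = 1/d is the NB size parameter. This parameterization is stated once
here and used everywhere: generator, dispersion estimator, and regression.

### Normalization

TMM factors are computed against a reference sample (the one whose
upper-quartile of depth-scaled counts is closest to the mean upper
quartile). For each sample, M = log2 ratio and A = mean log2 abundance of
depth-scaled proportions are formed over features nonzero in both samples;
the most extreme 30% of M and 5% of A are trimmed; the remaining M are
averaged with inverse-variance weights; factors are rescaled to geometric
mean 1. Effective library size = raw column sum × factor.

Two weighting conventions are offered. The default computes the
delta-method variance of M from the count *proportions* at a common nominal
depth, which makes the factors exactly invariant to rescaling any single
sample's counts — a pure sequencing-depth change then moves only the
library size, never the factor. The `weights="library"` option uses each
library's own binomial variances (the edgeR convention) and reproduces
edgeR's `calcNormFactors` to machine precision (verified against frozen
edgeR 4.0 reference factors in the test suite). The two differ by well
under 1% on typical matrices; the proportion form was preferred because
exact depth invariance is the property downstream stages rely on.

RPKM = count / (feature kb × effective library size in millions), with
subfamily length = summed locus length.

### Dispersion

d is estimated by method of moments: counts are scaled to a common depth
using effective library sizes, and the per-feature estimate
max(0, (s² − μ̂)/μ̂²) is averaged over features with positive mean. With a
grouping (default: the control/starved series), moments are taken within
each group of ≥ 2 samples so that genuine between-series signal does not
inflate d; the starved series still carries the planted time trends, so on
the demo data the estimate lands slightly above the generating value
(≈ 0.12 at true 0.1). A conditional-maximum-likelihood refinement was
considered and rejected: the moment estimator is transparent, testable, and
accurate to well inside the tolerance the selection stage needs. d = 0
(Poisson) is allowed; Θ is then +inf and fits fall back to Poisson.

### Two-stage time-course selection

For each subfamily, an NB log-link GLM is fit (statsmodels, fixed Θ from
the normalization stage, log effective library sizes as offsets) on the
design: intercept, centered-time powers t¹..t^degree, a starved dummy, and
starved×time interactions (degree 2 by default). Stage 1 computes the
likelihood-ratio test of the full model against intercept-only; p-values
are BH-adjusted across features and thresholded at Q = 0.01. Stage 2 runs
backward stepwise elimination — repeatedly drop the non-intercept term with
the largest Wald p > 0.05 and refit — and requires the final model's
deviance r² = 1 − D_res/D_null (clipped to [0,1]) to reach 0.7. Backward
elimination was chosen over forward selection because the screened features
already carry strong global signal; a forward mode is a one-line switch in
`stepwise_select`. r² is defined on the deviance scale because the model is
NB; a Gaussian r² on log-RPKM gives similar orderings but is not the fitted
likelihood.

**No replicates:** the design has one library per (series, time) point.
All inference therefore leans on the externally fixed Θ; per-feature
variance cannot be checked against within-condition replicates. This is a
real limitation of both the emulated design and any dataset shaped like it,
and it is why the selection is deliberately conservative (Q = 0.01 *and*
r² ≥ 0.7).

Selected features are clustered on z-scored RPKM profiles, columns ordered
control-then-starved by time, with correlation distance and average-linkage
hierarchical clustering cut at k = 4 (matching the four observed profile
groups; k is exposed). Cluster ids are renumbered by descending mean z over
the late starvation time points, so up-clusters come first. Whether times
should enter the design on a log scale is not determinable from the emulated
study; raw centered hours are the default and `log_time=True` is available.

### Averaged differential expression

The alternative route averages the 15/30/72 h starvation libraries against
the three controls with a pooled-variance two-tailed t-test
(df = n₁+n₂−2). Repeat mode keeps p < 0.05 only; gene mode additionally
requires fold change > 2 and an average of ≥ 5 counts over the six compared
samples. The statistic is computed on RPKM by default (the scale choice
matters little for a ratio-based test; a raw-normalized-count mode exists).
Fold changes use a 0.5 pseudocount to stay finite at zeros. Constant-equal
groups give t = 0, p = 1; constant-unequal groups are flagged degenerate
with p = 0 rather than silently dropped.

### Enrichment

Class/family enrichment builds, per category and per set (cluster or
up/down list), the 2×2 table of membership against the background of *all*
taxonomy subfamilies, and computes the exact two-sided Fisher p as the sum
of hypergeometric probabilities ≤ the observed table's (relative tie slack
1e-12). The odds ratio is the sample estimate ad/bc with Haldane's 0.5
correction when a cell is zero. Raw p drives the reporting tiers (* p<0.05,
*** p<0.001), mirroring figure-style annotation without multiplicity
correction across the handful of classes; BH-adjusted p is always reported
alongside. Gene-set ORA uses the same machinery one-sided (greater) over a
GMT collection intersected with the expressed-gene background, ranks by
adjusted p (ties by odds ratio), and flags adjusted p < 0.05; the q-value
threshold of 0.2 used in some workflows is approximated by the BH-adjusted
p unless a dedicated q-value estimator is wired in.

### qPCR quantification

Relative expression uses the efficiency-corrected (Pfaffl) ratio
E_t^ΔCt_t / E_r^ΔCt_r with ΔCt = Ct(control) − Ct(sample) and per-gene
amplification efficiencies E ∈ (1, 2], defaulting to 2 (perfect doubling)
when unknown. Ratios are computed per technical replicate (replicate i of
the target paired with replicate i of the reference) and then summarized —
mean ± SD by default, SEM or half-range as options — with the control
condition pinned at 1. Averaging Ct before forming the ratio is available
behind `scheme` conventions but ratio-per-replicate is the default because
the dispersion of fold changes, not of cycles, is what is reported.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical design* of the study: two series
(control 6/30/120 h, starved 6/15/30/72/120 h), one library per point,
NB counts with common d over ~2000 subfamilies drawn from realistic class
proportions (SINE 0.30, LINE 0.30, LTR 0.15, DNA 0.15, Satellite 0.05,
Others 0.05), log-normal baseline abundances, planted expression archetypes
in log2 space (linear ramp up; transient peak at 15 h; flat then dropping
after 72 h; linear ramp down) with maximum effect 3 log2 units at 120 h,
class-biased planting (70% of up-archetype features drawn from LTR, 70% of
down from LINE), and a progressively induced single-copy transgene. Library
sizes default to 2×10⁵ reads — scaled down from the 10–20 M of a real
experiment so the complete pipeline and test suite run in minutes on one
CPU while keeping NB asymptotics meaningful.

It does **not** emulate: sequence content or alignment artifacts (reads are
placed uniformly within loci), multi-mapping ambiguity between subfamilies,
GC/length biases, batch effects, or biological correlation between
subfamilies of the same family. Passing tests therefore demonstrate that
the *statistics* of the pipeline behave as designed under the assumed NB
model, not that a specific biological dataset would reproduce.

Archetype shapes were chosen to be mutually distinguishable smooth curves;
with d = 0.1 and 8 time points the planted-archetype cluster recovery
(adjusted Rand index at k = 4) is typically 0.7–0.9 depending on seed — the
two down-shaped archetypes are genuinely the closest pair. The fixed-seed
acceptance test documents the recovery level at the demo conditions.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; RepeatMasker `.out`
  (1-based inclusive) is converted at parse time only.
- GLM fits: IRLS with tol 1e-8, max 100 iterations; non-converging or
  non-finite fits flag the feature `unfit` and exclude it from selection.
- BH adjustment is applied over all features with a finite global p.
- Fisher two-sided ties use a 1+1e-12 relative slack, the standard guard
  against float jitter in pmf comparisons.
- Stepwise elimination treats a non-finite Wald p as "worst" and drops that
  term first; if every term is eliminated the feature keeps an empty term
  set and r² = 0.
- `tmm_factors` errors on all-zero samples; `estimate_common_dispersion`
  errors with < 2 samples; `cluster_profiles` errors when k exceeds the
  number of features; empty enrichment sets error rather than returning
  vacuous tables.
- The CLI writes a manifest (parameters, seed, input checksums, version; no
  timestamps) with every stage, so identical configuration yields
  byte-identical artifacts.

## Known limitations

- Common (not per-feature) dispersion; empirical-Bayes tagwise shrinkage is
  out of scope and would require replicates to be worthwhile here.
- Counting is interval-based and strand-agnostic; no EM reassignment of
  multi-mapping reads across subfamilies.
- The maximum-likelihood path assumes the fixed-Θ NB is correct; model
  misspecification (e.g. zero inflation) is not diagnosed.
- Cluster count k must be chosen by the user; no gap-statistic or silhouette
  selection is built in.
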