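# Methods

## Model

For each gene within one intervention protocol, the pipeline treats the
per-study log2 fold-changes y_i (POST − PRE; for inactivity, post-bed-rest
minus baseline) with sampling variances v_i as draws from

    y_i = μ + u_i + ε_i,   u_i ~ N(0, τ²),   ε_i ~ N(0, v_i),

independent across studies. Assumptions: the within-study summaries are
approximately normal with known variance; true study effects vary
normally around a common mean; studies are exchangeable within a protocol
once subgroup filters (health status, muscle, biopsy timing, sex, age)
have been applied. Moderator effects are handled by filtering, not by
meta-regression.

## Within-study differential expression

Paired designs use per-subject differences d_s = POST − PRE:
logFC = mean(d), v = sd²(d)/n, t on n−1 df, two-sided p, 95% CI from the
t quantile, BH FDR across the study's genes (over non-missing p only).
Unpaired designs use Welch statistics with Satterthwaite df. Genes with
fewer than two complete pairs (or fewer than two samples per condition)
are emitted with missing statistics and an aggregate warning — they are
then invisible to pooling, which requires finite (y, v).

Degenerate inputs: a sample variance of exactly zero (constant
differences, typical of toy fixtures) is floored at v = 1e−8 and the
record flagged `var_floored`, preserving the effect size for pooling
while keeping t and the CI finite.

Optional empirical-Bayes variance moderation (method of moments on log
variances, shrinkage toward the grand mean with the usual
signal/(signal+noise) weight) is available behind a flag and OFF by
default; plain per-gene statistics are the reference path.

## Random-effects estimation

τ² is estimated by REML, maximizing the profile restricted log-likelihood
l_R(τ²) over τ² ≥ 0. The optimizer evaluates a 129-point linear grid on
[0, 10·var(y)] and refines the best cell with bounded scalar minimization
(absolute tolerance 1e−8, ≤200 iterations), then compares against the
τ² = 0 boundary. This derivative-free scheme is monotone-safe and
directly checkable: the test suite and acceptance script verify agreement
with an independent dense-grid maximizer to 1e−4 in τ² and 1e−6 in μ̂,
and with the R package metafor on a fixture. If the bounded refinement
ever fails to converge, the DerSimonian–Laird moment estimate
τ̂² = max(0, (Q−(k−1))/C) is substituted and the row flagged
`NONCONVERGED_FALLBACK`.

Inference on μ̂ is Wald-normal: SE = (Σ w_i)^{−1/2}, CI = μ̂ ± z₀.₉₇₅·SE,
p = 2Φ(−|z|). The Knapp–Hartung small-sample adjustment is deliberately
not the default; the plain Wald interval is the reference behavior. A
consequence, quantified by the acceptance script's coverage benchmark, is
mild under-coverage at small study counts: at K = 8 with τ² comparable to
the sampling variances the realized 95% coverage is ≈ 92–93%, the
well-documented price of plugging an estimated τ² into a normal interval.

Genes contributed by fewer than `min_k = 3` studies are reported
`TOO_FEW_STUDIES` with all estimates missing — pooling two studies gives
a meaningless τ̂² — matching the NA convention of sparse protocols
(e.g. HIIT). BH FDR is applied across the successfully pooled genes of
one protocol, never across protocols, mirroring per-protocol reporting.

## Cross-study concordance

The genes × studies log2FC matrix takes the union of genes; platform
differences appear as explicit missingness. Genes missing in more than
10% of studies are excluded *before* imputation (the stated order of
operations). Remaining gaps are filled by nearest-neighbor averaging:
neighbors are restricted to complete-profile genes, distance is Euclidean
over the columns the target gene was observed in (so imputations never
feed imputations), and k = 10 by default — the conventional default for
this imputation family; fewer complete genes ⇒ use all. Observed cells
are never modified.

PCA treats studies as observations and genes as variables, centers per
gene, and does not scale to unit variance — fold-changes already share a
log2 scale. Component signs follow the largest-loading-positive
convention so runs are reproducible. Pearson correlations require a
complete matrix; zero-variance study columns yield missing entries with a
warning rather than NaN surprises downstream.

## Significance sets and enrichment

Significant sets require status OK, FDR strictly below the threshold, and
a matching sign. Top-N ranking is by μ̂ with fully deterministic
tie-breaks (smaller FDR, then gene id). The healthy-specific rule flags
genes with FDR < 0.01 in the healthy table and FDR > 0.9 in the
metabolically impaired table of the same protocol. Concordance overlaps
(e.g. up in each acute modality, down in inactivity) take caller-supplied
per-protocol thresholds — published examples imply the contributing
thresholds were not uniform across protocols, so none are hard-coded;
0.05 is the suggested default.

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ overlap) with BH across sets — the core computation of the usual
enrichment tools — against user-supplied GMT collections. The universe is
the measured background: all genes with an OK pooled result in the
queried protocol. Complex projection averages pooled μ̂ over a complex's
measured genes, tolerating unmeasured members.

## Normalization choices

Quantile normalization maps every column onto the mean of the
column-sorted matrix; ties within a column receive the mean of the
reference values at their tied ranks, making the result deterministic and
row-order independent. RNA-seq counts enter through median-of-ratios size
factors (median over genes with all-positive counts of count/geometric
mean) followed by log2(count/s + 0.5); the 0.5 pseudocount keeps zero
counts finite while compressing low-count noise. Note the scale-free
invariant: multiplying one sample by c multiplies its size factor
*relative to the other samples* by c (the geometric-mean reference
absorbs c^(1/m)). Probe sets collapse to genes by per-sample median —
robust to outlying probes, no expression-level tie-breaking.

## Synthetic data generator

The generator emulates the statistical skeleton of a multi-study paired
collection: a fraction π of genes is truly responsive with signed effects
|μ_g| ~ N(effect_mean, effect_sd²) and Rademacher sign; study-level true
effects θ_gi ~ N(μ_g·a_i, τ²) with a_i an attenuation multiplier for
metabolically impaired study groups; observed effects add sampling noise
v = noise_sd²/n; platform coverage drops each (gene, study) independently.
Non-responsive genes carry no heterogeneity (τ²_g = 0), so a null
configuration yields exactly standard-normal pooled z-statistics — the
calibration the type-I benchmark checks. A single root seed spawns one
substream per study; appending studies never perturbs earlier draws, and
equal seeds reproduce tables bitwise.

Two levels are provided: direct effect-level sampling (the structure the
pooling model assumes, with exact v — used for calibration benchmarks,
where p-values are exact), and subject-level paired expression matrices
(baseline N(7,1) log2 intensities, POST = PRE + θ_gi + N(0, noise_sd²))
that exercise the full ingest → DE → pooling path. The two agree on
pooled estimates within Monte-Carlo error; the subject-level path
estimates each v from n−1 df, so its tail p-values are slightly
anti-conservative — realistic, and the reason calibration claims are
benchmarked at effect level while the subject-level path is benchmarked
on effect recovery (pooled μ̂ within 3 SE of truth for ≥90% of responsive
genes).

Benchmark defaults (chosen once as realistic for this literature):
8 studies × 10 subjects, π = 0.05, effect_mean = 1.0, effect_sd = 0.3
log2 units, τ = 0.2 (heterogeneity SD comparable to half the typical
sampling SD), subject-level response SD 0.8, 95% gene coverage, root seed
20200124.

What the generator does **not** emulate: probe-level microarray
artifacts, batch and lab effects, count overdispersion, correlated genes,
or missingness that tracks platform families. Passing recovery benchmarks
therefore demonstrates the estimator and pipeline are correct under the
model's assumptions — not that real cross-platform collections satisfy
those assumptions.

## Problem sizes

Benchmarks run at 2000 genes × 8 studies (calibration, benchmark
pipeline), 1000 replicates (CI coverage), 500 genes × 50 studies
(recovery), and 200 random instances (REML oracle agreement) — large
enough for the Monte-Carlo tolerances they assert while keeping a full
run in the tens of seconds.

## Known limitations

- Wald intervals under-cover at small K (≈92–93% at K = 8); enable the
  planned Knapp–Hartung flag for conservative small-K inference.
- No meta-regression: phenotype effects are explored only by subgroup
  filtering, so confounded moderators cannot be separated.
- Identifier spaces are taken as given (one namespace per collection); no
  cross-namespace translation.
- The RNA-seq path is a size-factor log transform, not a count model;
  very low counts are better served upstream by a dedicated count
  pipeline whose per-study effects can be imported directly.
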