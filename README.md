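# myometa

Gene-wise random-effects meta-analysis of multi-study skeletal-muscle
transcriptomic responses to exercise and inactivity.

## The problem

Dozens of small human studies have profiled the skeletal-muscle
transcriptome before and after acute aerobic or resistance exercise,
exercise training, or enforced inactivity (bed rest / limb unloading).
Individually these cohorts are underpowered and heterogeneous — different
platforms, muscles, ages, sexes, and metabolic health — so single-study
gene lists disagree. Pooling them per gene with a random-effects model
recovers the consistent transcriptional response while explicitly modelling
between-study heterogeneity, and lets any single gene be interrogated as a
forest of study effects plus a pooled score.

`myometa` is a tested, reusable implementation of that pipeline for
researchers in exercise physiology and muscle transcriptomics:

- **ingest** — TSV expression tables (paired `subject:PRE/POST` columns),
  quantile normalization for arrays, median-of-ratios log2 transform for
  RNA-seq counts, probe→gene collapse, annotations, GMT gene sets,
  complex maps;
- **within-study DE** — paired (per-subject POST−PRE) or Welch unpaired
  statistics per gene: log2FC, sampling variance, t, p, Benjamini–Hochberg
  FDR, 95% CI;
- **meta-analysis** — REML random-effects pooling per gene with
  DerSimonian–Laird fallback, Cochran's Q, I², per-protocol BH FDR, forest
  records, fold-change conversion;
- **cross-study concordance** — genes × studies log2FC matrix, 10%
  missingness filter, k-nearest-neighbor imputation, Pearson correlation
  matrix, study-level PCA;
- **set operations & enrichment** — significance sets, Venn regions, top-N
  responders, healthy-vs-impaired specificity rule, exercise/inactivity
  concordance overlaps, hypergeometric over-representation, complex-level
  fold-change projection;
- **synthetic data** — a seeded multi-study paired-design generator with
  known truth, for calibration and recovery benchmarking;
- **CLI** — `myometa run|simulate|ingest|de|meta|crossstudy|enrich|gene`.

## The model

For one gene and one protocol, each contributing study i supplies an
observed log2 fold-change y_i with sampling variance v_i. The
random-effects model is

    y_i = μ + u_i + ε_i,   u_i ~ N(0, τ²),   ε_i ~ N(0, v_i)

τ² (between-study variance) is estimated by restricted maximum likelihood,
maximizing the profile log-likelihood

    l_R(τ²) = −½ [ Σ ln(v_i + τ²) + ln Σ w_i + Σ w_i (y_i − μ̂)² ]

with weights w_i = 1/(v_i + τ²) and μ̂ = Σ w_i y_i / Σ w_i. Inference on
the pooled effect is Wald: SE(μ̂) = (Σ w_i)^{−1/2}, z = μ̂/SE,
CI = μ̂ ± 1.96·SE, with BH adjustment across genes within a protocol.
Heterogeneity is reported as Cochran's Q and I² = max(0, (Q−(k−1))/Q)·100.
The non-iterative DerSimonian–Laird moment estimator
τ̂² = max(0, (Q−(k−1))/C) serves as the fallback if the optimizer fails.
Genes contributed by fewer than `min_k` studies (default 3) are reported
`TOO_FEW_STUDIES` rather than pooled.

## Worked example

Simulate a collection of eight paired acute-aerobic studies (10 subjects
each, 5% truly responsive genes, between-study SD τ = 0.2), pool every
gene, and inspect the strongest responder:

```python
from myometa import (SimulationConfig, StudySpec, simulate_effect_table,
                     meta_all_genes, query_gene, logfc_to_fold)

spec = StudySpec(protocol="acute_aerobic", n_subjects=10, noise_sd=0.8)
config = SimulationConfig(n_genes=500, studies=(spec,) * 8,
                          pi_responsive=0.05, effect_mean=1.0,
                          effect_sd=0.3, tau=0.2, seed=20200124)
effects, truth = simulate_effect_table(config)
result = meta_all_genes(effects, "acute_aerobic", min_k=3)

hits = result[(result.status == "OK") & (result.fdr < 0.01)]
print(f"{len(hits)} of {len(result)} genes significant at meta FDR < 1%")
top = result.sort_values("mu", ascending=False).iloc[0]
fold, pct = logfc_to_fold(top.mu)
print(f"strongest induction: {top.gene}  mu={top.mu:.2f} "
      f"({fold:.1f}-fold, 95% CI [{top.ci_low:.2f}, {top.ci_high:.2f}]), "
      f"tau2={top.tau2:.3f}, I2={top.I2:.0f}%, k={int(top.k)}, fdr={top.fdr:.1e}")
```

prints

```
31 of 500 genes significant at meta FDR < 1%
strongest induction: G293  mu=1.79 (3.4-fold, 95% CI [1.55, 2.03]), tau2=0.055, I2=46%, k=8, fdr=5.3e-46
```

i.e. gene G293 is induced 3.4-fold on average across the eight studies,
with moderate heterogeneity (46% of the total variability between
studies). `query_gene(top.gene, ["acute_aerobic"], effects)` returns the
per-study forest behind that pooled row — each study's log2FC, CI and FDR
plus the meta row — exactly what the per-gene interrogation surface
serves. Against the generator's truth, this run calls 31 genes at meta
FDR < 0.05 with sensitivity 0.94 and no false discoveries.

The same analysis runs from a YAML config on the command line:

```sh
myometa run --config config.yaml --seed 20200124 --out results/
```

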