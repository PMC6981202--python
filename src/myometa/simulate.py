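"""Synthetic multi-study paired transcriptome experiments.

The generator emulates a collection of paired pre/post intervention studies
with the statistical structure the random-effects stage assumes: a sparse
set of truly responsive genes with signed log2 effects, between-study
heterogeneity τ², study-specific sampling noise, platform-dependent gene
coverage, and optional attenuation of true effects in metabolically
impaired (MTI) study groups.

Two entry points exist at different levels: :func:`simulate_effect_table`
draws per-study effect summaries directly (fast, for testing the pooling
engine), while :func:`simulate_expression_studies` draws subject-level
paired expression matrices so the full ingest → within-study → meta
pipeline can be exercised.  A single root seed spawns one substream per
study, so adding a study never perturbs earlier studies' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    Design, EffectTable, ExpressionStudy, HealthStatus, Protocol,
    StudyAnnotation, STATUS_OK, POST, PRE,
)
from .within_study import bh_adjust

#: Default root seed for stochastic runs.
DEFAULT_SEED = 20200124


@dataclass(frozen=True)
class StudySpec:
    """One simulated study group."""

    protocol: Protocol
    n_subjects: int
    noise_sd: float
    gene_coverage_fraction: float = 1.0
    health_status: HealthStatus = HealthStatus.HLY

    def __post_init__(self):
        object.__setattr__(self, "protocol", Protocol.coerce(self.protocol))
        object.__setattr__(self, "health_status",
                           HealthStatus.coerce(self.health_status))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.gene_coverage_fraction <= 1.0:
            raise ValueError("gene_coverage_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-collection configuration for the generator."""

    n_genes: int
    studies: tuple[StudySpec, ...]
    pi_responsive: float
    effect_mean: float
    effect_sd: float
    tau: float
    mti_attenuation: float = 1.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        object.__setattr__(self, "studies", tuple(self.studies))
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.pi_responsive <= 1.0:
            raise ValueError("pi_responsive must lie in [0, 1]")
        if self.effect_sd < 0 or self.tau < 0:
            raise ValueError("effect_sd and tau must be >= 0")
        if not 0.0 <= self.mti_attenuation <= 1.0:
            raise ValueError("mti_attenuation must lie in [0, 1]")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def study_ids(self) -> list[str]:
        counts: dict[str, int] = {}
        ids = []
        for spec in self.studies:
            counts[spec.protocol.name] = counts.get(spec.protocol.name, 0) + 1
            ids.append(f"sim_{spec.protocol.value}_{counts[spec.protocol.name]:02d}")
        return ids

    def annotations(self) -> list[StudyAnnotation]:
        out = []
        for sid, spec in zip(self.study_ids(), self.studies):
            out.append(StudyAnnotation(
                study_id=sid, protocol=spec.protocol,
                n_subjects=spec.n_subjects,
                health_status=spec.health_status,
            ))
        return out


def load_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file.

    Study entries accept an optional ``count`` to repeat a spec, e.g.::

        n_genes: 2000
        pi_responsive: 0.05
        effect_mean: 1.0
        effect_sd: 0.3
        tau: 0.2
        seed: 20200124
        studies:
          - {protocol: acute_aerobic, n_subjects: 10, noise_sd: 0.8, count: 8}
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimulationConfig:
    specs: list[StudySpec] = []
    for entry in raw.get("studies", []):
        entry = dict(entry)
        count = int(entry.pop("count", 1))
        spec = StudySpec(
            protocol=entry["protocol"],
            n_subjects=int(entry["n_subjects"]),
            noise_sd=float(entry["noise_sd"]),
            gene_coverage_fraction=float(entry.get("gene_coverage_fraction", 1.0)),
            health_status=entry.get("health_status", HealthStatus.HLY),
        )
        specs.extend([spec] * count)
    return SimulationConfig(
        n_genes=int(raw["n_genes"]),
        studies=tuple(specs),
        pi_responsive=float(raw["pi_responsive"]),
        effect_mean=float(raw["effect_mean"]),
        effect_sd=float(raw.get("effect_sd", 0.0)),
        tau=float(raw["tau"]),
        mti_attenuation=float(raw.get("mti_attenuation", 1.0)),
        seed=int(raw.get("seed", DEFAULT_SEED)),
    )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated collection, for recovery metrics."""

    genes: list[str]
    responsive: np.ndarray          # bool per gene
    mu: np.ndarray                  # true pooled effect per gene
    tau2: np.ndarray                # true between-study variance per gene
    theta: pd.DataFrame             # realized study effects, genes x studies


def _gene_level_truth(config: SimulationConfig, rng: np.random.Generator):
    g = config.n_genes
    responsive = rng.random(g) < config.pi_responsive
    signs = rng.choice([-1.0, 1.0], size=g)
    magnitudes = rng.normal(config.effect_mean, config.effect_sd, size=g)
    mu = np.where(responsive, signs * magnitudes, 0.0)
    # null genes carry no heterogeneity so that, with pi = 0 and tau = 0,
    # pooled z-statistics are standard normal
    tau2 = np.where(responsive, config.tau ** 2, 0.0)
    return responsive, mu, tau2


def _study_streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + len(config.studies))
    gene_rng = np.random.default_rng(children[0])
    study_rngs = [np.random.default_rng(c) for c in children[1:]]
    return gene_rng, study_rngs


def simulate_effect_table(config: SimulationConfig
                          ) -> tuple[EffectTable, SyntheticTruth]:
    """Draw per-study effect summaries directly.

    For each study i: realized effect θ_gi ~ N(μ_g·a_i, τ²_g) with
    a_i = ``mti_attenuation`` for MTI studies (1 otherwise); the observed
    y_gi ~ N(θ_gi, v_gi) with v_gi = noise_sd²/n_subjects; each (gene,
    study) is dropped with probability 1 − gene_coverage_fraction.
    """
    genes = config.gene_ids()
    gene_rng, study_rngs = _study_streams(config)
    responsive, mu, tau2 = _gene_level_truth(config, gene_rng)
    tau_sd = np.sqrt(tau2)

    study_ids = config.study_ids()
    theta_cols = {}
    frames = []
    for spec, sid, rng in zip(config.studies, study_ids, study_rngs):
        a = (config.mti_attenuation
             if spec.health_status is HealthStatus.MTI else 1.0)
        theta = mu * a + tau_sd * rng.standard_normal(config.n_genes)
        v = spec.noise_sd ** 2 / spec.n_subjects
        y = theta + np.sqrt(v) * rng.standard_normal(config.n_genes)
        observed = rng.random(config.n_genes) < spec.gene_coverage_fraction
        theta_cols[sid] = theta

        n = spec.n_subjects
        df = n - 1
        var = np.full(config.n_genes, v)
        if v > 0 and df > 0:
            from scipy import stats as _st
            t = y / np.sqrt(v)
            p = 2.0 * _st.t.sf(np.abs(t), df)
            tcrit = float(_st.t.ppf(0.975, df))
            ci_low = y - tcrit * np.sqrt(v)
            ci_high = y + tcrit * np.sqrt(v)
        else:
            t = np.full(config.n_genes, np.nan)
            p = np.full(config.n_genes, np.nan)
            ci_low = np.full(config.n_genes, np.nan)
            ci_high = np.full(config.n_genes, np.nan)
        frame = pd.DataFrame({
            "gene": genes, "study_id": sid, "logfc": y, "var": var,
            "n": float(n), "t": t, "df": float(df), "p": p,
            "fdr": bh_adjust(p), "ci_low": ci_low, "ci_high": ci_high,
        })
        frames.append(frame.loc[observed])

    table = EffectTable(frame=pd.concat(frames, ignore_index=True),
                        studies=config.annotations())
    truth = SyntheticTruth(
        genes=genes, responsive=responsive, mu=mu, tau2=tau2,
        theta=pd.DataFrame(theta_cols, index=genes),
    )
    return table, truth


def simulate_expression_studies(config: SimulationConfig
                                ) -> tuple[list[ExpressionStudy], SyntheticTruth]:
    """Draw subject-level paired PRE/POST expression matrices.

    Each subject's PRE value is a gene-specific baseline draw from N(7, 1)
    (log2 intensity scale); POST = PRE + θ_gi + N(0, noise_sd²) per subject.
    Studies omit each gene with probability 1 − gene_coverage_fraction.
    """
    genes = np.array(config.gene_ids())
    gene_rng, study_rngs = _study_streams(config)
    responsive, mu, tau2 = _gene_level_truth(config, gene_rng)
    tau_sd = np.sqrt(tau2)

    studies = []
    theta_cols = {}
    for spec, sid, rng in zip(config.studies, config.study_ids(), study_rngs):
        a = (config.mti_attenuation
             if spec.health_status is HealthStatus.MTI else 1.0)
        theta = mu * a + tau_sd * rng.standard_normal(config.n_genes)
        theta_cols[sid] = theta
        n = spec.n_subjects
        baseline = rng.normal(7.0, 1.0, size=(config.n_genes, n))
        noise = rng.normal(0.0, spec.noise_sd, size=(config.n_genes, n)) \
            if spec.noise_sd > 0 else np.zeros((config.n_genes, n))
        post = baseline + theta[:, None] + noise
        observed = rng.random(config.n_genes) < spec.gene_coverage_fraction

        subjects = [f"{sid}_S{j + 1}" for j in range(n)]
        cols = pd.MultiIndex.from_tuples(
            [(s, c) for s in subjects for c in (PRE, POST)],
            names=["subject", "condition"],
        )
        mat = np.empty((config.n_genes, 2 * n))
        mat[:, 0::2] = baseline
        mat[:, 1::2] = post
        frame = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                             columns=cols).loc[observed]
        studies.append(ExpressionStudy(sid, frame, Design.PAIRED))

    truth = SyntheticTruth(
        genes=list(genes), responsive=responsive, mu=mu, tau2=tau2,
        theta=pd.DataFrame(theta_cols, index=genes),
    )
    return studies, truth


def evaluate_truth(results: pd.DataFrame, truth: SyntheticTruth,
                   fdr_threshold: float = 0.05) -> dict:
    """Recovery metrics of a pooled table against the generator's truth.

    Returns sensitivity (responsive genes called at the FDR threshold),
    observed false-discovery proportion, mean bias of the pooled effect
    among responsive genes, and realized CI coverage of the true μ_g.
    """
    truth_idx = pd.Index(truth.genes)
    res_idx = pd.Index(results["gene"])
    if set(res_idx) - set(truth_idx):
        raise ValueError("results contain genes absent from the truth record")
    tr = pd.DataFrame({"responsive": truth.responsive, "mu_true": truth.mu},
                      index=truth_idx)
    merged = results.set_index("gene").join(tr, how="left")
    ok = merged["status"] == STATUS_OK
    called = ok & merged["fdr"].notna() & (merged["fdr"] < fdr_threshold)
    n_responsive = int(tr["responsive"].sum())
    tp = int((called & merged["responsive"]).sum())
    fp = int((called & ~merged["responsive"]).sum())
    resp_ok = ok & merged["responsive"]
    bias = float((merged.loc[resp_ok, "mu"]
                  - merged.loc[resp_ok, "mu_true"]).mean()) if resp_ok.any() else float("nan")
    cover = ((merged["ci_low"] <= merged["mu_true"])
             & (merged["mu_true"] <= merged["ci_high"]))
    coverage = float(cover[ok].mean()) if ok.any() else float("nan")
    return {
        "n_genes": int(len(merged)),
        "n_responsive": n_responsive,
        "n_called": int(called.sum()),
        "sensitivity": tp / n_responsive if n_responsive else float("nan"),
        "fdp": fp / max(int(called.sum()), 1),
        "mean_bias_mu": bias,
        "ci_coverage": coverage,
    }


def benchmark_config(seed: int = DEFAULT_SEED, n_genes: int = 2000,
                     n_studies: int = 8) -> SimulationConfig:
    """Reference benchmark: a sparse-signal acute-exercise collection.

    Eight paired studies of ten subjects each, 5% responsive genes with
    mean |log2FC| 1.0 (SD 0.3), between-study SD τ = 0.2, subject-level
    response SD 0.8 and 95% platform gene coverage — sizes and noise chosen
    to resemble a well-powered multi-study acute-exercise collection.
    """
    spec = StudySpec(protocol=Protocol.ACUTE_AEROBIC, n_subjects=10,
                     noise_sd=0.8, gene_coverage_fraction=0.95)
    return SimulationConfig(
        n_genes=n_genes, studies=(spec,) * n_studies, pi_responsive=0.05,
        effect_mean=1.0, effect_sd=0.3, tau=0.2, seed=seed,
    )
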