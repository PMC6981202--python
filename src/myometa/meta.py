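"""Gene-wise random-effects meta-analysis.

Model: observed study effects y_i = μ + u_i + ε_i with u_i ~ N(0, τ²) and
ε_i ~ N(0, v_i), where y_i is a study's log2 fold-change for a gene and v_i
its sampling variance.  τ² is estimated by restricted maximum likelihood
(REML), with the non-iterative DerSimonian–Laird moment estimator as a
fallback; μ is the inverse-variance weighted mean at the estimated τ², with
SE = (Σ w_i)^{-1/2}, w_i = 1/(v_i + τ²).

The REML profile log-likelihood maximized over τ² ≥ 0 is

    l_R(τ²) = −½ [ Σ ln(v_i + τ²) + ln Σ w_i + Σ w_i (y_i − μ̂(τ²))² ]

up to an additive constant.  The optimizer is a coarse grid over
[0, τ²_max] with τ²_max = 10·var(y) followed by bounded scalar refinement
(absolute tolerance 1e-8), which is derivative-free and directly checkable
against a dense-grid oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .filters import SubgroupFilter, subset_studies
from .types import (
    EffectTable, META_COLUMNS, Protocol, STATUS_FALLBACK, STATUS_OK,
    STATUS_TOO_FEW,
)
from .within_study import bh_adjust

log = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))

#: Default minimum number of contributing studies per gene.  Below this the
#: pooled statistics are not meaningful and the gene is reported NA.
DEFAULT_MIN_K = 3


def _validate_yv(y, v):
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("y and v must be 1-D vectors of equal length")
    if len(y) < 2:
        raise ValueError("at least two studies are required (k >= 2)")
    if not (np.isfinite(y).all() and np.isfinite(v).all()):
        raise ValueError("y and v must be finite")
    if (v <= 0).any():
        raise ValueError("all sampling variances must be positive")
    return y, v


def dl_tau2(y, v) -> float:
    """DerSimonian–Laird moment estimator of τ² (truncated at zero)."""
    y, v = _validate_yv(y, v)
    w = 1.0 / v
    mu_f = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_f) ** 2))
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    k = len(y)
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def heterogeneity_stats(y, v) -> tuple[float, float]:
    """Cochran's Q and I² (% of total variability due to heterogeneity)."""
    y, v = _validate_yv(y, v)
    w = 1.0 / v
    mu_f = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_f) ** 2))
    k = len(y)
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, i2


def reml_loglik(tau2, y, v):
    """Profile restricted log-likelihood l_R(τ²); vectorized over tau2."""
    tau2 = np.asarray(tau2, dtype=float)
    scalar = tau2.ndim == 0
    t = np.atleast_1d(tau2)[:, None]
    tot = v[None, :] + t
    w = 1.0 / tot
    sw = w.sum(axis=1)
    mu = (w * y[None, :]).sum(axis=1) / sw
    ll = -0.5 * (np.log(tot).sum(axis=1) + np.log(sw)
                 + (w * (y[None, :] - mu[:, None]) ** 2).sum(axis=1))
    return float(ll[0]) if scalar else ll


@dataclass
class REMLFit:
    mu: float
    se: float
    tau2: float
    loglik: float
    estimator: str  # "REML" or "DL" (nonconvergence fallback)
    converged: bool


def _pool_at(tau2, y, v):
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return mu, se


def reml_fit(y, v, tau2_max: float | None = None, xatol: float = 1e-8,
             max_iter: int = 200) -> REMLFit:
    """REML estimate of (μ, τ²) with Wald SE.

    Coarse grid + bounded refinement on [0, τ²_max]; on optimizer failure
    the DerSimonian–Laird estimate is substituted and flagged.
    """
    y, v = _validate_yv(y, v)
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        # identical effects: τ² = 0 and the fixed-effect pooled mean
        mu, se = _pool_at(0.0, y, v)
        return REMLFit(mu, se, 0.0, reml_loglik(0.0, y, v), "REML", True)

    hi = tau2_max if tau2_max is not None else 10.0 * var_y
    grid = np.linspace(0.0, hi, 129)
    ll = reml_loglik(grid, y, v)
    i = int(np.argmax(ll))
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -reml_loglik(t, y, v), bounds=(lo_b, hi_b),
        method="bounded", options={"xatol": xatol, "maxiter": max_iter},
    )
    if res.success:
        tau2 = float(res.x)
        if -float(res.fun) < ll[i]:
            tau2 = float(grid[i])
        # honor the τ² >= 0 boundary
        candidates = [tau2, 0.0]
        tau2 = max(candidates, key=lambda t: reml_loglik(t, y, v))
        mu, se = _pool_at(tau2, y, v)
        return REMLFit(mu, se, tau2, reml_loglik(tau2, y, v), "REML", True)

    tau2 = dl_tau2(y, v)
    mu, se = _pool_at(tau2, y, v)
    log.warning("REML failed to converge (k=%d); DerSimonian–Laird fallback",
                len(y))
    return REMLFit(mu, se, tau2, reml_loglik(tau2, y, v), "DL", False)


def logfc_to_fold(mu: float) -> tuple[float, float]:
    """Convert a pooled log2 effect to (fold-change, percent change)."""
    if not np.isfinite(mu):
        raise ValueError("log2 effect must be finite")
    fold = float(2.0 ** mu)
    return fold, (fold - 1.0) * 100.0


def _na_row(gene, protocol, k):
    return {
        "gene": gene, "protocol": protocol.name, "k": k,
        "mu": np.nan, "se_mu": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "z": np.nan, "p": np.nan, "fdr": np.nan, "tau2": np.nan,
        "Q": np.nan, "I2": np.nan, "estimator": "NA",
        "status": STATUS_TOO_FEW,
    }


def meta_all_genes(effects: EffectTable, protocol,
                   filters: SubgroupFilter | None = None,
                   min_k: int = DEFAULT_MIN_K) -> pd.DataFrame:
    """Random-effects pooling of every gene within one protocol.

    Returns one row per gene (schema :data:`myometa.types.META_COLUMNS`).
    Genes observed in fewer than ``min_k`` studies are reported with status
    ``TOO_FEW_STUDIES`` and missing estimates; the BH FDR is computed across
    the protocol's successfully pooled genes.
    """
    protocol = Protocol.coerce(protocol)
    candidates = [a for a in effects.studies if a.protocol is protocol]
    selected = subset_studies(candidates, filters)
    if not selected:
        raise ValueError(
            f"no studies match protocol {protocol.name} under filter "
            f"{filters.describe() if filters is not None else '{}'}"
        )
    study_ids = [a.study_id for a in selected]
    sub = effects.frame[effects.frame["study_id"].isin(study_ids)]

    rows = []
    n_dropped_obs = 0
    for gene, grp in sub.groupby("gene", sort=True):
        ok = grp["logfc"].notna() & grp["var"].notna() & (grp["var"] > 0)
        n_dropped_obs += int((~ok).sum())
        y = grp.loc[ok, "logfc"].to_numpy(dtype=float)
        v = grp.loc[ok, "var"].to_numpy(dtype=float)
        k = len(y)
        if k < min_k:
            rows.append(_na_row(gene, protocol, k))
            continue
        fit = reml_fit(y, v)
        q, i2 = heterogeneity_stats(y, v)
        z = fit.mu / fit.se if fit.se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "gene": gene, "protocol": protocol.name, "k": k,
            "mu": fit.mu, "se_mu": fit.se,
            "ci_low": fit.mu - _Z975 * fit.se,
            "ci_high": fit.mu + _Z975 * fit.se,
            "z": z, "p": p, "fdr": np.nan,
            "tau2": fit.tau2, "Q": q, "I2": i2,
            "estimator": fit.estimator,
            "status": STATUS_OK if fit.converged else STATUS_FALLBACK,
        })
    if n_dropped_obs:
        log.info("protocol %s: dropped %d missing/invalid study observations "
                 "across genes", protocol.name, n_dropped_obs)
    frame = pd.DataFrame(rows, columns=META_COLUMNS)
    pooled = frame["status"] != STATUS_TOO_FEW
    if pooled.any():
        frame.loc[pooled, "fdr"] = bh_adjust(frame.loc[pooled, "p"].to_numpy())
    return frame


def forest_data(gene: str, protocol, effects: EffectTable,
                filters: SubgroupFilter | None = None,
                min_k: int = DEFAULT_MIN_K,
                meta_table: pd.DataFrame | None = None) -> dict:
    """Per-study rows plus the pooled meta row for one gene.

    Study rows follow the stable order of the effect table's annotations;
    studies lacking the gene are flagged ``missing``.  ``meta_table`` may be
    a precomputed :func:`meta_all_genes` result for the same filter set to
    avoid re-pooling every gene per query.
    """
    protocol = Protocol.coerce(protocol)
    if gene not in set(effects.genes):
        raise KeyError(f"unknown gene {gene!r}")
    candidates = [a for a in effects.studies if a.protocol is protocol]
    selected = subset_studies(candidates, filters)
    if not selected:
        raise ValueError(
            f"no studies match protocol {protocol.name} under the given filter"
        )
    sub = effects.frame[effects.frame["gene"] == gene].set_index("study_id")
    study_rows = []
    for ann in selected:
        base = {
            "study_id": ann.study_id,
            "protocol": ann.protocol.name,
            "health_status": ann.health_status.name,
            "muscle": ann.muscle.name,
            "biopsy_timing": ann.biopsy_timing.name,
            "n_subjects": ann.n_subjects,
        }
        if ann.study_id in sub.index and pd.notna(sub.loc[ann.study_id, "logfc"]):
            rec = sub.loc[ann.study_id]
            base.update({
                "missing": False,
                "logfc": float(rec["logfc"]),
                "ci_low": float(rec["ci_low"]) if pd.notna(rec["ci_low"]) else None,
                "ci_high": float(rec["ci_high"]) if pd.notna(rec["ci_high"]) else None,
                "fdr": float(rec["fdr"]) if pd.notna(rec["fdr"]) else None,
            })
        else:
            base.update({"missing": True, "logfc": None, "ci_low": None,
                         "ci_high": None, "fdr": None})
        study_rows.append(base)

    if meta_table is None:
        meta_table = meta_all_genes(effects, protocol, filters=filters,
                                    min_k=min_k)
    hit = meta_table[meta_table["gene"] == gene]
    if len(hit):
        meta_row = {k: (None if (isinstance(val, float) and np.isnan(val)) else val)
                    for k, val in hit.iloc[0].items()}
    else:
        meta_row = _na_row(gene, protocol, 0)
    return {
        "gene": gene,
        "protocol": protocol.name,
        "filters": filters.describe() if filters is not None else None,
        "studies": study_rows,
        "meta": meta_row,
    }
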