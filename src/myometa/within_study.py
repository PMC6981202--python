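"""Per-study differential expression for paired and unpaired designs.

Each gene in a study yields a log2 fold-change (POST − PRE), its sampling
variance, a t statistic, a two-sided p-value, a Benjamini–Hochberg FDR
computed within the study, and a 95% confidence interval.  These per-study
summaries are the observations (y_i, v_i) of the random-effects stage.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats, special
from statsmodels.stats.multitest import multipletests

from .types import (
    Design, EffectTable, ExpressionStudy, StudyAnnotation, EFFECT_COLUMNS,
    POST, PRE,
)

log = logging.getLogger(__name__)

#: Sampling variances of exactly zero (constant differences on a fixture)
#: are floored here so t/CI stay finite while the effect size is preserved.
VAR_FLOOR = 1e-8


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Missing entries pass through as missing; the adjustment is computed over
    the non-missing entries only.  Input order is preserved.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def moderate_variances(sample_vars: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Empirical-Bayes shrinkage of per-gene sample variances toward a pooled
    prior, by method of moments on log variances.

    log s² is roughly log σ² + noise with Var = ψ'(df/2); the signal variance
    is estimated by subtraction and each log variance is pulled toward the
    grand mean with the usual signal/(signal+noise) weight.  Offered behind a
    flag; plain per-gene variances are the default path.
    """
    sample_vars = np.asarray(sample_vars, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(sample_vars) & (sample_vars > 0) & (df > 0)
    out = sample_vars.copy()
    if ok.sum() < 2:
        return out
    logv = np.log(sample_vars[ok])
    noise = special.polygamma(1, df[ok] / 2.0)
    total = np.var(logv, ddof=1)
    signal = max(total - float(np.mean(noise)), 0.0)
    weight = signal / (signal + noise)
    center = float(np.mean(logv + special.polygamma(0, df[ok] / 2.0)
                           - np.log(df[ok] / 2.0)))
    out[ok] = np.exp(center + weight * (logv - center))
    return out


def _finalize(genes, study_id, logfc, var, n, df) -> pd.DataFrame:
    """Common tail of paired/unpaired DE: floor variances, t/p/CI, BH."""
    logfc = np.asarray(logfc, dtype=float)
    var = np.asarray(var, dtype=float)
    n = np.asarray(n, dtype=float)
    df = np.asarray(df, dtype=float)
    usable = np.isfinite(logfc) & np.isfinite(var) & (df > 0)

    floored = usable & (var < VAR_FLOOR)
    var = np.where(floored, VAR_FLOOR, var)
    if floored.any():
        log.warning("%s: floored %d zero/degenerate sampling variances",
                    study_id, int(floored.sum()))

    se = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(usable, logfc / se, np.nan)
        p = np.where(usable, 2.0 * stats.t.sf(np.abs(t), df), np.nan)
        tcrit = np.where(usable, stats.t.ppf(0.975, df), np.nan)
    ci_low = logfc - tcrit * se
    ci_high = logfc + tcrit * se
    fdr = bh_adjust(p)

    frame = pd.DataFrame({
        "gene": genes,
        "study_id": study_id,
        "logfc": np.where(usable, logfc, np.nan),
        "var": np.where(usable, var, np.nan),
        "n": n,
        "t": t,
        "df": np.where(usable, df, np.nan),
        "p": p,
        "fdr": fdr,
        "ci_low": np.where(usable, ci_low, np.nan),
        "ci_high": np.where(usable, ci_high, np.nan),
    })
    frame["var_floored"] = floored
    n_missing = int((~usable).sum())
    if n_missing:
        log.warning("%s: %d genes with too few observations; statistics "
                    "recorded as missing", study_id, n_missing)
    return frame


def paired_de(study: ExpressionStudy, moderate: bool = False) -> pd.DataFrame:
    """Paired differential expression: per-subject POST − PRE differences.

    For each gene with at least two complete pairs: logfc = mean(d),
    var = sd²(d)/n, t = logfc/√var on n−1 degrees of freedom, two-sided p,
    95% CI, and BH FDR over the study's genes.  Genes with fewer than two
    complete pairs yield missing statistics (with an aggregate warning).
    """
    if study.design is not Design.PAIRED:
        raise ValueError(f"{study.study_id}: paired_de requires a paired design")
    pre = study.condition_matrix(PRE)
    post = study.condition_matrix(POST)
    post = post.loc[:, pre.columns]  # align subjects
    d = post.to_numpy(dtype=float) - pre.to_numpy(dtype=float)

    complete = ~np.isnan(d)
    n = complete.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        mean_d = np.nanmean(np.where(complete, d, np.nan), axis=1)
        # sample variance of differences, ddof=1, over complete pairs
        dev = np.where(complete, d - mean_d[:, None], 0.0)
        ss = (dev ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_var = np.where(n >= 2, ss / np.maximum(n - 1, 1), np.nan)
    df = n - 1
    if moderate:
        sample_var = moderate_variances(sample_var, df)
    var = sample_var / n
    logfc = np.where(n >= 2, mean_d, np.nan)
    var = np.where(n >= 2, var, np.nan)
    return _finalize(study.genes, study.study_id, logfc, var, n, df)


def unpaired_de(study: ExpressionStudy, moderate: bool = False) -> pd.DataFrame:
    """Welch two-sample differential expression for unpaired designs.

    logfc = mean(POST) − mean(PRE); var = s²_post/n_post + s²_pre/n_pre;
    Welch–Satterthwaite degrees of freedom; p/CI/FDR as in :func:`paired_de`.
    """
    if study.design is not Design.UNPAIRED:
        raise ValueError(f"{study.study_id}: unpaired_de requires an unpaired design")
    pre = study.condition_matrix(PRE).to_numpy(dtype=float)
    post = study.condition_matrix(POST).to_numpy(dtype=float)

    def _moments(x):
        obs = ~np.isnan(x)
        n = obs.sum(axis=1).astype(float)
        mean = np.where(n > 0, np.nansum(x, axis=1) / np.maximum(n, 1), np.nan)
        dev = np.where(obs, x - mean[:, None], 0.0)
        s2 = np.where(n >= 2, (dev ** 2).sum(axis=1) / np.maximum(n - 1, 1), np.nan)
        return n, mean, s2

    n1, m1, s1 = _moments(pre)
    n2, m2, s2 = _moments(post)
    usable = (n1 >= 2) & (n2 >= 2)
    logfc = np.where(usable, m2 - m1, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = s1 / n1
        v2 = s2 / n2
        var = np.where(usable, v1 + v2, np.nan)
        # Welch–Satterthwaite; guard the zero-variance fixture case, where
        # the floored variance pairs with a conservative df
        num = (v1 + v2) ** 2
        den = v1 ** 2 / np.maximum(n1 - 1, 1) + v2 ** 2 / np.maximum(n2 - 1, 1)
        df = np.where(usable & (den > 0), num / np.where(den > 0, den, 1.0),
                      np.minimum(n1, n2) - 1)
    n_total = n1 + n2
    return _finalize(study.genes, study.study_id, logfc, var, n_total, df)


def differential_expression(study: ExpressionStudy,
                            moderate: bool = False) -> pd.DataFrame:
    """Dispatch to :func:`paired_de` or :func:`unpaired_de` by design."""
    if study.design is Design.PAIRED:
        return paired_de(study, moderate=moderate)
    return unpaired_de(study, moderate=moderate)


def build_effect_table(frames: Iterable[pd.DataFrame],
                       annotations: Iterable[StudyAnnotation]) -> EffectTable:
    """Stack per-study DE frames into one :class:`EffectTable`."""
    frames = list(frames)
    if not frames:
        raise ValueError("no effect frames supplied")
    combined = pd.concat(frames, ignore_index=True)
    keep = EFFECT_COLUMNS + [c for c in ("var_floored",) if c in combined.columns]
    return EffectTable(frame=combined[keep], studies=list(annotations))
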