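"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from the defining formula or by brute
force, sharing no code path with the implementation it validates.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bh_stepup(p):
    """Benjamini–Hochberg by direct sort / step-up / cummin-from-top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def reml_grid(y, v, hi=10.0, coarse_step=1e-3, fine_step=1e-6):
    """Dense-grid maximization of the REML profile log-likelihood.

    Two-stage grid: coarse over [0, hi], then fine around the coarse
    maximum; resolution fine_step in tau^2.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)

    def loglik(tau2_vec):
        tot = v[None, :] + tau2_vec[:, None]
        w = 1.0 / tot
        sw = w.sum(axis=1)
        mu = (w * y[None, :]).sum(axis=1) / sw
        return -0.5 * (np.log(tot).sum(axis=1) + np.log(sw)
                       + (w * (y[None, :] - mu[:, None]) ** 2).sum(axis=1))

    coarse = np.arange(0.0, hi + coarse_step, coarse_step)
    i = int(np.argmax(loglik(coarse)))
    lo = max(coarse[i] - coarse_step, 0.0)
    fine = np.arange(lo, coarse[i] + coarse_step + fine_step, fine_step)
    tau2 = float(fine[int(np.argmax(loglik(fine)))])
    w = 1.0 / (v + tau2)
    mu = float((w * y).sum() / w.sum())
    return tau2, mu


def hypergeom_tail_enumeration(universe, gene_set, query_size, min_overlap):
    """P(overlap >= min_overlap) by enumerating every possible query draw."""
    universe = sorted(universe)
    gene_set = set(gene_set)
    hits = total = 0
    for draw in combinations(universe, query_size):
        total += 1
        if len(gene_set & set(draw)) >= min_overlap:
            hits += 1
    return hits / total


def venn_by_membership(sets):
    """Region counts by per-element membership enumeration."""
    names = list(sets)
    as_sets = {n: set(sets[n]) for n in names}
    union = set().union(*as_sets.values())
    counts = {}
    for element in union:
        region = frozenset(n for n in names if element in as_sets[n])
        counts[region] = counts.get(region, 0) + 1
    return counts
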