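"""Significance-set logic and enrichment projections.

Operations on pooled meta-analysis tables: thresholded significant-gene
sets, Venn region counts, top-N responsive genes, the healthy-specific rule
(significant in healthy, flat in metabolically impaired), exercise/
inactivity concordance overlaps, hypergeometric over-representation against
user-supplied gene sets, and complex-level fold-change projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import ComplexMap, GeneSetCollection, Protocol, STATUS_OK
from .within_study import bh_adjust

UP = "UP"
DOWN = "DOWN"
ANY = "ANY"


@dataclass(frozen=True)
class SignificanceQuery:
    fdr_threshold: float
    direction: str = ANY

    def __post_init__(self):
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.direction not in (UP, DOWN, ANY):
            raise ValueError(f"direction must be one of {UP}/{DOWN}/{ANY}")


def significant_set(results: pd.DataFrame,
                    query: SignificanceQuery | None = None, *,
                    fdr_threshold: float | None = None,
                    direction: str = ANY) -> set[str]:
    """Genes pooled OK with FDR below threshold and matching direction."""
    if query is None:
        if fdr_threshold is None:
            raise ValueError("provide a SignificanceQuery or fdr_threshold")
        query = SignificanceQuery(fdr_threshold, direction)
    ok = results[(results["status"] == STATUS_OK)
                 & results["fdr"].notna()
                 & (results["fdr"] < query.fdr_threshold)]
    if query.direction == UP:
        ok = ok[ok["mu"] > 0]
    elif query.direction == DOWN:
        ok = ok[ok["mu"] < 0]
    return set(ok["gene"])


def venn_counts(sets: Mapping[str, Iterable]) -> dict[frozenset, int]:
    """Counts of every exclusive membership region of 2–5 named sets.

    Keys are frozensets of set names; the values over all 2^m − 1 regions
    sum to the cardinality of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 5:
        raise ValueError("venn_counts supports between 2 and 5 sets")
    as_sets = {name: set(sets[name]) for name in names}
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(set(), *(as_sets[n] for n in names
                                         if n not in combo))
            counts[frozenset(combo)] = len(inside - outside)
    return counts


def top_n_genes(results: pd.DataFrame, n: int,
                by: str = "mu") -> tuple[list[str], list[str]]:
    """Top-n up- and downregulated genes by pooled effect.

    Ties are broken by smaller FDR, then lexicographic gene id, so the
    selection is fully deterministic.
    """
    if by.lower() != "mu":
        raise ValueError("ranking is by pooled effect ('mu')")
    ok = results[results["status"] == STATUS_OK].copy()
    if ok.empty:
        raise ValueError("no successfully pooled genes to rank")
    up = ok.sort_values(["mu", "fdr", "gene"],
                        ascending=[False, True, True])["gene"].head(n)
    down = ok.sort_values(["mu", "fdr", "gene"],
                          ascending=[True, True, True])["gene"].head(n)
    return list(up), list(down)


def healthy_specific(healthy: pd.DataFrame, impaired: pd.DataFrame,
                     fdr_lo: float = 0.01, fdr_hi: float = 0.9) -> set[str]:
    """Genes responsive in healthy but flat in metabolically impaired
    groups: FDR < ``fdr_lo`` in healthy and FDR > ``fdr_hi`` in impaired."""
    h = healthy.set_index("gene")["fdr"]
    m = impaired.set_index("gene")["fdr"]
    common = h.index.intersection(m.index)
    h, m = h.loc[common], m.loc[common]
    mask = h.notna() & m.notna() & (h < fdr_lo) & (m > fdr_hi)
    return set(common[mask])


def concordance_overlap(up_sets: Iterable[Iterable],
                        down_sets: Iterable[Iterable]) -> set:
    """Genes present in every up-set and every down-set (e.g. increased by
    each acute exercise modality and decreased by inactivity)."""
    up_sets = [set(s) for s in up_sets]
    down_sets = [set(s) for s in down_sets]
    if not up_sets or not down_sets:
        raise ValueError("need at least one up-set and one down-set")
    return set.intersection(*up_sets, *down_sets)


def ora_hypergeometric(query: Iterable, universe: Iterable,
                       collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation analysis: one-sided hypergeometric upper-tail
    test of the query against each gene set, BH-adjusted across sets.

    The universe is the measured background (conventionally all genes with
    a pooled result in the queried protocol); set members outside it are
    ignored and sets with zero universe overlap are dropped.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, (_, genes) in collection.sets.items():
        members = set(genes) & universe
        if not members:
            continue
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members),
                                     n_query))
        rows.append({
            "set_name": name, "overlap": overlap, "set_size": len(members),
            "query_size": n_query, "universe_size": n_universe,
            "p": min(max(p, 0.0), 1.0),
        })
    frame = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size",
                       "universe_size", "p"],
    )
    frame["fdr"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return frame.sort_values("p", kind="mergesort").reset_index(drop=True)


def complex_projection(results_by_protocol: Mapping[object, pd.DataFrame],
                       cmap: ComplexMap) -> pd.DataFrame:
    """Complex x protocol matrix of mean pooled log2 fold-changes.

    Each cell averages the pooled effects of the complex's genes that have
    an OK result in that protocol; missing when none are measured.
    """
    if not cmap.complexes:
        raise ValueError("empty complex map")
    protocols = [Protocol.coerce(p).name for p in results_by_protocol]
    out = pd.DataFrame(index=sorted(cmap.complexes), columns=protocols,
                       dtype=float)
    for proto_key, table in results_by_protocol.items():
        proto = Protocol.coerce(proto_key).name
        ok = table[table["status"] == STATUS_OK].set_index("gene")["mu"]
        for cplx, genes in cmap.complexes.items():
            measured = [g for g in genes if g in ok.index]
            out.loc[cplx, proto] = float(ok.loc[measured].mean()) if measured else np.nan
    return out
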