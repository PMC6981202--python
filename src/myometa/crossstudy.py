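"""Cross-study concordance: fold-change matrix, missingness filter,
nearest-neighbor imputation, correlation matrix and study-level PCA.

The genes x studies log2 fold-change matrix is the common currency: genes
with too many missing values (platform coverage differences) are excluded,
the remaining gaps filled by nearest-neighbor averaging, and study-study
structure summarized by Pearson correlation and PCA with studies as
observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EffectTable, StudyAnnotation

log = logging.getLogger(__name__)

DEFAULT_MAX_MISSING = 0.10
DEFAULT_K_NEIGHBORS = 10


@dataclass
class FoldChangeMatrix:
    """Genes x studies log2FC with explicit missing entries."""

    frame: pd.DataFrame  # genes x study_ids
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    @property
    def studies(self) -> pd.Index:
        return self.frame.columns

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "FoldChangeMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(frame=frame)


def assemble_fc_matrix(effects: EffectTable,
                       studies: list[str] | list[StudyAnnotation] | None = None,
                       ) -> FoldChangeMatrix:
    """Pivot an effect table into a genes x studies log2FC matrix.

    Genes are the union across studies; a study without a gene leaves the
    cell missing.
    """
    if studies is None:
        study_ids = [a.study_id for a in effects.studies]
    else:
        study_ids = [s.study_id if isinstance(s, StudyAnnotation) else str(s)
                     for s in studies]
    if len(study_ids) < 2:
        raise ValueError("a fold-change matrix needs at least two studies")
    sub = effects.frame[effects.frame["study_id"].isin(study_ids)]
    if sub.empty:
        raise ValueError("no effect rows for the requested studies")
    wide = sub.pivot(index="gene", columns="study_id", values="logfc")
    wide = wide.reindex(columns=study_ids).sort_index()
    return FoldChangeMatrix(frame=wide, provenance={"studies": study_ids})


def filter_and_impute(matrix: FoldChangeMatrix,
                      max_missing_fraction: float = DEFAULT_MAX_MISSING,
                      k_neighbors: int = DEFAULT_K_NEIGHBORS,
                      ) -> FoldChangeMatrix:
    """Exclude genes with too many missing values, then fill the remaining
    gaps by k-nearest-neighbor averaging.

    A gene is excluded when its missing fraction exceeds
    ``max_missing_fraction`` (strictly).  Each remaining missing cell (g, s)
    is replaced by the mean of column s over the ``k_neighbors``
    complete-profile genes nearest to g in Euclidean distance computed over
    the columns g was observed in — so imputed values never feed later
    imputations.  If fewer complete genes exist, all are used.
    """
    frame = matrix.frame
    miss_frac = frame.isna().mean(axis=1)
    kept = frame.loc[miss_frac <= max_missing_fraction].copy()
    n_excluded = len(frame) - len(kept)
    if n_excluded:
        log.info("excluded %d of %d genes above %.0f%% missingness",
                 n_excluded, len(frame), 100 * max_missing_fraction)

    incomplete = kept.index[kept.isna().any(axis=1)]
    if len(incomplete):
        complete = kept.loc[~kept.isna().any(axis=1)]
        if complete.empty:
            raise ValueError(
                "no complete-profile genes available as imputation neighbors"
            )
        cmat = complete.to_numpy(dtype=float)
        for gene in incomplete:
            row = kept.loc[gene].to_numpy(dtype=float)
            observed = ~np.isnan(row)
            dist = np.sqrt(((cmat[:, observed] - row[observed]) ** 2).sum(axis=1))
            k = min(k_neighbors, len(complete))
            nearest = np.argsort(dist, kind="mergesort")[:k]
            fill = cmat[nearest].mean(axis=0)
            row[~observed] = fill[~observed]
            kept.loc[gene] = row
    provenance = dict(matrix.provenance)
    provenance.update({
        "max_missing_fraction": max_missing_fraction,
        "k_neighbors": k_neighbors,
        "genes_excluded": n_excluded,
        "genes_imputed": int(len(incomplete)),
    })
    return FoldChangeMatrix(frame=kept, provenance=provenance)


def correlation_matrix(matrix: FoldChangeMatrix) -> pd.DataFrame:
    """Studies x studies Pearson correlations of log2 fold-changes.

    Requires a complete matrix with at least three genes.  Zero-variance
    study columns yield missing correlations with a warning.
    """
    frame = matrix.frame
    if frame.isna().any().any():
        raise ValueError("correlation requires a complete matrix; run "
                         "filter_and_impute first")
    if len(frame) < 3:
        raise ValueError("correlation requires at least three genes")
    degenerate = frame.columns[frame.std(ddof=1) == 0]
    if len(degenerate):
        warnings.warn(
            f"zero-variance study column(s) {list(degenerate)}: "
            "correlations set to missing", RuntimeWarning, stacklevel=2,
        )
    corr = frame.corr(method="pearson")
    return corr


def pca_studies(matrix: FoldChangeMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with studies as observations and genes as variables.

    Fold-changes share a log2 scale, so columns are centered per gene but
    not scaled.  Returns (scores, variance_explained) where the variance
    percentages sum to 100 and component signs follow the
    largest-loading-positive convention.
    """
    frame = matrix.frame
    if frame.isna().any().any():
        raise ValueError("PCA requires a complete matrix")
    if frame.shape[1] < 2:
        raise ValueError("PCA requires at least two studies")
    x = frame.T.to_numpy(dtype=float)          # studies x genes
    xc = x - x.mean(axis=0, keepdims=True)     # center per gene
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix signs: make the largest-magnitude loading of each component positive
    for c in range(len(s)):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u * s[None, :]
    total = float((s ** 2).sum())
    if total == 0:
        variance_explained = np.zeros(len(s))
    else:
        variance_explained = s ** 2 / total * 100.0
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=frame.columns, columns=cols), variance_explained
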