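"""Reading and normalizing per-study inputs.

Expression tables are tab-delimited, UTF-8, ``NA`` for missing: first column
is the gene (or probe) identifier, remaining column headers encode samples as
``subject:condition`` with condition PRE or POST.  Annotation tables, GMT
gene-set files and complex maps follow the standard plain-text dialects.

Two normalizations are provided: simple quantile normalization for array-type
log2 intensities, and a median-of-ratios size-factor log transform for raw
RNA-seq counts, so that every study enters the downstream stages as a
per-sample log2 abundance matrix.
"""

from __future__ import annotations

import json
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    ComplexMap, Design, ExpressionStudy, GeneSetCollection, StudyAnnotation,
    annotations_from_frame, annotations_to_frame,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_sample_label(label: str, lineno: int, path) -> tuple[str, str]:
    parts = label.split(":")
    if len(parts) != 2 or not parts[0] or parts[1].upper() not in ("PRE", "POST"):
        raise ParseError(
            f"{path}: line {lineno}: sample header {label!r} is not of the "
            "form subject:PRE or subject:POST"
        )
    return parts[0], parts[1].upper()


def read_expression_table(path, design: str | Design = Design.PAIRED,
                          study_id: str | None = None) -> ExpressionStudy:
    """Parse a TSV expression table into an :class:`ExpressionStudy`.

    Duplicate gene/probe rows are preserved (collapse them later with
    :func:`collapse_to_genes`).  Raises :class:`ParseError` naming the line
    for ragged rows or non-numeric cells, and ``ValueError`` if a paired
    layout has incomplete subject pairs.
    """
    design = Design.coerce(design)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: line 1: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header needs a gene column and at "
                         "least one sample column")
    samples = [_parse_sample_label(lbl, 1, path) for lbl in header[1:]]
    ncol = len(header)
    genes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        row = []
        for lbl, cell in zip(header[1:], fields[1:]):
            cell = cell.strip()
            if cell == "NA" or cell == "":
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} in "
                    f"column {lbl!r}"
                ) from None
        rows.append(row)
    values = pd.DataFrame(
        rows, index=pd.Index(genes, name="gene"),
        columns=pd.MultiIndex.from_tuples(samples, names=["subject", "condition"]),
    )
    sid = study_id if study_id is not None else str(path)
    return ExpressionStudy(study_id=sid, values=values, design=design)


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Simple quantile normalization: every column is mapped onto the mean
    of the column-sorted values (the reference distribution).

    Tied values within a column receive the mean of the reference values at
    their tied ranks, so the result is deterministic and independent of row
    order.  Missing values are not supported; impute or drop first.
    """
    mat = study.values.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError(
            f"{study.study_id}: quantile normalization requires a complete "
            "matrix; impute or remove missing values first"
        )
    n, m = mat.shape
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(m):
        col = mat[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values across tied ranks
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=study.values.index,
                          columns=study.values.columns)
    return ExpressionStudy(study.study_id, values, study.design)


def median_ratio_log_normalize(counts: pd.DataFrame, pseudocount: float = 0.5,
                               study_id: str = "study",
                               design: str | Design = Design.PAIRED,
                               ) -> ExpressionStudy:
    """Median-of-ratios size factors followed by a log2 transform.

    For sample j the size factor is the median over genes (restricted to
    genes with a strictly positive geometric mean across samples) of
    ``count_gj / geomean_g``; the output value is
    ``log2(count_gj / s_j + pseudocount)``.

    ``counts`` must be nonnegative with columns labelled either as a
    (subject, condition) MultiIndex or as ``subject:condition`` strings.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    cols = counts.columns
    if not isinstance(cols, pd.MultiIndex):
        cols = pd.MultiIndex.from_tuples(
            [_parse_sample_label(str(c), 1, "<counts>") for c in cols],
            names=["subject", "condition"],
        )
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any() or np.isnan(mat).any():
        raise ValueError("counts must be nonnegative and complete")
    zero_samples = np.where(mat.sum(axis=0) == 0)[0]
    if len(zero_samples):
        raise ValueError(
            f"{study_id}: sample(s) {list(zero_samples)} have all-zero counts"
        )
    with np.errstate(divide="ignore"):
        log_geomean = np.log(mat).mean(axis=1)
    positive = np.isfinite(log_geomean)
    if not positive.any():
        raise ValueError(
            f"{study_id}: no gene has nonzero counts in every sample; "
            "cannot compute size factors"
        )
    ratios = mat[positive] / np.exp(log_geomean[positive])[:, None]
    size_factors = np.median(ratios, axis=0)
    if (size_factors <= 0).any():
        raise ValueError(f"{study_id}: nonpositive size factor")
    values = np.log2(mat / size_factors[None, :] + pseudocount)
    frame = pd.DataFrame(values, index=counts.index, columns=cols)
    return ExpressionStudy(study_id, frame, Design.coerce(design))


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors alone (see
    :func:`median_ratio_log_normalize`)."""
    mat = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_geomean = np.log(mat).mean(axis=1)
    positive = np.isfinite(log_geomean)
    if not positive.any():
        raise ValueError("no gene with all-positive counts")
    return np.median(mat[positive] / np.exp(log_geomean[positive])[:, None], axis=0)


def collapse_to_genes(study: ExpressionStudy,
                      probe_map: Mapping[str, str]) -> ExpressionStudy:
    """Collapse probe rows to one row per gene (per-sample median across the
    gene's probes).  Probes absent from ``probe_map`` are dropped with an
    aggregate logged count."""
    probes = study.values.index
    mapped = probes.isin(probe_map.keys())
    n_dropped = int((~mapped).sum())
    if n_dropped:
        log.warning("%s: dropped %d unmapped probe rows", study.study_id, n_dropped)
    kept = study.values.loc[mapped]
    if kept.empty:
        raise ValueError(
            f"{study.study_id}: no probes overlap the probe→gene map"
        )
    gene_ids = pd.Index([probe_map[p] for p in kept.index], name="gene")
    collapsed = kept.groupby(gene_ids, sort=True).median()
    return ExpressionStudy(study.study_id, collapsed, study.design)


# ---------------------------------------------------------------------------
# Annotations / gene sets / complex maps


def read_study_annotations(path) -> list[StudyAnnotation]:
    """Load study annotations from TSV or JSON (by file suffix)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            records = json.load(fh)
        frame = pd.DataFrame(records)
    else:
        frame = pd.read_csv(path, sep="\t", na_values="NA")
    return annotations_from_frame(frame)


def write_study_annotations(annotations, path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False,
                                             na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one gene"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def read_complex_map(path) -> ComplexMap:
    """Read a two-column TSV (complex_id, gene_id) into a :class:`ComplexMap`."""
    frame = pd.read_csv(path, sep="\t", header=0)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: complex map needs complex_id and gene_id columns")
    complexes: dict[str, list[str]] = {}
    for cplx, gene in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        complexes.setdefault(str(cplx), []).append(str(gene))
    return ComplexMap(complexes)
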