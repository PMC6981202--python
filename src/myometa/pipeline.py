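"""End-to-end orchestration and the per-gene interrogation surface.

:func:`run_pipeline` drives ingest/simulation → within-study DE → per-
protocol random-effects pooling → cross-study concordance → significance
sets (and optional enrichment) from a single YAML configuration, writing
TSV/JSON outputs plus a provenance log.  :func:`query_gene` mirrors the
online tool's semantics: forest data for one gene across protocols under a
subgroup filter.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .crossstudy import (
    DEFAULT_K_NEIGHBORS, DEFAULT_MAX_MISSING, assemble_fc_matrix,
    correlation_matrix, filter_and_impute, pca_studies,
)
from .filters import SubgroupFilter, subset_studies
from .ingest import read_gmt, read_study_annotations
from .meta import DEFAULT_MIN_K, forest_data, meta_all_genes
from .setops import ora_hypergeometric, significant_set
from .simulate import config_from_dict, simulate_expression_studies
from .types import EffectTable, Protocol
from .within_study import build_effect_table, differential_expression

log = logging.getLogger(__name__)


def _filter_from_dict(raw: dict | None) -> SubgroupFilter | None:
    if not raw:
        return None
    return SubgroupFilter(
        protocols=raw.get("protocols"),
        health_status=raw.get("health_status"),
        muscles=raw.get("muscles"),
        biopsy_timing=raw.get("biopsy_timing"),
        sex_fraction_range=tuple(raw["sex_fraction_range"]) if raw.get("sex_fraction_range") else None,
        age_range=tuple(raw["age_range"]) if raw.get("age_range") else None,
        include_studies=raw.get("include_studies"),
        exclude_studies=raw.get("exclude_studies", ()),
    )


def _load_effects(config: dict, seed: int | None) -> EffectTable:
    if "simulate" in config:
        sim_raw = dict(config["simulate"])
        if seed is not None:
            sim_raw["seed"] = seed
        sim_config = config_from_dict(sim_raw)
        studies, _ = simulate_expression_studies(sim_config)
        frames = [differential_expression(s) for s in studies]
        return build_effect_table(frames, sim_config.annotations())
    if "effects" in config and "annotations" in config:
        annotations = read_study_annotations(config["annotations"])
        return EffectTable.from_tsv(config["effects"], annotations)
    raise ValueError(
        "config must provide either a 'simulate' section or "
        "'effects' + 'annotations' paths"
    )


def run_pipeline(config_path, seed: int | None = None,
                 out_dir=None) -> dict:
    """Execute the configured analysis and write a result bundle.

    Returns a dict with the written paths and the in-memory result tables.
    Protocols configured but backed by zero studies are skipped with a
    logged warning.
    """
    config_path = Path(config_path)
    raw_text = config_path.read_text(encoding="utf-8")
    config = yaml.safe_load(raw_text) or {}
    if seed is None:
        seed = config.get("seed")
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)

    effects = _load_effects(config, seed)
    effects_path = out / "effects.tsv"
    effects.to_tsv(effects_path)

    flt = _filter_from_dict(config.get("filters"))
    meta_cfg = config.get("meta", {})
    min_k = int(meta_cfg.get("min_k", DEFAULT_MIN_K))
    wanted = meta_cfg.get("protocols")
    if wanted is None:
        wanted = sorted({a.protocol.name for a in effects.studies})

    meta_tables: dict[str, pd.DataFrame] = {}
    written = {"effects": str(effects_path)}
    for proto_name in wanted:
        proto = Protocol.coerce(proto_name)
        available = subset_studies(
            [a for a in effects.studies if a.protocol is proto], flt)
        if not available:
            log.warning("protocol %s: no matching studies; skipped", proto.name)
            continue
        table = meta_all_genes(effects, proto, filters=flt, min_k=min_k)
        meta_tables[proto.name] = table
        path = out / f"meta_{proto.value}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
        written[f"meta_{proto.value}"] = str(path)

    cross_cfg = config.get("crossstudy", {})
    cross_results = {}
    study_ids = [a.study_id for a in subset_studies(effects.studies, flt)]
    if len(study_ids) >= 2:
        fcm = assemble_fc_matrix(effects, studies=study_ids)
        fcm.to_tsv(out / "fc_matrix.tsv")
        written["fc_matrix"] = str(out / "fc_matrix.tsv")
        filled = filter_and_impute(
            fcm,
            max_missing_fraction=float(cross_cfg.get("max_missing_fraction",
                                                     DEFAULT_MAX_MISSING)),
            k_neighbors=int(cross_cfg.get("k_neighbors", DEFAULT_K_NEIGHBORS)),
        )
        if len(filled.frame) >= 3:
            corr = correlation_matrix(filled)
            corr.to_csv(out / "correlation.tsv", sep="\t", na_rep="NA")
            written["correlation"] = str(out / "correlation.tsv")
            scores, varexp = pca_studies(filled)
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            pd.DataFrame({"component": scores.columns,
                          "variance_explained_pct": varexp}).to_csv(
                out / "pca_variance.tsv", sep="\t", index=False)
            written["pca_scores"] = str(out / "pca_scores.tsv")
            written["pca_variance"] = str(out / "pca_variance.tsv")
            cross_results = {"correlation": corr, "pca_scores": scores,
                             "variance_explained": varexp}

    sets_cfg = config.get("sets", {})
    fdr_threshold = float(sets_cfg.get("fdr_threshold", 0.01))
    sig_sets = {proto: sorted(significant_set(tbl, fdr_threshold=fdr_threshold))
                for proto, tbl in meta_tables.items()}
    with open(out / "significant_sets.json", "w", encoding="utf-8") as fh:
        json.dump({"fdr_threshold": fdr_threshold, "sets": sig_sets}, fh,
                  indent=2)
    written["significant_sets"] = str(out / "significant_sets.json")

    enrich_cfg = config.get("enrich", {})
    enrich_tables = {}
    if enrich_cfg.get("gmt"):
        collection = read_gmt(enrich_cfg["gmt"])
        for proto, tbl in meta_tables.items():
            universe = set(tbl.loc[tbl["status"] == "OK", "gene"])
            query = set(sig_sets[proto]) & universe
            if not query:
                continue
            enr = ora_hypergeometric(query, universe, collection)
            path = out / f"enrichment_{proto.lower()}.tsv"
            enr.to_csv(path, sep="\t", index=False, na_rep="NA")
            written[f"enrichment_{proto.lower()}"] = str(path)
            enrich_tables[proto] = enr

    run_log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "config_sha256": hashlib.sha256(raw_text.encode()).hexdigest(),
        "seed": seed,
        "filters": flt.describe() if flt is not None else None,
        "min_k": min_k,
        "protocols_run": sorted(meta_tables),
        "outputs": written,
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2)
    written["run_log"] = str(out / "run_log.json")

    return {
        "paths": written,
        "effects": effects,
        "meta": meta_tables,
        "crossstudy": cross_results,
        "significant_sets": sig_sets,
        "enrichment": enrich_tables,
    }


def query_gene(gene: str, protocols, effects: EffectTable,
               flt: SubgroupFilter | None = None,
               min_k: int = DEFAULT_MIN_K) -> dict[str, dict]:
    """Forest records for one gene, one per requested protocol.

    Protocols whose filtered study count falls below ``min_k`` yield a meta
    row with status ``TOO_FEW_STUDIES``; protocols with no matching studies
    at all report an empty study list.  An unknown gene raises with
    near-match suggestions.
    """
    known = set(effects.genes)
    if gene not in known:
        suggestions = difflib.get_close_matches(gene, sorted(known), n=5)
        hint = f"; did you mean {suggestions}?" if suggestions else ""
        raise KeyError(f"unknown gene {gene!r}{hint}")
    out: dict[str, dict] = {}
    for proto_key in protocols:
        proto = Protocol.coerce(proto_key)
        try:
            out[proto.name] = forest_data(gene, proto, effects, filters=flt,
                                          min_k=min_k)
        except ValueError:
            out[proto.name] = {
                "gene": gene, "protocol": proto.name,
                "filters": flt.describe() if flt is not None else None,
                "studies": [],
                "meta": {"gene": gene, "protocol": proto.name, "k": 0,
                         "status": "TOO_FEW_STUDIES"},
            }
    return out
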