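"""Bundled reference summary tables.

Small published pooled-result excerpts used as worked examples: per-gene
pooled log2 fold-changes and FDRs for training protocols in healthy vs
metabolically impaired groups, and the strongest acute-aerobic responders.
They let the significance-set rules be exercised against known outputs
without reprocessing any primary data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import STATUS_OK


def _read(name: str) -> pd.DataFrame:
    with resources.files("myometa.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def _as_meta_table(genes, mu, fdr, protocol: str) -> pd.DataFrame:
    frame = pd.DataFrame({"gene": genes, "mu": mu, "fdr": fdr})
    frame["protocol"] = protocol
    frame["status"] = STATUS_OK
    return frame


def load_training_reference() -> dict[tuple[str, str], pd.DataFrame]:
    """Pooled training-response excerpts for ten genes.

    Returns meta-style tables keyed by (protocol, group) with protocol in
    {"aerobic", "resistance"} and group in {"healthy", "impaired"}.
    """
    raw = _read("training_reference.tsv")
    out = {}
    for proto in ("aerobic", "resistance"):
        for group in ("healthy", "impaired"):
            out[(proto, group)] = _as_meta_table(
                raw["gene"], raw[f"{proto}_{group}_logfc"],
                raw[f"{proto}_{group}_fdr"],
                f"TRAINING_{proto.upper()}",
            )
    return out


def load_acute_aerobic_reference() -> pd.DataFrame:
    """Pooled acute-aerobic excerpt: five strongest up- and downregulated
    genes, as a meta-style table."""
    raw = _read("acute_aerobic_reference.tsv")
    return _as_meta_table(raw["gene"], raw["mu"], raw["fdr"], "ACUTE_AEROBIC")
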