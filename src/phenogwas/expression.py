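"""Summaries of externally produced differential-expression tables.

Consumes DESeq2/MSstats-style output: one record per gene per layer
(``rna`` or ``protein``) with a log2 fold change (sign convention
log2[T] - log2[A]) and an FDR. Provides DE counts at an FDR threshold,
Pearson correlation of RNA and protein fold changes over differentially
expressed genes, and one-sided hypergeometric overlaps between gene sets
against a measured-genes background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapResult:
    query_size: int
    signature_size: int
    background_size: int
    overlap: int
    p_value: float  # upper-tail hypergeometric P[X >= overlap]


def count_de(table: pd.DataFrame, fdr_threshold: float = 0.10) -> dict[str, int]:
    """Number of differentially expressed records per layer at FDR <= threshold."""
    if "fdr" not in table.columns:
        raise ValueError("table needs an fdr column")
    if table.empty:
        return {}
    de = table[table["fdr"] <= fdr_threshold]
    counts = de.groupby("layer").size().to_dict()
    return {layer: 0 for layer in table["layer"].unique()} | counts


def fc_correlation(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    restrict_to_de: bool = True,
    fdr_threshold: float = 0.10,
) -> float:
    """Pearson r between RNA and protein log2 fold changes.

    When restricted, only genes differentially expressed in either layer
    (union) enter the correlation. Tables need columns gene, log2fc, fdr.
    """
    merged = rna.merge(protein, on="gene", suffixes=("_rna", "_protein"))
    if restrict_to_de:
        de = (merged["fdr_rna"] <= fdr_threshold) | (
            merged["fdr_protein"] <= fdr_threshold
        )
        merged = merged[de]
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared genes after restriction")
    r, _ = stats.pearsonr(merged["log2fc_rna"], merged["log2fc_protein"])
    return float(r)


def overlap_test(
    query: set[str], signature: set[str], background: set[str]
) -> OverlapResult:
    """Upper-tail hypergeometric test of gene-set overlap.

    Both sets are intersected with the background first (only measured genes
    count). p = P[X >= overlap] for X hypergeometric with the background as
    population, the signature as successes and the query size as draws.
    """
    if not background:
        raise ValueError("background gene set is empty")
    query = set(query) & set(background)
    signature = set(signature) & set(background)
    overlap = len(query & signature)
    n_bg, n_sig, n_query = len(background), len(signature), len(query)
    # survival function at k-1 gives P[X >= k]
    p = float(stats.hypergeom.sf(overlap - 1, n_bg, n_sig, n_query))
    return OverlapResult(
        query_size=n_query,
        signature_size=n_sig,
        background_size=n_bg,
        overlap=overlap,
        p_value=min(p, 1.0),
    )


def directional_overlaps(
    table: pd.DataFrame,
    signature_up: set[str],
    signature_down: set[str],
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Up/down-split overlaps of a DE table against a signature pair.

    Splits the table's DE genes by fold-change sign, then tests each half
    against the corresponding signature with the layer's measured genes as
    background. Returns one row per (layer, direction).
    """
    records = []
    for layer, sub in table.groupby("layer"):
        background = set(sub["gene"])
        de = sub[sub["fdr"] <= fdr_threshold]
        for direction, signature in (("up", signature_up), ("down", signature_down)):
            sign = de["log2fc"] > 0 if direction == "up" else de["log2fc"] < 0
            res = overlap_test(set(de.loc[sign, "gene"]), signature, background)
            records.append(
                dict(
                    layer=layer,
                    direction=direction,
                    query_size=res.query_size,
                    signature_size=res.signature_size,
                    background_size=res.background_size,
                    overlap=res.overlap,
                    p=res.p_value,
                )
            )
    return pd.DataFrame.from_records(records)
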