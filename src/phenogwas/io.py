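"""Plain-text readers and writers for the pipeline's tabular and VCF formats.

All tables are tab-separated. Plate coordinates are 0-based row/col indices;
VCF positions are 1-based, with haploid GT calls (``0``, ``1`` or ``.``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

PLATE_COLUMNS = ["row", "col", "size_px", "circularity"]
LAYOUT_COLUMNS = ["row", "col", "strain", "is_reference"]


def write_plate_tsv(plate: pd.DataFrame, path: str | Path) -> None:
    """Write a colony-plate table (0-based row/col, size in pixels)."""
    plate.to_csv(path, sep="\t", index=False)


def read_plate_tsv(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    return plate


def write_layout_tsv(layout: pd.DataFrame, path: str | Path) -> None:
    layout.to_csv(path, sep="\t", index=False)


def read_layout_tsv(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path, sep="\t")
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout table missing columns: {missing}")
    layout["is_reference"] = layout["is_reference"].astype(bool)
    return layout


def write_phenotype_tsv(strains, values, path: str | Path) -> None:
    """Two-column phenotype table (strain, value)."""
    pd.DataFrame({"strain": strains, "value": values}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs two columns (strain, value)")
    df.columns = ["strain", "value", *df.columns[2:]]
    return df


def write_curves_tsv(curves: pd.DataFrame, path: str | Path) -> None:
    """Long-format growth-curve table with columns well, time, od."""
    curves.to_csv(path, sep="\t", index=False)


def read_curves_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("well", "time", "od") if c not in df.columns]
    if missing:
        raise ValueError(f"curve table missing columns: {missing}")
    return df


def write_truth_json(truth: dict, path: str | Path) -> None:
    """Sidecar ground-truth file; numpy values are converted to lists/floats."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=1, default=_default))


def write_vcf(
    samples: list[str],
    variants: pd.DataFrame,
    calls: np.ndarray,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal haploid VCF.

    ``variants`` needs columns chrom, pos (1-based), ref, alt (alt may hold a
    comma-joined string for multiallelic records); ``calls`` is an
    (n_samples, n_variants) float array of allele indices with NaN = missing.
    """
    if calls.shape != (len(samples), len(variants)):
        raise ValueError("calls shape does not match samples x variants")
    lines = ["##fileformat=VCFv4.2"]
    chroms = list(dict.fromkeys(variants["chrom"]))
    for chrom in chroms:
        length = (contig_lengths or {}).get(
            chrom, int(variants.loc[variants["chrom"] == chrom, "pos"].max()) + 1000
        )
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for j, var in enumerate(variants.itertuples(index=False)):
        gts = [
            "." if np.isnan(calls[i, j]) else str(int(calls[i, j]))
            for i in range(len(samples))
        ]
        lines.append(
            f"{var.chrom}\t{int(var.pos)}\t.\t{var.ref}\t{var.alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
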