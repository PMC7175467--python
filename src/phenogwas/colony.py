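"""Colony-array fitness scoring: spatial normalization, QC, resistance scores.

Plates are pandas DataFrames with columns ``row``, ``col`` (0-based),
``size_px`` and ``circularity``; layouts add ``strain`` and ``is_reference``.
A 384-format plate carries a reference grid of control-strain colonies (one
per 2x2 block); their sizes define a smooth spatial reference surface, and
each colony's corrected size is its raw size divided by the surface value at
its position, so the control strain has corrected size ~1 everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

QC_PASS = "pass"
QC_NO_GROWTH = "no-growth"
QC_ABNORMAL_SHAPE = "abnormal-shape"

MIN_SIZE_PX = 10.0  # colonies smaller than this did not grow
CIRCULARITY_LOW = 0.85
CIRCULARITY_HIGH = 1.1


@dataclass
class ScreenMetrics:
    """Screen-level quality metrics from internal control colonies."""

    signal_to_noise: float  # mean(controls) / SD(controls)
    unexplained_variance: float  # SD(controls) / SD(all colonies)
    n_controls: int


def apply_qc(plate: pd.DataFrame) -> pd.DataFrame:
    """Flag colonies failing per-colony QC.

    Colonies with ``size_px`` < 10 (600 dpi scan) are flagged "no-growth";
    circularity outside [0.85, 1.1] is flagged "abnormal-shape". A ``qc_flag``
    column is added; nothing is removed. The strain-level consistency rule
    (replicate SD vs screen-wide SD) is applied later, in
    :func:`strain_fitness`, because it needs corrected sizes pooled over the
    whole screen.
    """
    if "circularity" not in plate.columns:
        raise ValueError("plate table must carry a circularity column")
    out = plate.copy()
    flag = np.full(len(out), QC_PASS, dtype=object)
    flag[out["size_px"].to_numpy() < MIN_SIZE_PX] = QC_NO_GROWTH
    circ = out["circularity"].to_numpy()
    bad_shape = (circ > CIRCULARITY_HIGH) | (circ < CIRCULARITY_LOW)
    flag[bad_shape & (flag == QC_PASS)] = QC_ABNORMAL_SHAPE
    out["qc_flag"] = flag
    return out


def _reference_surface(ref: pd.DataFrame):
    """Bilinear surface over the reference subgrid.

    QC-failed grid nodes are imputed from the mean of their available grid
    neighbours (iteratively, so isolated holes fill from the outside in).
    Border rows/cols outside the reference grid get linear extrapolation from
    the nearest grid cell, so an affine bias field is corrected exactly
    everywhere on the plate.
    """
    grid_rows = np.unique(ref["row"])
    grid_cols = np.unique(ref["col"])
    values = np.full((len(grid_rows), len(grid_cols)), np.nan)
    ri = {r: i for i, r in enumerate(grid_rows)}
    ci = {c: i for i, c in enumerate(grid_cols)}
    for rec in ref.itertuples(index=False):
        values[ri[rec.row], ci[rec.col]] = rec.size_px
    while np.isnan(values).any():
        nan_mask = np.isnan(values)
        padded = np.pad(values, 1, constant_values=np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            neighbour_mean = np.nanmean(
                np.stack(
                    [
                        padded[:-2, 1:-1],
                        padded[2:, 1:-1],
                        padded[1:-1, :-2],
                        padded[1:-1, 2:],
                    ]
                ),
                axis=0,
            )
        fillable = nan_mask & ~np.isnan(neighbour_mean)
        if not fillable.any():  # pragma: no cover - cannot happen with >= 1 ref
            raise ValueError("reference surface cannot be filled")
        values[fillable] = neighbour_mean[fillable]
    interp = RegularGridInterpolator(
        (grid_rows.astype(float), grid_cols.astype(float)),
        values,
        method="linear",
        bounds_error=False,
        fill_value=None,  # linear extrapolation beyond the reference grid
    )

    def surface(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return interp(np.column_stack([rows, cols]))

    return surface


def normalize_reference_grid(
    plate: pd.DataFrame, layout: pd.DataFrame
) -> pd.DataFrame:
    """Reference-grid spatial normalization.

    Interpolates a bilinear surface through the QC-passing reference-colony
    sizes and divides every colony's size by the surface value at its
    position, adding a ``corrected_size`` column (NaN for QC-failed
    colonies). Corrected reference colonies are ~1 by construction.
    """
    merged = plate.merge(layout, on=["row", "col"], how="left", validate="1:1")
    if merged["strain"].isna().any():
        raise ValueError("plate contains positions missing from the layout")
    if "qc_flag" not in merged.columns:
        merged = apply_qc(merged)
    ref = merged[merged["is_reference"] & (merged["qc_flag"] == QC_PASS)]
    if len(ref) < 4:
        raise ValueError(
            f"only {len(ref)} reference colonies pass QC; plate rejected"
        )
    surface = _reference_surface(ref)
    values = surface(
        merged["row"].to_numpy(float), merged["col"].to_numpy(float)
    )
    corrected = merged["size_px"].to_numpy() / values
    corrected[merged["qc_flag"].to_numpy() != QC_PASS] = np.nan
    out = merged.copy()
    out["corrected_size"] = corrected
    return out


def strain_fitness(
    plates: pd.DataFrame | list[pd.DataFrame],
    include_reference: bool = False,
    sd_exclusion: bool = True,
) -> pd.DataFrame:
    """Aggregate corrected colony sizes into per-strain fitness records.

    Takes one or more normalized plates (output of
    :func:`normalize_reference_grid`) and averages surviving corrected sizes
    per strain. Strains whose replicate SD exceeds the SD of all QC-passing
    colonies of all strains are excluded as inconsistent; strains with no
    surviving colony are excluded as all-failed.

    Returns a DataFrame with strain, fitness, sd, n_replicates, excluded,
    reason.
    """
    if isinstance(plates, pd.DataFrame):
        plates = [plates]
    data = pd.concat(plates, ignore_index=True)
    if "corrected_size" not in data.columns:
        raise ValueError("plates must be normalized first")
    if not include_reference:
        data = data[~data["is_reference"]]
    surviving = data.dropna(subset=["corrected_size"])
    pooled_sd = float(surviving["corrected_size"].std(ddof=1))

    records = []
    for strain, group in data.groupby("strain", sort=True):
        vals = group["corrected_size"].dropna().to_numpy()
        if len(vals) == 0:
            records.append(
                dict(strain=strain, fitness=np.nan, sd=np.nan, n_replicates=0,
                     excluded=True, reason="all-colonies-failed-qc")
            )
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        excluded = sd_exclusion and sd > pooled_sd
        records.append(
            dict(
                strain=strain,
                fitness=float(vals.mean()) if not excluded else np.nan,
                sd=sd,
                n_replicates=len(vals),
                excluded=bool(excluded),
                reason="inconsistent-replicates" if excluded else "",
            )
        )
    return pd.DataFrame.from_records(records)


def resistance_scores(
    condition: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Per-strain resistance score: condition fitness / control fitness.

    Strains excluded or missing in either screen are omitted; strains with
    zero control fitness are omitted with a diagnostic warning.
    """
    cond = condition[~condition["excluded"]][["strain", "fitness"]]
    ctrl = control[~control["excluded"]][["strain", "fitness"]]
    merged = cond.merge(ctrl, on="strain", suffixes=("_condition", "_control"))
    zero = merged["fitness_control"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} strain(s) with zero control fitness omitted"
        )
        merged = merged[~zero]
    merged["score"] = merged["fitness_condition"] / merged["fitness_control"]
    return merged[["strain", "fitness_condition", "fitness_control", "score"]]


def screen_metrics(
    plates: pd.DataFrame | list[pd.DataFrame],
    control_strain: str = "control",
) -> ScreenMetrics:
    """Signal-to-noise and unexplained variance of a screen.

    Internal controls are the QC-passing control-strain colonies *outside*
    the reference grid (the grid itself is consumed by normalization).
    SNR = mean(controls)/SD(controls); unexplained variance =
    SD(controls)/SD(all QC-passing colonies).
    """
    if isinstance(plates, pd.DataFrame):
        plates = [plates]
    data = pd.concat(plates, ignore_index=True).dropna(subset=["corrected_size"])
    controls = data[(data["strain"] == control_strain) & (~data["is_reference"])]
    vals = controls["corrected_size"].to_numpy()
    if len(vals) < 2:
        raise ValueError("need at least 2 internal control colonies")
    sd_controls = float(np.std(vals, ddof=1))
    if sd_controls == 0:
        warnings.warn("internal controls have zero variance; SNR is infinite")
        snr = math.inf
    else:
        snr = float(vals.mean()) / sd_controls
    sd_all = float(data["corrected_size"].std(ddof=1))
    unexplained = sd_controls / sd_all if sd_all > 0 else math.nan
    return ScreenMetrics(
        signal_to_noise=snr,
        unexplained_variance=unexplained,
        n_controls=len(vals),
    )
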