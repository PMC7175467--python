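"""Physiology calculators and two-group metabolite statistics.

Covers the scalar read-outs derived from targeted metabolomics and simple
kinetic assays: adenylate energy charge, redox ratios of cofactor pairs,
enzyme rates from NADH absorbance traces (Beer-Lambert conversion, blank
subtraction, OD normalization), glucose consumption against a linear standard
curve, oxygen consumption slopes, biomass yield, and Welch's t-test with
Benjamini-Hochberg correction across metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EPSILON_NADH = 6220.0  # extinction coefficient at 340 nm, 1/(M*cm)
PATH_CM = 0.5411  # effective path length of a 200-ul well in a 96-well plate
CENSOR_FLOOR = 0.2  # absorbance readings below this are unreliable


@dataclass
class NucleotidePools:
    """ATP/ADP/AMP concentrations in one sample (same units each)."""

    atp: float
    adp: float
    amp: float

    def __post_init__(self):
        if self.atp < 0 or self.adp < 0 or self.amp < 0:
            raise ValueError("nucleotide concentrations must be non-negative")
        if self.atp + self.adp + self.amp == 0:
            raise ValueError("all-zero nucleotide pools")


def energy_charge(pools: NucleotidePools) -> float:
    """Adenylate energy charge, (ATP + ADP/2) / (ATP + ADP + AMP), in [0, 1]."""
    total = pools.atp + pools.adp + pools.amp
    return (pools.atp + 0.5 * pools.adp) / total


def redox_ratio(reduced: float, oxidized: float) -> float:
    """Reduced/oxidized concentration ratio of a cofactor pair."""
    if reduced < 0 or oxidized < 0:
        raise ValueError("concentrations must be non-negative")
    if oxidized == 0:
        raise ValueError("oxidized concentration is zero; ratio undefined")
    return reduced / oxidized


def _censored_slope(
    time_min: np.ndarray, a340: np.ndarray, floor: float
) -> tuple[float, int]:
    """OLS slope of absorbance vs time after censoring values below floor."""
    keep = a340 >= floor
    n_valid = int(keep.sum())
    if n_valid < 5:
        raise ValueError(
            f"only {n_valid} absorbance points above the {floor} floor"
        )
    res = stats.linregress(time_min[keep], a340[keep])
    return float(res.slope), n_valid


def enzyme_rate(
    trace: pd.DataFrame,
    blank: pd.DataFrame | None = None,
    culture_od: float = 1.0,
    epsilon: float = EPSILON_NADH,
    path_cm: float = PATH_CM,
    censor_floor: float = CENSOR_FLOOR,
) -> float:
    """Enzyme rate from an NADH absorbance trace, in M/min per OD unit.

    Absorbance below the censoring floor is dropped pointwise; the remaining
    trace is converted to concentration via A = C * epsilon * path and the
    OLS slope taken. The blank trace's slope (background reaction) is
    subtracted, and the result divided by the culture OD at sampling.
    Traces need columns ``time_min`` and ``a340``.
    """
    if culture_od <= 0:
        raise ValueError("culture OD must be positive")
    slope_a, _ = _censored_slope(
        trace["time_min"].to_numpy(float), trace["a340"].to_numpy(float), censor_floor
    )
    slope_blank = 0.0
    if blank is not None:
        slope_blank, _ = _censored_slope(
            blank["time_min"].to_numpy(float),
            blank["a340"].to_numpy(float),
            censor_floor,
        )
    rate = (slope_a - slope_blank) / (epsilon * path_cm)
    return rate / culture_od


@dataclass
class StandardCurve:
    """Linear absorbance-vs-concentration standard, from a dilution series."""

    slope: float  # absorbance per concentration unit
    intercept: float
    r_squared: float

    @classmethod
    def fit(cls, concentrations: np.ndarray, absorbances: np.ndarray):
        res = stats.linregress(np.asarray(concentrations), np.asarray(absorbances))
        if res.slope <= 0:
            raise ValueError("standard curve has non-positive slope")
        return cls(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
        )

    def concentration(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


def glucose_consumed(
    sample_absorbance: float,
    blank_absorbance: float,
    standard_curve: StandardCurve,
    fresh_concentration: float,
    culture_od: float,
    dilution: float = 20.0,
) -> float:
    """Glucose consumed from the medium, per OD unit of culture.

    The blanked absorbance is converted to concentration via the standard
    curve and multiplied by the dilution factor; consumption is the fresh
    medium's glucose minus the measured residual, divided by the culture OD.
    A measured value above the fresh concentration (negative consumption) is
    reported with a warning.
    """
    if culture_od <= 0:
        raise ValueError("culture OD must be positive")
    measured = dilution * standard_curve.concentration(
        sample_absorbance - blank_absorbance + standard_curve.intercept
    )
    consumed = (fresh_concentration - measured) / culture_od
    if measured > fresh_concentration:
        warnings.warn(
            "measured glucose exceeds fresh-media glucose; negative consumption"
        )
    return consumed


def oxygen_rate(
    time_min: np.ndarray, saturation: np.ndarray, culture_od: float
) -> float:
    """Oxygen consumption: OLS slope of saturation vs time, per OD unit."""
    time_min = np.asarray(time_min, dtype=float)
    saturation = np.asarray(saturation, dtype=float)
    if time_min.size < 4:
        raise ValueError("need at least 4 points for an oxygen slope")
    if culture_od <= 0:
        raise ValueError("culture OD must be positive")
    res = stats.linregress(time_min, saturation)
    return float(res.slope) / culture_od


def biomass_yield(dry_weight: float, glucose_mass: float) -> float:
    """Biomass yield in percent: 100 * dry weight / glucose consumed (same units)."""
    if glucose_mass <= 0:
        raise ValueError("glucose mass must be positive")
    if dry_weight < 0:
        raise ValueError("dry weight must be non-negative")
    return 100.0 * dry_weight / glucose_mass


def groupwise_stats(
    table: pd.DataFrame,
    group_col: str = "group",
    numerator: str = "A",
    denominator: str = "T",
    exclude_cols: tuple[str, ...] = ("sample", "culture_od"),
) -> pd.DataFrame:
    """Welch's t-test with BH correction across a two-group metabolite table.

    For each metabolite column: ratio of group means (numerator/denominator),
    ratio of group medians, Welch's unpaired two-sided t with
    Welch-Satterthwaite degrees of freedom, and the BH-adjusted q across all
    metabolites in the table. Groups where both variances are zero and the
    means are equal get p = 1.
    """
    groups = table[group_col].unique()
    if set(groups) != {numerator, denominator}:
        raise ValueError(
            f"expected exactly groups {{{numerator!r}, {denominator!r}}}, "
            f"got {sorted(groups)}"
        )
    metabolites = [
        c for c in table.columns if c not in exclude_cols and c != group_col
    ]
    x = table.loc[table[group_col] == numerator, metabolites].to_numpy(float)
    y = table.loc[table[group_col] == denominator, metabolites].to_numpy(float)
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(x, y, axis=0, equal_var=False)
        vx, vy = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
        nx, ny = x.shape[0], y.shape[0]
        num = (vx / nx + vy / ny) ** 2
        den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        df = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        mean_ratio = x.mean(axis=0) / y.mean(axis=0)
        median_ratio = np.median(x, axis=0) / np.median(y, axis=0)
    # degenerate case: both groups constant with equal means -> no evidence
    degenerate = (vx == 0) & (vy == 0) & (x.mean(axis=0) == y.mean(axis=0))
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "metabolite": metabolites,
            "mean_ratio": mean_ratio,
            "median_ratio": median_ratio,
            "t": t_stat,
            "df": df,
            "p": p,
            "q": q,
        }
    )
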