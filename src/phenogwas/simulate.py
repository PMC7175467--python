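"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one of the experimental data types consumed downstream:

- colony plates in 384 (16x24) format with a 96-position reference grid of the
  control strain and a multiplicative spatial bias field,
- logistic OD growth curves sampled at plate-reader intervals,
- a structured haploid population (Balding-Nichols lineage model) with one
  causal variant plus a polygenic background at a set heritability,
- two-group metabolite concentration tables with log-normal noise,
- linear NADH-depletion absorbance traces (Beer-Lambert conversion),
- biallelic SNP haplotypes dropped on a known random tree, as VCF records.

A single global seed in :class:`SimConfig` expands deterministically into
per-generator child seeds, so one config reproduces the whole data set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

# stable child-seed keys, one per generator
_CHILD = {
    "plate": 1,
    "growth": 2,
    "population": 3,
    "metabolome": 4,
    "enzyme": 5,
    "region": 6,
}


def _rng(seed: int, generator: str, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _CHILD[generator], int(offset)])
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PlateConfig:
    """Colony-array generator: 16x24 plate, 8x12 reference subgrid (96 refs)."""

    n_rows: int = 16
    n_cols: int = 24
    base_size: float = 100.0  # px, control-strain colony in unbiased conditions
    n_test_strains: int = 93  # in triplicate: 279 positions
    n_internal_controls: int = 9  # control colonies outside the reference grid
    replicates: int = 3
    bias_row_range: float = 0.2  # relative size change across rows
    bias_col_range: float = 0.3  # relative size change across columns
    bias_smooth_sd: float = 0.02  # log-SD of the smooth random bias component
    strain_effect_sd: float = 0.15  # log-SD of true strain fitness
    noise_sd: float = 0.05  # multiplicative log-scale measurement noise
    qc_fail_fraction: float = 0.02  # colonies forced to fail QC
    circularity_sd: float = 0.03


@dataclass
class GrowthConfig:
    """Logistic OD curve, 15-min sampling as in plate-reader screens."""

    kind: str = "logistic"  # or "linear"
    carrying_capacity: float = 1.0  # K (OD units)
    rate: float = 0.4  # r (per hour)
    t_mid: float = 12.0  # t0 (hours)
    linear_slope: float = 0.05  # OD/h, used when kind == "linear"
    duration_h: float = 48.0
    interval_min: float = 15.0
    noise_sd: float = 0.01  # additive OD noise


@dataclass
class PopulationConfig:
    """Two-lineage haploid panel with one causal variant.

    Defaults mirror a 161-strain panel with a rare causal allele carried by 18
    strains and strong substructure (Balding-Nichols F = 0.4).
    """

    n_strains: int = 161
    n_variants: int = 1000
    n_lineages: int = 2
    fst: float = 0.4  # Balding-Nichols divergence F
    causal_carriers: int = 18
    beta: float = 0.8  # causal effect in phenotype-SD units per alt allele
    h2_poly: float = 0.5  # polygenic heritability
    missing_rate: float = 0.0
    freq_low: float = 0.05  # ancestral allele-frequency range
    freq_high: float = 0.95


@dataclass
class MetabolomeConfig:
    """Two-group targeted-metabolomics table (T vs A strains)."""

    n_metabolites: int = 50
    n_group_t: int = 9
    n_group_a: int = 8
    base_mean: float = 100.0  # concentration units (e.g. uM), T-group mean
    fold_change: float = 1.0  # scalar or per-metabolite array; A relative to T
    cv: float = 0.172  # log-normal coefficient of variation
    culture_od: float = 0.8


@dataclass
class EnzymeConfig:
    """Linear NADH-depletion trace read as absorbance at 340 nm."""

    rate: float = 2e-6  # true dC/dt magnitude, M/min (NADH consumed)
    start_absorbance: float = 0.67  # ~200 uM NADH at epsilon*path below
    epsilon: float = 6220.0  # extinction coefficient, 1/(M*cm)
    path_cm: float = 0.5411  # effective path length of a 200-ul well
    duration_min: float = 10.0
    interval_s: float = 15.0
    noise_sd: float = 0.002  # additive absorbance noise
    blank_rate: float = 0.0  # background dC/dt in the no-lysate control
    culture_od: float = 1.0
    censor_floor: float = 0.2  # absorbance below this is unreliable


@dataclass
class RegionConfig:
    """Biallelic SNP haplotypes on a random tree, plus non-SNP decoy records."""

    n_taxa: int = 12
    n_snps: int = 31
    n_decoy_indels: int = 2
    n_decoy_multiallelic: int = 1
    chrom: str = "I"
    region_start: int = 3_844_243  # 1-based inclusive
    region_end: int = 3_847_145
    missing_rate: float = 0.0


@dataclass
class SimConfig:
    """All generator parameters plus the single global seed."""

    seed: int = 0
    plate: PlateConfig = field(default_factory=PlateConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    metabolome: MetabolomeConfig = field(default_factory=MetabolomeConfig)
    enzyme: EnzymeConfig = field(default_factory=EnzymeConfig)
    region: RegionConfig = field(default_factory=RegionConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = {"seed": d.get("seed", 0)}
        for name, sub in (
            ("plate", PlateConfig),
            ("growth", GrowthConfig),
            ("population", PopulationConfig),
            ("metabolome", MetabolomeConfig),
            ("enzyme", EnzymeConfig),
            ("region", RegionConfig),
        ):
            if name in d:
                kwargs[name] = sub(**d[name])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class PlateTruth:
    bias_field: np.ndarray  # (n_rows, n_cols), multiplicative, > 0
    strain_effect: dict[str, float]  # true relative fitness, control = 1.0
    noise_sd: float


@dataclass
class PopulationTruth:
    causal_index: int
    beta: float
    h2_poly: float
    lineage_divergence: float
    allele_freqs: np.ndarray  # (n_lineages, n_variants)
    lineage: np.ndarray  # per-strain lineage index
    genetic_values: np.ndarray  # beta * g_causal + polygenic component
    realized_h2: float
    target_h2: float


CONTROL_STRAIN = "control"


# ---------------------------------------------------------------------------
# colony plates


def reference_positions(n_rows: int = 16, n_cols: int = 24) -> np.ndarray:
    """Boolean mask of the reference subgrid: (even row, even col).

    One position per 2x2 block, the geometry of up-pinning a 96-array onto a
    384-array, giving a uniform 8x12 grid of control colonies.
    """
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    return (rows % 2 == 0) & (cols % 2 == 0)


def make_layout(config: PlateConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random plate layout: reference grid + test strains in triplicate +
    interspersed internal control colonies."""
    ref = reference_positions(config.n_rows, config.n_cols)
    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    layout = pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "is_reference": ref.ravel()}
    )
    n_free = (~ref).sum()
    n_needed = config.n_test_strains * config.replicates + config.n_internal_controls
    if n_needed != n_free:
        raise ValueError(
            f"layout needs {n_needed} non-reference positions, plate has {n_free}"
        )
    strains = [f"strain{(i + 1):03d}" for i in range(config.n_test_strains)]
    assignment = np.array(
        [s for s in strains for _ in range(config.replicates)]
        + [CONTROL_STRAIN] * config.n_internal_controls,
        dtype=object,
    )
    rng.shuffle(assignment)
    names = np.full(len(layout), CONTROL_STRAIN, dtype=object)
    names[~ref.ravel()] = assignment
    layout["strain"] = names
    return layout[["row", "col", "strain", "is_reference"]]


def _bias_field(config: PlateConfig, rng: np.random.Generator) -> np.ndarray:
    r = np.linspace(-0.5, 0.5, config.n_rows)[:, None]
    c = np.linspace(-0.5, 0.5, config.n_cols)[None, :]
    a = rng.uniform(-config.bias_row_range, config.bias_row_range)
    b = rng.uniform(-config.bias_col_range, config.bias_col_range)
    bias = 1.0 + a * r + b * c
    if config.bias_smooth_sd > 0:
        rough = rng.normal(0.0, 1.0, size=(config.n_rows, config.n_cols))
        smooth = ndimage.gaussian_filter(rough, sigma=2.0, mode="reflect")
        smooth *= config.bias_smooth_sd / max(smooth.std(), 1e-12)
        bias = bias * np.exp(smooth)
    if np.any(bias <= 0):
        raise ValueError("generated bias field has non-positive entries")
    return bias


def simulate_plate(
    config: SimConfig,
    strain_effects: dict[str, float] | None = None,
    layout: pd.DataFrame | None = None,
    seed_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlateTruth]:
    """Generate one colony plate.

    Returns (plate, layout, truth). Observed size is
    ``base_size * bias(row, col) * strain_effect * exp(noise)``; reference
    positions carry the control strain with effect 1. Pass ``strain_effects``
    and ``layout`` to re-use a screen's truth on a second (condition) plate;
    ``seed_offset`` decorrelates noise between plates of one screen.
    """
    pc = config.plate
    rng = _rng(config.seed, "plate", seed_offset)
    if layout is None:
        layout = make_layout(pc, rng)
    if strain_effects is None:
        strains = sorted(set(layout["strain"]) - {CONTROL_STRAIN})
        effects = np.exp(rng.normal(0.0, pc.strain_effect_sd, size=len(strains)))
        strain_effects = dict(zip(strains, effects))
        strain_effects[CONTROL_STRAIN] = 1.0
    else:
        strain_effects = dict(strain_effects)
        strain_effects.setdefault(CONTROL_STRAIN, 1.0)
    if any(e <= 0 for e in strain_effects.values()):
        raise ValueError("strain effects must be positive")

    bias = _bias_field(pc, rng)
    effect = layout["strain"].map(strain_effects).to_numpy(dtype=float)
    noise = np.exp(rng.normal(0.0, pc.noise_sd, size=len(layout)))
    size = pc.base_size * bias[layout["row"], layout["col"]] * effect * noise
    circ = 1.0 + rng.normal(0.0, pc.circularity_sd, size=len(layout))

    # force a stated fraction of colonies to fail QC downstream
    n_fail = int(round(pc.qc_fail_fraction * len(layout)))
    fail_idx = rng.choice(len(layout), size=n_fail, replace=False)
    for i, idx in enumerate(fail_idx):
        if i % 2 == 0:
            size[idx] = rng.uniform(0.0, 9.0)  # "no growth"
        else:
            circ[idx] = rng.choice([1.15, 0.80])  # abnormal shape

    plate = layout[["row", "col"]].copy()
    plate["size_px"] = size
    plate["circularity"] = circ
    truth = PlateTruth(
        bias_field=bias, strain_effect=strain_effects, noise_sd=pc.noise_sd
    )
    return plate, layout, truth


def simulate_screen(
    config: SimConfig, condition_effect: dict[str, float] | float = 1.0
) -> dict:
    """Paired control/condition plates sharing a layout and strain effects.

    ``condition_effect`` multiplies each strain's true fitness on the
    condition plate (scalar, or per-strain dict defaulting to 1.0); the
    per-strain truth of the resulting resistance score is that multiplier.
    """
    control_plate, layout, truth = simulate_plate(config)
    if np.isscalar(condition_effect):
        cond = {s: float(condition_effect) for s in truth.strain_effect}
    else:
        cond = {s: condition_effect.get(s, 1.0) for s in truth.strain_effect}
    cond[CONTROL_STRAIN] = 1.0
    cond_effects = {s: e * cond[s] for s, e in truth.strain_effect.items()}
    condition_plate, _, cond_truth = simulate_plate(
        config, strain_effects=cond_effects, layout=layout, seed_offset=1
    )
    return {
        "layout": layout,
        "control": control_plate,
        "condition": condition_plate,
        "truth": truth,
        "condition_truth": cond_truth,
        "true_scores": {
            s: m for s, m in cond.items() if s != CONTROL_STRAIN
        },
    }


# ---------------------------------------------------------------------------
# growth curves


def simulate_growth(
    config: SimConfig, seed_offset: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate one OD time series plus analytic truth.

    Logistic model ``OD(t) = K / (1 + exp(-r (t - t0)))`` with additive
    Gaussian noise; maximum derivative is ``r K / 4`` at ``t0``. The linear
    option produces a ramp of the configured slope.
    """
    gc = config.growth
    rng = _rng(config.seed, "growth", seed_offset)
    if gc.kind == "logistic" and (gc.carrying_capacity <= 0 or gc.rate <= 0):
        raise ValueError("logistic growth needs K > 0 and r > 0")
    dt = gc.interval_min / 60.0
    t = np.arange(0.0, gc.duration_h + dt / 2, dt)
    if gc.kind == "logistic":
        od = gc.carrying_capacity / (1.0 + np.exp(-gc.rate * (t - gc.t_mid)))
        true_slope = gc.rate * gc.carrying_capacity / 4.0
        t_max = gc.t_mid
    elif gc.kind == "linear":
        od = gc.linear_slope * t
        true_slope = gc.linear_slope
        t_max = float(t[len(t) // 2])
    else:
        raise ValueError(f"unknown growth kind {gc.kind!r}")
    noisy = od + rng.normal(0.0, gc.noise_sd, size=len(t))
    curve = pd.DataFrame({"time": t, "od": noisy, "od_noiseless": od})
    truth = {
        "true_max_slope": float(true_slope),  # OD per hour
        "t_max": float(t_max),
        "interval_h": dt,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# structured haploid population


def simulate_population(
    config: SimConfig, seed_offset: int = 0
) -> tuple[np.ndarray, pd.DataFrame, list[str], np.ndarray, PopulationTruth]:
    """Generate a structured haploid genotype matrix and phenotype.

    Balding-Nichols lineage model: each variant's ancestral frequency p is
    uniform on [freq_low, freq_high]; each lineage draws its frequency from
    Beta(p (1-F)/F, (1-p) (1-F)/F) and strains draw haploid alleles from
    their lineage frequency. The causal variant is planted with an exact
    carrier count. Phenotype = beta * g_causal + polygenic + residual; the
    polygenic part has covariance h2_poly * K (per-variant effects over the
    standardized genotypes) and the residual variance is 1 - h2_poly.

    Returns (calls, variants, strains, phenotype, truth); ``calls`` is
    (n_strains, n_variants) float with NaN for missing.
    """
    pop = config.population
    rng = _rng(config.seed, "population", seed_offset)
    if not 0.0 <= pop.h2_poly <= 1.0:
        raise ValueError("h2_poly must lie in [0, 1]")
    if not 0.0 < pop.fst < 1.0:
        raise ValueError("Balding-Nichols F must lie in (0, 1)")
    n, m = pop.n_strains, pop.n_variants
    lineage = rng.integers(0, pop.n_lineages, size=n)
    p_anc = rng.uniform(pop.freq_low, pop.freq_high, size=m)
    a = p_anc * (1.0 - pop.fst) / pop.fst
    b = (1.0 - p_anc) * (1.0 - pop.fst) / pop.fst
    freqs = rng.beta(a, b, size=(pop.n_lineages, m))
    calls = (rng.random((n, m)) < freqs[lineage, :]).astype(float)

    # plant the causal variant with an exact carrier count
    causal_index = int(rng.integers(0, m))
    carriers = rng.choice(n, size=pop.causal_carriers, replace=False)
    g_causal = np.zeros(n)
    g_causal[carriers] = 1.0
    calls[:, causal_index] = g_causal

    if pop.missing_rate > 0:
        mask = rng.random((n, m)) < pop.missing_rate
        mask[:, causal_index] = False
        calls[mask] = np.nan

    # polygenic component from standardized genotypes, exact sample variance
    filled = np.where(np.isnan(calls), np.nanmean(calls, axis=0), calls)
    z = filled - filled.mean(axis=0)
    sd = z.std(axis=0)
    ok = sd > 0
    z = z[:, ok] / sd[ok]
    # per-variant effects give u ~ (0, h2_poly * K) conditional on genotypes
    u = z @ rng.normal(0.0, 1.0, size=ok.sum()) / np.sqrt(ok.sum())
    u *= np.sqrt(pop.h2_poly)
    e = rng.normal(0.0, np.sqrt(1.0 - pop.h2_poly), size=n)
    genetic = pop.beta * g_causal + u
    y = genetic + e

    var_y = y.var()
    realized_h2 = float(genetic.var() / var_y) if var_y > 0 else 0.0
    strains = [f"JB{i + 1:03d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "I",
            "pos": np.sort(rng.choice(np.arange(1, 10 * m + 1), size=m, replace=False)),
            "ref": "A",
            "alt": "T",
        }
    )
    truth = PopulationTruth(
        causal_index=causal_index,
        beta=pop.beta,
        h2_poly=pop.h2_poly,
        lineage_divergence=pop.fst,
        allele_freqs=freqs,
        lineage=lineage,
        genetic_values=genetic,
        realized_h2=realized_h2,
        target_h2=float(pop.h2_poly) if pop.beta == 0 else realized_h2,
    )
    return calls, variants, strains, y, truth


def phenotype_from_kinship(
    K: np.ndarray, h2: float, seed: int
) -> np.ndarray:
    """Draw one phenotype from the variance-component model given a kinship.

    y = g + e with g ~ MVN(0, h2 * K) and e ~ N(0, (1 - h2) * I); the exact
    generative model of the REML fit, for parameter-recovery simulations.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    s, u = np.linalg.eigh(np.asarray(K, dtype=float))
    s = np.clip(s, 0.0, None)
    g = u @ (np.sqrt(h2 * s) * rng.standard_normal(len(s)))
    e = rng.standard_normal(len(s)) * np.sqrt(1.0 - h2)
    return g + e


# ---------------------------------------------------------------------------
# metabolome tables


def simulate_metabolome(
    config: SimConfig, seed_offset: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Two-group metabolite table with log-normal sampling noise.

    Group T (reference) has mean ``base_mean`` per metabolite; group A has
    mean ``base_mean * fold_change``. Noise is log-normal with the configured
    coefficient of variation. Truth stores the true A/T fold change.
    """
    mc = config.metabolome
    rng = _rng(config.seed, "metabolome", seed_offset)
    if mc.cv < 0:
        raise ValueError("CV must be non-negative")
    fc = np.broadcast_to(
        np.asarray(mc.fold_change, dtype=float), (mc.n_metabolites,)
    ).copy()
    sigma = np.sqrt(np.log1p(mc.cv**2))
    # mean-preserving log-normal: E[exp(N(-s^2/2, s^2))] = 1
    def draw(n_samples, means):
        ln = rng.normal(-0.5 * sigma**2, sigma, size=(n_samples, mc.n_metabolites))
        return means[None, :] * np.exp(ln)

    mean_t = np.full(mc.n_metabolites, mc.base_mean)
    mean_a = mean_t * fc
    conc = np.vstack([draw(mc.n_group_t, mean_t), draw(mc.n_group_a, mean_a)])
    metabolites = [f"met{j + 1:03d}" for j in range(mc.n_metabolites)]
    table = pd.DataFrame(conc, columns=metabolites)
    table.insert(0, "sample", [f"s{i + 1:02d}" for i in range(len(table))])
    table.insert(1, "group", ["T"] * mc.n_group_t + ["A"] * mc.n_group_a)
    table.insert(2, "culture_od", mc.culture_od)
    truth = {"fold_change": fc, "cv": mc.cv, "metabolites": metabolites}
    return table, truth


# ---------------------------------------------------------------------------
# enzyme-assay absorbance traces


def simulate_enzyme_trace(
    config: SimConfig, seed_offset: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Linear NADH-depletion trace and its blank, as absorbance at 340 nm.

    Concentration falls at the true rate (M/min); absorbance follows
    Beer-Lambert A = C * epsilon * path. Points below the 0.2 absorbance
    floor are marked censored in the truth.
    """
    ec = config.enzyme
    rng = _rng(config.seed, "enzyme", seed_offset)
    if ec.path_cm <= 0:
        raise ValueError("path length must be positive")
    t = np.arange(0.0, ec.duration_min + 1e-9, ec.interval_s / 60.0)
    scale = ec.epsilon * ec.path_cm  # absorbance per molar
    a_clean = ec.start_absorbance - ec.rate * scale * t
    trace = pd.DataFrame(
        {"time_min": t, "a340": a_clean + rng.normal(0.0, ec.noise_sd, len(t))}
    )
    blank_clean = ec.start_absorbance - ec.blank_rate * scale * t
    blank = pd.DataFrame(
        {"time_min": t, "a340": blank_clean + rng.normal(0.0, ec.noise_sd, len(t))}
    )
    truth = {
        "rate": ec.rate,
        "blank_rate": ec.blank_rate,
        "slope_absorbance": -ec.rate * scale,  # per minute
        "censored": a_clean < ec.censor_floor,
        "culture_od": ec.culture_od,
    }
    return trace, blank, truth


# ---------------------------------------------------------------------------
# region variants on a known tree


class _Node:
    __slots__ = ("name", "children", "length", "leaves")

    def __init__(self, name=None, children=(), length=0.0):
        self.name = name
        self.children = list(children)
        self.length = length
        self.leaves = (
            {name} if not children else set().union(*(c.leaves for c in children))
        )

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def _random_tree(taxa: list[str], rng: np.random.Generator) -> _Node:
    nodes = [_Node(name=t) for t in taxa]
    for node in nodes:
        node.length = rng.exponential(1.0)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = _Node(children=(nodes[i], nodes[j]), length=rng.exponential(1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = _Node(children=tuple(nodes), length=0.0)
    return root


def _edges(root: _Node) -> list[_Node]:
    out = []

    def walk(node):
        for child in node.children:
            out.append(child)
            walk(child)

    walk(root)
    # the two root-adjacent edges form a single edge of the unrooted tree;
    # dropping one of them avoids double-counting its split
    if len(root.children) == 2:
        out.remove(root.children[1])
    return out


def simulate_region_variants(
    config: SimConfig, seed_offset: int = 0
) -> tuple[list[str], pd.DataFrame, np.ndarray, dict]:
    """Haplotypes from mutations dropped on a known random tree.

    Infinite-sites: each SNP mutates once, on an edge chosen with probability
    proportional to branch length; taxa below the edge carry the alternate
    allele. Decoy indel and multiallelic records are added so downstream
    biallelic-SNP extraction has something to reject.

    Returns (samples, variants, calls, truth); truth holds the generating
    topology as Newick, with branch lengths in realized substitutions per SNP
    site so that p-distances are exactly additive on it.
    """
    rc = config.region
    rng = _rng(config.seed, "region", seed_offset)
    if rc.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    taxa = [f"JB{i + 1:03d}" for i in range(rc.n_taxa)]
    root = _random_tree(taxa, rng)
    edges = _edges(root)
    lengths = np.array([e.length for e in edges])
    mut_edge = rng.choice(len(edges), size=rc.n_snps, p=lengths / lengths.sum())

    taxon_index = {t: i for i, t in enumerate(taxa)}
    calls = np.zeros((rc.n_taxa, rc.n_snps))
    counts = np.zeros(len(edges), dtype=int)
    for j, ei in enumerate(mut_edge):
        counts[ei] += 1
        for t in edges[ei].leaves:
            calls[taxon_index[t], j] = 1.0

    # rewrite branch lengths as realized substitutions per site
    for e, c in zip(edges, counts):
        e.length = c / rc.n_snps
    if len(root.children) == 2:
        root.children[1].length = 0.0

    n_sites = rc.n_snps + rc.n_decoy_indels + rc.n_decoy_multiallelic
    span = rc.region_end - rc.region_start
    if span + 1 < n_sites:
        raise ValueError("region too small for requested site count")
    pos = np.sort(
        rng.choice(np.arange(rc.region_start, rc.region_end + 1), n_sites, False)
    )
    kinds = np.array(
        ["snp"] * rc.n_snps
        + ["indel"] * rc.n_decoy_indels
        + ["multi"] * rc.n_decoy_multiallelic
    )
    rng.shuffle(kinds)
    bases = np.array(list("ACGT"))
    rows, snp_j = [], 0
    all_calls = []
    for p, kind in zip(pos, kinds):
        ref, alt = rng.choice(bases, size=2, replace=False)
        if kind == "snp":
            col = calls[:, snp_j].copy()
            if rc.missing_rate > 0:
                col[rng.random(rc.n_taxa) < rc.missing_rate] = np.nan
            rows.append({"chrom": rc.chrom, "pos": int(p), "ref": ref, "alt": alt})
            all_calls.append(col)
            snp_j += 1
        elif kind == "indel":
            rows.append(
                {"chrom": rc.chrom, "pos": int(p), "ref": ref + alt, "alt": ref}
            )
            all_calls.append(rng.integers(0, 2, rc.n_taxa).astype(float))
        else:
            third = rng.choice([b for b in bases if b not in (ref, alt)])
            rows.append(
                {"chrom": rc.chrom, "pos": int(p), "ref": ref, "alt": f"{alt},{third}"}
            )
            all_calls.append(rng.integers(0, 3, rc.n_taxa).astype(float))
    variants = pd.DataFrame(rows)
    call_matrix = np.column_stack(all_calls)
    truth = {
        "newick": root.newick() + ";",
        "n_snps": rc.n_snps,
        "mutations_per_edge": counts,
    }
    return taxa, variants, call_matrix, truth
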