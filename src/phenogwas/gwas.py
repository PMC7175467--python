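"""Mixed-model GWAS for a haploid strain panel.

Workflow: Box-Cox-standardize the phenotype, filter variants at MAF > 5%,
build a centered-scaled genomic relationship (kinship) matrix, estimate
variance components by REML under ``y = mu + g + e`` with
``g ~ (0, sigma_g^2 K)`` and ``e ~ (0, sigma_e^2 I)``, and scan each variant
by generalized least squares with variance components fixed at their
null-model estimates (the EMMAX approximation), reporting Wald p-values.

Narrow-sense heritability is ``h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GenotypeMatrix:
    """Haploid 0/1 calls for strains x variants; NaN marks missing calls."""

    calls: np.ndarray  # (n_strains, n_variants), float, values {0, 1, NaN}
    variants: pd.DataFrame  # columns chrom, pos (1-based), ref, alt [, annotation]
    strains: list[str]

    def __post_init__(self):
        vals = self.calls[~np.isnan(self.calls)]
        if vals.size and not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("haploid calls must be 0, 1 or missing")

    @property
    def n_strains(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.calls, axis=0)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class PhenotypeVector:
    """Raw and Box-Cox-standardized phenotype values per strain."""

    strains: list[str]
    raw: np.ndarray
    transformed: np.ndarray  # mean 0, variance 1
    lmbda: float
    shift: float  # added to raw values before the power transform


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    converged: bool = True


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic haploid calls from a VCF (plain text or compressed).

    Multiallelic records and records with non-haploid genotypes are rejected;
    indels are kept (a "variant" here is any biallelic small variant, as in a
    freebayes-style haploid call set).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    rows, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        col = np.full(len(strains), np.nan)
        for i, gt in enumerate(rec.genotypes):
            allele = gt[0]
            if allele >= 0:
                col[i] = float(allele)
        rows.append(
            dict(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0])
        )
        columns.append(col)
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        calls=np.column_stack(columns),
        variants=pd.DataFrame(rows),
        strains=strains,
    )


# ---------------------------------------------------------------------------
# phenotype transformation


def boxcox_transform(
    strains: list[str] | np.ndarray, raw: np.ndarray
) -> PhenotypeVector:
    """Box-Cox transform (maximum-likelihood lambda), then standardize.

    Non-positive inputs are shifted by ``1 - min(raw)`` first, and the shift
    is recorded. Output has mean 0 and variance 1 (population variance).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 10:
        raise ValueError("need at least 10 values to fit a Box-Cox transform")
    if np.ptp(raw) == 0:
        raise ValueError("constant phenotype: Box-Cox lambda is undefined")
    shift = 0.0
    shifted = raw
    if raw.min() <= 0:
        shift = 1.0 - raw.min()
        shifted = raw + shift
    transformed, lmbda = stats.boxcox(shifted)
    standardized = (transformed - transformed.mean()) / transformed.std()
    return PhenotypeVector(
        strains=list(strains),
        raw=raw,
        transformed=standardized,
        lmbda=float(lmbda),
        shift=shift,
    )


# ---------------------------------------------------------------------------
# variant filtering and kinship


def filter_maf(G: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop variants with minor allele frequency <= threshold (keep MAF > 5%)."""
    keep = G.maf() > threshold
    return GenotypeMatrix(
        calls=G.calls[:, keep],
        variants=G.variants.loc[keep].reset_index(drop=True),
        strains=G.strains,
    )


def kinship_grm(G: GenotypeMatrix) -> np.ndarray:
    """Centered-scaled genomic relationship matrix K = Z Z' / m.

    Missing calls are mean-imputed per variant; columns are centered and
    scaled to unit variance. K is symmetrized and eigenvalue-clipped to be
    positive semi-definite; its diagonal averages ~1.
    """
    if G.n_variants == 0:
        raise ValueError("no variants left to build a kinship matrix from")
    z = G.calls.copy()
    col_mean = np.nanmean(z, axis=0)
    nan_r, nan_c = np.where(np.isnan(z))
    z[nan_r, nan_c] = col_mean[nan_c]
    z -= z.mean(axis=0)
    sd = z.std(axis=0)
    ok = sd > 0
    if not ok.any():
        raise ValueError("all variants are constant after imputation")
    z = z[:, ok] / sd[ok]
    k = z @ z.T / ok.sum()
    k = (k + k.T) / 2.0
    w, v = np.linalg.eigh(k)
    if w.min() < -1e-8:
        k = (v * np.clip(w, 0.0, None)) @ v.T
        k = (k + k.T) / 2.0
    return k


# ---------------------------------------------------------------------------
# REML variance components


def _reml_neg_loglik(h2: float, s: np.ndarray, yr: np.ndarray, xr: np.ndarray):
    """Negative REML log-likelihood profiled over beta and total variance.

    ``s`` are eigenvalues of K; ``yr``/``xr`` are phenotype and fixed-effect
    design rotated into K's eigenbasis. V = sigma2 * diag(h2*s + 1 - h2).
    """
    d = h2 * s + (1.0 - h2)
    if np.any(d <= 0):
        return np.inf, None
    w = 1.0 / d
    xtwx = xr.T @ (w[:, None] * xr)
    xtwy = xr.T @ (w * yr)
    beta = np.linalg.solve(xtwx, xtwy)
    r = yr - xr @ beta
    n, p = xr.shape
    rss = float(r @ (w * r))
    sigma2 = rss / (n - p)
    _, logdet_xtwx = np.linalg.slogdet(xtwx)
    nll = 0.5 * (
        (n - p) * np.log(sigma2)
        + np.sum(np.log(d))
        + logdet_xtwx
        + (n - p)
    )
    return nll, (beta, sigma2)


def reml_fit(
    y: np.ndarray, K: np.ndarray, n_grid: int = 100
) -> VarianceComponents:
    """REML variance components for ``y = mu + g + e`` with g ~ (0, sg^2 K).

    The REML log-likelihood is profiled to a one-dimensional function of
    h2 = sg^2/(sg^2+se^2) after spectral decomposition of K, scanned on a
    grid and refined by bounded scalar minimization; boundary solutions
    (h2 = 0 or 1) are allowed.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("kinship matrix does not match phenotype length")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    s, u = np.linalg.eigh(K)
    if s.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semi-definite")
    s = np.clip(s, 0.0, None)
    yr = u.T @ y
    xr = u.T @ np.ones((n, 1))

    grid = np.linspace(0.0, 1.0 - 1e-9, n_grid)
    nlls = np.array([_reml_neg_loglik(h, s, yr, xr)[0] for h in grid])
    if not np.isfinite(nlls).any():
        raise RuntimeError("REML likelihood is not finite anywhere on [0, 1)")
    best = int(np.nanargmin(nlls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda h: _reml_neg_loglik(h, s, yr, xr)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x) if res.fun <= nlls[best] else float(grid[best])
    nll, aux = _reml_neg_loglik(h2, s, yr, xr)
    _, sigma2 = aux
    return VarianceComponents(
        sigma_g2=float(sigma2 * h2),
        sigma_e2=float(sigma2 * (1.0 - h2)),
        h2=h2,
        reml_loglik=float(-nll),
        converged=bool(np.isfinite(nll)),
    )


# ---------------------------------------------------------------------------
# association scan


def lmm_scan(
    y: np.ndarray,
    K: np.ndarray,
    G: GenotypeMatrix,
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Mixed-model association scan with fixed variance components (EMMAX).

    Per variant, generalized least squares of the phenotype on an intercept
    plus the allele dosage under the null covariance
    ``V = sigma_g^2 K + sigma_e^2 I``; Wald z-test with a Gaussian reference.
    Missing calls are excluded case-wise per variant (the GLS is then solved
    on the subsetted covariance). Variants constant after missing-exclusion
    are skipped with a flag.

    Returns a DataFrame sorted by p with columns variant, chrom, pos, maf,
    beta, se, p, bh_q, n, skipped.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if vc is None:
        vc = reml_fit(y, K)
    s, u = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    d = vc.sigma_g2 * s + vc.sigma_e2
    if np.any(d <= 0):
        raise ValueError("null covariance is singular (all variance at zero)")
    v_full = (u * (vc.sigma_g2 * s)) @ u.T + vc.sigma_e2 * np.eye(n)

    # fast path: rotate once, weight by 1/d
    w = 1.0 / d
    yr = u.T @ y
    ones_r = u.T @ np.ones(n)

    maf = G.maf()
    complete = ~np.isnan(G.calls).any(axis=0)
    betas = np.full(G.n_variants, np.nan)
    ses = np.full(G.n_variants, np.nan)
    ps = np.full(G.n_variants, np.nan)
    ns = np.full(G.n_variants, n)
    skipped = np.zeros(G.n_variants, dtype=bool)

    def gls(yv, X, vinv):
        xtvx = X.T @ vinv @ X
        cov = np.linalg.inv(xtvx)
        beta = cov @ (X.T @ (vinv @ yv))
        return beta, cov

    if complete.any():
        gr = u.T @ G.calls[:, complete]  # rotated genotypes
        # closed-form 2x2 GLS for [1, g] per variant, vectorized
        a = float(ones_r @ (w * ones_r))
        b = (ones_r * w) @ gr
        c = (gr * w[:, None] * gr).sum(axis=0)
        ry = (ones_r * w) @ yr
        gy = (gr * w[:, None]).T @ yr
        det = a * c - b * b
        const = np.isclose(det, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_g = (a * gy - b * ry) / det
            se_g = np.sqrt(a / det)
        idx = np.where(complete)[0]
        betas[idx] = beta_g
        ses[idx] = se_g
        skipped[idx] = const
    for j in np.where(~complete)[0]:
        g = G.calls[:, j]
        keep = ~np.isnan(g)
        ns[j] = int(keep.sum())
        gk = g[keep]
        if np.ptp(gk) == 0:
            skipped[j] = True
            continue
        vinv = np.linalg.inv(v_full[np.ix_(keep, keep)])
        X = np.column_stack([np.ones(keep.sum()), gk])
        beta, cov = gls(y[keep], X, vinv)
        betas[j], ses[j] = beta[1], np.sqrt(cov[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = betas / ses
    ps = 2.0 * stats.norm.sf(np.abs(z))
    ps[skipped] = np.nan

    out = G.variants.copy()
    out.insert(0, "variant", [
        f"{c}:{p}_{r}/{al}" for c, p, r, al in zip(
            out["chrom"], out["pos"], out["ref"], out["alt"]
        )
    ])
    out["maf"] = maf
    out["beta"] = betas
    out["se"] = ses
    out["p"] = ps
    out["n"] = ns
    out["skipped"] = skipped
    tested = ~out["p"].isna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    out["bh_q"] = q
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor lambda_GC: median chi2(1) / expected median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
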