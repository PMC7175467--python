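"""Phenotype transform, kinship, REML heritability and association scan."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from conftest import population_config
from phenogwas import gwas, simulate as sim


def make_genotypes(calls, positions=None):
    n, m = calls.shape
    variants = pd.DataFrame(
        {
            "chrom": "I",
            "pos": positions if positions is not None else np.arange(1, m + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    return gwas.GenotypeMatrix(
        calls=np.asarray(calls, dtype=float),
        variants=variants,
        strains=[f"s{i}" for i in range(n)],
    )


def grid_boxcox_lambda(x, lambdas=np.linspace(-2, 2, 401)):
    """Independent grid-search MLE for the Box-Cox exponent."""
    lls = [stats.boxcox_llf(l, x) for l in lambdas]
    return lambdas[int(np.argmax(lls))]


def direct_reml_loglik(y, K, sigma_g2, sigma_e2):
    """Textbook REML log-likelihood with explicit matrices (up to a constant)."""
    n = len(y)
    X = np.ones((n, 1))
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ld_v + ld_x + y @ P @ y))


class TestBoxCox:
    def test_normal_sample_gives_lambda_near_one(self):
        # standard-normal input, shifted positive internally; the MLE exponent
        # is ~1 on average (single-draw spread at n = 200 is a few tenths)
        strains = [f"s{i}" for i in range(200)]
        lambdas = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0.0, 1.0, size=200)
            pv = gwas.boxcox_transform(strains, x)
            assert pv.lmbda == pytest.approx(
                grid_boxcox_lambda(x + pv.shift), abs=0.02
            )
            lambdas.append(pv.lmbda)
        assert abs(np.mean(lambdas) - 1.0) < 0.3

    def test_lognormal_sample_gives_lambda_near_zero(self):
        strains = [f"s{i}" for i in range(200)]
        lambdas = []
        for seed in range(10):
            x = np.exp(np.random.default_rng(seed).normal(0.0, 1.0, size=200))
            pv = gwas.boxcox_transform(strains, x)
            assert pv.lmbda == pytest.approx(grid_boxcox_lambda(x), abs=0.02)
            lambdas.append(pv.lmbda)
        assert abs(np.mean(lambdas)) < 0.3

    def test_output_standardized(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 1.0, size=50)
        pv = gwas.boxcox_transform([f"s{i}" for i in range(50)], x)
        assert abs(pv.transformed.mean()) < 1e-8
        assert abs(pv.transformed.var() - 1.0) < 1e-8

    def test_non_positive_values_shifted_and_recorded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, size=100)
        pv = gwas.boxcox_transform([f"s{i}" for i in range(100)], x)
        assert pv.shift == pytest.approx(1.0 - x.min())

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            gwas.boxcox_transform(list("abcdefghij"), np.full(10, 2.0))


class TestMafFilter:
    def test_18_of_161_retained_8_removed(self):
        calls = np.zeros((161, 2))
        calls[:18, 0] = 1.0  # MAF 0.1118 > 0.05 -> kept
        calls[:8, 1] = 1.0  # MAF 0.0497 <= 0.05 -> removed
        G = gwas.filter_maf(make_genotypes(calls))
        assert G.n_variants == 1
        assert G.maf()[0] == pytest.approx(18 / 161)

    def test_monomorphic_variant_removed(self):
        calls = np.zeros((20, 1))
        assert gwas.filter_maf(make_genotypes(calls)).n_variants == 0

    def test_maf_uses_non_missing_calls(self):
        calls = np.zeros((20, 1))
        calls[:3, 0] = 1.0
        calls[10:, 0] = np.nan  # 3/10 among non-missing
        G = make_genotypes(calls)
        assert G.maf()[0] == pytest.approx(0.3)


class TestKinship:
    def test_identical_strains_share_diagonal_value(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, size=(10, 300)).astype(float)
        calls[1] = calls[0]
        K = gwas.kinship_grm(make_genotypes(calls))
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_independent_variants_give_near_identity(self):
        rng = np.random.default_rng(5)
        calls = (rng.random((30, 5000)) < 0.5).astype(float)
        K = gwas.kinship_grm(make_genotypes(calls))
        assert np.allclose(np.diag(K), 1.0, atol=0.05)
        off = K[~np.eye(30, dtype=bool)]
        assert np.abs(off).max() < 0.05 * np.sqrt(5000 / 30) / 3 + 0.05

    def test_two_lineage_structure_shows_in_kinship(self):
        cfg = population_config(10, fst=0.4, n_lineages=2)
        calls, variants, strains, _, truth = sim.simulate_population(cfg)
        K = gwas.kinship_grm(gwas.filter_maf(make_genotypes(calls)))
        same = truth.lineage[:, None] == truth.lineage[None, :]
        off_diag = ~np.eye(len(strains), dtype=bool)
        assert K[same & off_diag].mean() > K[~same].mean()

    def test_psd_and_symmetric(self):
        cfg = population_config(11, missing_rate=0.1)
        calls, *_ = sim.simulate_population(cfg)
        K = gwas.kinship_grm(gwas.filter_maf(make_genotypes(calls)))
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)


class TestReml:
    def test_recovers_h2_half_over_seeds(self):
        ests = []
        for seed in range(50):
            cfg = population_config(seed, beta=0.0, h2_poly=0.5)
            calls, *_ = sim.simulate_population(cfg)
            K = gwas.kinship_grm(gwas.filter_maf(make_genotypes(calls)))
            y = sim.phenotype_from_kinship(K, h2=0.5, seed=seed)
            ests.append(gwas.reml_fit(y, K).h2)
        assert abs(np.mean(ests) - 0.5) < 0.05

    def test_pure_noise_phenotype_gives_near_zero_h2(self):
        ests = []
        for seed in range(50):
            cfg = population_config(seed, beta=0.0, h2_poly=0.5)
            calls, *_ = sim.simulate_population(cfg)
            K = gwas.kinship_grm(gwas.filter_maf(make_genotypes(calls)))
            rng = np.random.default_rng(seed)
            ests.append(gwas.reml_fit(rng.standard_normal(len(K)), K).h2)
        assert np.median(ests) < 0.1

    def test_optimum_beats_direct_likelihood_grid(self):
        cfg = population_config(12, beta=0.0, h2_poly=0.5)
        calls, *_ = sim.simulate_population(cfg)
        K = gwas.kinship_grm(gwas.filter_maf(make_genotypes(calls)))
        y = sim.phenotype_from_kinship(K, h2=0.5, seed=12)
        vc = gwas.reml_fit(y, K)
        ll_hat = direct_reml_loglik(y, K, vc.sigma_g2, vc.sigma_e2)
        total = vc.sigma_g2 + vc.sigma_e2
        for h2 in np.linspace(0.005, 0.995, 100):
            # profile the total variance at each grid point independently
            res = optimize.minimize_scalar(
                lambda log_s2: -direct_reml_loglik(
                    y, K, np.exp(log_s2) * h2, np.exp(log_s2) * (1 - h2)
                ),
                bounds=(np.log(total) - 3, np.log(total) + 3),
                method="bounded",
            )
            assert ll_hat >= -res.fun - 1e-6

    def test_h2_bounded_and_strain_permutation_invariant(self):
        cfg = population_config(13, beta=0.0, h2_poly=0.5)
        calls, *_ = sim.simulate_population(cfg)
        K = gwas.kinship_grm(gwas.filter_maf(make_genotypes(calls)))
        y = sim.phenotype_from_kinship(K, h2=0.5, seed=13)
        vc = gwas.reml_fit(y, K)
        assert 0.0 <= vc.h2 <= 1.0
        perm = np.random.default_rng(0).permutation(len(y))
        vc_p = gwas.reml_fit(y[perm], K[np.ix_(perm, perm)])
        assert vc_p.h2 == pytest.approx(vc.h2, abs=1e-6)

    def test_non_psd_kinship_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            gwas.reml_fit(np.array([0.1, -0.1]), bad)


class TestLmmScan:
    def test_null_pvalues_calibrated_with_structure(self):
        cfg = population_config(7, beta=0.0, h2_poly=0.5, n_variants=5000)
        calls, variants, strains, y, _ = sim.simulate_population(cfg)
        G = gwas.filter_maf(make_genotypes(calls))
        K = gwas.kinship_grm(G)
        assoc = gwas.lmm_scan(y, K, G)
        p = assoc["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.03
        assert 0.9 < gwas.genomic_inflation(p) < 1.1

    def test_causal_variant_ranks_high_in_power_simulation(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = population_config(
                seed, beta=0.8, h2_poly=0.5, causal_carriers=18
            )
            calls, variants, strains, y, truth = sim.simulate_population(cfg)
            G = gwas.filter_maf(make_genotypes(calls, variants["pos"]))
            K = gwas.kinship_grm(G)
            assoc = gwas.lmm_scan(y, K, G)
            causal_pos = variants.loc[truth.causal_index, "pos"]
            rank = int(np.flatnonzero(assoc["pos"] == causal_pos)[0])
            hits += rank < max(1, int(0.01 * len(assoc)))
        assert hits / n_seeds >= 0.8

    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(14)
        n = 80
        calls = (rng.random((n, 5)) < 0.3).astype(float)
        y = rng.standard_normal(n)
        G = make_genotypes(calls)
        for j in range(5):
            x = calls[:, j]
            ols = stats.linregress(x, y)
            resid = y - (ols.intercept + ols.slope * x)
            s2 = float(resid @ resid) / (n - 2)
            vc = gwas.VarianceComponents(0.0, s2, 0.0, 0.0)
            assoc = gwas.lmm_scan(y, np.eye(n), G, vc=vc)
            row = assoc[assoc["pos"] == j + 1].iloc[0]
            assert row["beta"] == pytest.approx(ols.slope, abs=1e-8)
            assert row["se"] == pytest.approx(ols.stderr, abs=1e-8)

    def test_structure_correction_deflates_lineage_variant(self):
        cfg = population_config(15, beta=0.0, h2_poly=0.5)
        calls, variants, strains, y, truth = sim.simulate_population(cfg)
        # variant carried by exactly one lineage, at pos 1
        calls[:, 0] = (truth.lineage == 0).astype(float)
        G = gwas.filter_maf(make_genotypes(calls))
        K = gwas.kinship_grm(G)
        with_k = gwas.lmm_scan(y, K, G)
        vc0 = gwas.VarianceComponents(0.0, float(y.var()), 0.0, 0.0)
        without_k = gwas.lmm_scan(y, np.eye(len(y)), G, vc=vc0)
        p_with = float(with_k.loc[with_k["pos"] == 1, "p"].iloc[0])
        p_without = float(without_k.loc[without_k["pos"] == 1, "p"].iloc[0])
        assert p_with > p_without

    def test_constant_variant_skipped(self):
        rng = np.random.default_rng(16)
        calls = (rng.random((40, 3)) < 0.5).astype(float)
        calls[:, 1] = np.nan
        calls[:5, 1] = 1.0  # constant after missing-exclusion
        y = rng.standard_normal(40)
        G = make_genotypes(calls)
        vc = gwas.VarianceComponents(0.0, 1.0, 0.0, 0.0)
        assoc = gwas.lmm_scan(y, np.eye(40), G, vc=vc)
        row = assoc[assoc["pos"] == 2].iloc[0]
        assert bool(row["skipped"]) and np.isnan(row["p"])

    def test_outputs_invariant_to_strain_permutation(self):
        cfg = population_config(17, n_strains=60, n_variants=200)
        calls, variants, strains, y, _ = sim.simulate_population(cfg)
        G = gwas.filter_maf(make_genotypes(calls, variants["pos"]))
        K = gwas.kinship_grm(G)
        vc = gwas.reml_fit(y, K)
        base = gwas.lmm_scan(y, K, G, vc=vc)
        perm = np.random.default_rng(1).permutation(len(y))
        Gp = gwas.GenotypeMatrix(
            G.calls[perm], G.variants, [G.strains[i] for i in perm]
        )
        permuted = gwas.lmm_scan(
            y[perm], K[np.ix_(perm, perm)], Gp, vc=vc
        )
        merged = base.merge(permuted, on="pos", suffixes=("_a", "_b"))
        assert np.allclose(merged["beta_a"], merged["beta_b"], atol=1e-8)
        assert np.allclose(merged["p_a"], merged["p_b"], atol=1e-8)
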