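"""Simulation studies quantifying the method's headline properties.

Each function runs a self-contained synthetic study against the package's own
machinery and returns plain numbers: the summary-statistics/individual-level
equivalence error, fine-mapping credible-set coverage, the resolution gain of
joint over single-factor fine-mapping, latent-factor null calibration, and
factor-count recovery.  They are deterministic given their seed and are what
both the test suite and the reproduction script run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .factor import FactorModel, factor_scores, parallel_analysis
from .finemap import RegionData, credible_set, dynamic_cmax
from .flashfm import flashfm_zero_with_finemap
from .gwas import gwas_ols, harmonise, latent_sumstats_from_traits
from .simulate import simulate_factor_traits, simulate_genotypes

__all__ = [
    "summary_stat_equivalence_study",
    "shared_causal_resolution_study",
    "single_causal_coverage_study",
    "null_calibration_study",
    "factor_recovery_study",
]


def _block_loading(P: int, K: int, value: float = 0.8) -> pd.DataFrame:
    L = np.zeros((P, K))
    for i in range(P):
        L[i, i % K] = value
    return pd.DataFrame(L, index=[f"T{i+1}" for i in range(P)],
                        columns=[f"F{k+1}" for k in range(K)])


def _standardize(Y: pd.DataFrame) -> pd.DataFrame:
    return (Y - Y.mean()) / Y.std()


def summary_stat_equivalence_study(
    seed: int,
    n: int = 2000,
    P: int = 12,
    K: int = 3,
    n_variants: int = 300,
    effect: float = 0.12,
) -> dict[str, float]:
    """Latent GWAS from trait sumstats vs. OLS on factor scores.

    Returns the maximum absolute beta difference and maximum relative SE
    difference across all factors and variants on a complete synthetic
    cohort.  The betas agree as an algebraic identity; the SEs agree only
    approximately because Var(beta*) uses the marginal trait covariance.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    G = simulate_genotypes(n, n_variants, np.full(n_variants, 0.3), rho=0.5, seed=ss[0])
    L = _block_loading(P, K)
    causal = {"F1": {"rs20": effect}, "F2": {"rs150": effect}}
    Y, _ = simulate_factor_traits(G, L, causal, 1.0, 0.6, seed=ss[1])
    Y = _standardize(Y)

    res = FactorModel.from_traits(Y).fit(n_factors=K, seed=ss[2])
    tables = [gwas_ols(G, Y[c].to_numpy(), trait=c) for c in Y.columns]
    panel = harmonise(tables, min_maf=0.0, min_info=0.0)
    latent = latent_sumstats_from_traits(panel, res.loading_matrix, Y.cov())
    F = factor_scores(Y, res.loading_matrix)

    max_beta, max_se = 0.0, 0.0
    for k, fname in enumerate(res.loading_matrix.factor_names):
        direct = gwas_ols(G, F[fname].to_numpy(), trait=fname)
        b1 = latent[k].table.set_index("SNPID")["BETA"]
        b2 = direct.table.set_index("SNPID")["BETA"]
        s1 = latent[k].table.set_index("SNPID")["SE"]
        s2 = direct.table.set_index("SNPID")["SE"]
        max_beta = max(max_beta, float(np.max(np.abs(b1 - b2))))
        max_se = max(max_se, float(np.max(np.abs(s1 / s2 - 1))))
    return {"max_abs_beta_diff": max_beta, "max_rel_se_diff": max_se}


def _simulated_factor_region(G, causal_idx, effect, rng) -> np.ndarray:
    f = effect * G.dosages[:, causal_idx] + rng.standard_normal(G.n_individuals)
    return (f - f.mean()) / f.std()


def shared_causal_resolution_study(
    seed: int,
    n_regions: int = 100,
    p: int = 50,
    n: int = 10_000,
    rho: float = 0.9,
    n_factors: int = 3,
    effect: float = 0.09,
    kappa: float = 4.0,
    cs_level: float = 0.99,
) -> pd.DataFrame:
    """Joint vs. single-factor fine-mapping when all factors share one causal.

    Per region, ``n_factors`` latent-factor phenotypes share a single causal
    variant (mid-region) with independent noise; each factor is fine-mapped
    alone and jointly.  Returns one row per region x factor with CS sizes and
    whether the true causal lies in each credible set.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    causal_idx = p // 2
    for r, region_ss in enumerate(root.spawn(n_regions)):
        ss = region_ss.spawn(n_factors + 1)
        G = simulate_genotypes(n, p, np.full(p, 0.3), rho=rho, seed=ss[0])
        ld = np.corrcoef(G.dosages, rowvar=False)
        regions = []
        for k in range(n_factors):
            rng = np.random.default_rng(ss[k + 1])
            f = _simulated_factor_region(G, causal_idx, effect, rng)
            regions.append(RegionData(gwas_ols(G, f, trait=f"F{k+1}"), ld, n=n))
        res = flashfm_zero_with_finemap(regions, kappa=kappa, cs_level=cs_level)
        causal_id = G.variant_ids[causal_idx]
        for k, (cs_s, cs_j) in enumerate(
            zip(res.credible_sets(adjusted=False), res.credible_sets(adjusted=True))
        ):
            rows.append(
                {
                    "region": r,
                    "factor": k,
                    "single_cs_size": cs_s.size,
                    "joint_cs_size": cs_j.size,
                    "causal_in_single": causal_id in cs_s.variant_ids,
                    "causal_in_joint": causal_id in cs_j.variant_ids,
                }
            )
    return pd.DataFrame(rows)


def single_causal_coverage_study(
    seed: int,
    n_reps: int = 200,
    p: int = 50,
    n: int = 10_000,
    rho: float = 0.9,
    effect: float = 0.09,
    cs_level: float = 0.99,
    panels: int = 10,
) -> pd.DataFrame:
    """CS99 coverage of the true causal in single-trait fine-mapping.

    ``panels`` genotype panels are drawn and reused across replicates (fixed
    LD, fresh phenotype noise), the usual fine-mapping simulation design.
    """
    root = np.random.SeedSequence(seed)
    panel_ss = root.spawn(panels)
    rep_ss = root.spawn(panels + 1)[-1].spawn(n_reps)
    Gs = [
        simulate_genotypes(n, p, np.full(p, 0.3), rho=rho, seed=s) for s in panel_ss
    ]
    lds = [np.corrcoef(G.dosages, rowvar=False) for G in Gs]
    causal_idx = p // 2
    rows = []
    for r, s in enumerate(rep_ss):
        G, ld = Gs[r % panels], lds[r % panels]
        rng = np.random.default_rng(s)
        f = _simulated_factor_region(G, causal_idx, effect, rng)
        mp = dynamic_cmax(RegionData(gwas_ols(G, f, trait="F1"), ld, n=n))
        cs = credible_set(mp, cs_level)
        rows.append(
            {
                "rep": r,
                "cs_size": cs.size,
                "covered": G.variant_ids[causal_idx] in cs.variant_ids,
                "cmax_used": mp.cmax_used,
            }
        )
    return pd.DataFrame(rows)


def null_calibration_study(
    seed: int,
    n_tests: int = 20_000,
    n: int = 1000,
    P: int = 6,
    K: int = 2,
    variants_per_rep: int = 500,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Latent-factor Z calibration under the global null.

    Simulates trait panels with no causal variants, derives latent-factor
    summary statistics through the full transform (fitted loadings, marginal
    trait covariance), and reports the mean of Z^2 and the fraction of
    two-sided p-values below ``alpha`` over ``n_tests`` variant-factor tests.
    """
    n_reps = int(np.ceil(n_tests / (variants_per_rep * K)))
    root = np.random.SeedSequence(seed)
    z2, reject, total = 0.0, 0, 0
    for rep_ss in root.spawn(n_reps):
        s = rep_ss.spawn(3)
        G = simulate_genotypes(n, variants_per_rep, np.full(variants_per_rep, 0.3),
                               rho=0.3, seed=s[0])
        L = _block_loading(P, K)
        Y, _ = simulate_factor_traits(G, L, {}, 1.0, 0.6, seed=s[1])
        Y = _standardize(Y)
        res = FactorModel.from_traits(Y).fit(n_factors=K, seed=s[2])
        tables = [gwas_ols(G, Y[c].to_numpy(), trait=c) for c in Y.columns]
        panel = harmonise(tables, min_maf=0.0, min_info=0.0)
        latent = latent_sumstats_from_traits(panel, res.loading_matrix, Y.cov())
        for k in range(K):
            z = latent[k].z()
            z2 += float(np.sum(z**2))
            reject += int(np.sum(latent[k].table["P"] < alpha))
            total += len(z)
    return {"z2_mean": z2 / total, "type_i_error": reject / total, "n_tests": total}


def factor_recovery_study(
    seed: int,
    n_seeds: int = 50,
    P: int = 12,
    K: int = 3,
    n_obs: int = 5000,
    communality: float = 0.6,
) -> float:
    """Fraction of replicates in which parallel analysis returns the planted K."""
    root = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in root.spawn(n_seeds):
        s = rep_ss.spawn(2)
        rng = np.random.default_rng(s[0])
        L = np.zeros((P, K))
        for i in range(P):
            L[i, i % K] = np.sqrt(communality)
        F = rng.standard_normal((n_obs, K))
        eps = rng.standard_normal((n_obs, P)) * np.sqrt(1 - communality)
        Y = F @ L.T + eps
        corr = np.corrcoef(Y, rowvar=False)
        hits += parallel_analysis(corr, n_obs, n_sims=20, seed=s[1]) == K
    return hits / n_seeds
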