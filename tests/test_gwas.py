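"""Trait GWAS, harmonisation, and the latent summary-statistics transform."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import kstest, spearmanr

from latentfm.factor import FactorModel, LoadingMatrix, factor_scores
from latentfm.gwas import (
    SumStats,
    gwas_ols,
    harmonise,
    latent_sumstats_from_traits,
    rank_inverse_normal,
)
from latentfm.simulate import simulate_factor_traits, simulate_genotypes

from conftest import make_sumstats


class TestRankInverseNormal:
    def test_three_values_match_quantile_function(self):
        out = rank_inverse_normal([10.0, 20.0, 30.0])
        expected = ndtri((np.array([1, 2, 3]) - 0.375) / 3.25)
        assert np.allclose(out, expected, atol=1e-12)
        assert out[1] == 0.0

    def test_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 1, 200)
        out = rank_inverse_normal(x)
        assert spearmanr(x, out).statistic == 1.0

    def test_ties_and_missing_preserved(self):
        out = rank_inverse_normal([1.0, np.nan, 2.0, 2.0, 5.0])
        assert np.isnan(out[1])
        assert out[2] == out[3]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            rank_inverse_normal([1.0, 2.0])


class TestGwasOls:
    def test_perfect_fit(self):
        G = simulate_genotypes(3, 1, [0.5], rho=0.0, seed=2)
        G.dosages[:, 0] = [0.0, 1.0, 2.0]
        ss = gwas_ols(G, np.array([0.0, 1.0, 2.0]))
        assert ss.table.loc[0, "BETA"] == pytest.approx(1.0)
        assert ss.table.loc[0, "SE"] == pytest.approx(0.0, abs=1e-12)

    def test_null_pvalues_uniform(self):
        G = simulate_genotypes(600, 500, np.full(500, 0.3), rho=0.0, seed=3)
        y = np.random.default_rng(4).standard_normal(600)
        ss = gwas_ols(G, y)
        assert kstest(ss.table["P"], "uniform").pvalue > 0.001

    def test_constant_dosage_skipped_and_logged(self):
        G = simulate_genotypes(50, 2, np.full(2, 0.3), rho=0.0, seed=5)
        G.dosages[:, 1] = 1.0
        ss = gwas_ols(G, np.random.default_rng(6).standard_normal(50))
        assert ss.table["SNPID"].tolist() == ["rs1"]
        assert ss.table.attrs["skipped"] == ["rs2"]

    def test_pairwise_complete_matches_masked_subset(self):
        G = simulate_genotypes(200, 3, np.full(3, 0.3), rho=0.0, seed=7)
        y = np.random.default_rng(8).standard_normal(200)
        y[:20] = np.nan
        G.dosages[10:30, 1] = np.nan
        ss = gwas_ols(G, y)
        keep = np.isfinite(y) & np.isfinite(G.dosages[:, 1])
        x, yy = G.dosages[keep, 1], y[keep]
        beta_ref = np.polyfit(x, yy, 1)[0]
        row = ss.table.set_index("SNPID").loc["rs2"]
        assert row["BETA"] == pytest.approx(beta_ref, rel=1e-10)
        assert row["N"] == keep.sum()


def _table(ids, ea, oa, beta, eaf=0.3, info=1.0, n=1000, trait="t"):
    p = len(ids)
    tab = pd.DataFrame(
        {
            "SNPID": ids,
            "CHR": "1",
            "BP": np.arange(p) + 1,
            "EA": ea,
            "OA": oa,
            "EAF": eaf,
            "BETA": beta,
            "SE": 0.05,
            "P": 0.5,
            "INFO": info,
            "N": n,
        }
    )
    return SumStats(tab, trait)


class TestHarmonise:
    def test_allele_swap_flips_beta_and_eaf(self):
        a = _table(["v1"], "A", "G", [0.2], eaf=0.3, trait="t1")
        b = _table(["v1"], "G", "A", [-0.2], eaf=0.7, trait="t2")
        panel = harmonise([a, b], min_maf=0.0, min_info=0.0)
        assert panel.beta.loc["v1", "t1"] == pytest.approx(0.2)
        assert panel.beta.loc["v1", "t2"] == pytest.approx(0.2)

    def test_min_maf_removal(self):
        a = _table(["v1", "v2"], "A", "G", [0.1, 0.1], eaf=[0.004, 0.3], trait="t1")
        panel = harmonise([a], min_maf=0.005, min_info=0.0)
        assert panel.variant_ids == ["v2"]
        assert panel.filter_log["below_min_maf"] == 1

    def test_min_info_removal(self):
        a = _table(["v1", "v2"], "A", "G", [0.1, 0.1], info=[0.39, 0.8], trait="t1")
        panel = harmonise([a], min_maf=0.0, min_info=0.4)
        assert panel.variant_ids == ["v2"]

    def test_intersection_rule(self):
        a = _table(["v1", "v2"], "A", "G", [0.1, 0.2], trait="t1")
        b = _table(["v1"], "A", "G", [0.3], trait="t2")
        c = _table(["v1", "v2"], "A", "G", [0.4, 0.5], trait="t3")
        panel = harmonise([a, b, c], min_maf=0.0, min_info=0.0)
        assert panel.variant_ids == ["v1"]

    def test_allele_mismatch_dropped(self):
        a = _table(["v1", "v2"], "A", "G", [0.1, 0.2], trait="t1")
        b = _table(["v1", "v2"], ["A", "C"], ["G", "T"], [0.3, 0.4], trait="t2")
        panel = harmonise([a, b], min_maf=0.0, min_info=0.0)
        assert panel.variant_ids == ["v1"]
        assert panel.filter_log["allele_mismatch"] == 1

    def test_empty_intersection_raises_with_counts(self):
        a = _table(["v1"], "A", "G", [0.1], eaf=0.001, trait="t1")
        with pytest.raises(ValueError, match="empty variant intersection"):
            harmonise([a], min_maf=0.005, min_info=0.0)

    def test_idempotence(self):
        a = _table(["v1", "v2", "v3"], "A", "G", [0.1, 0.2, 0.3], trait="t1")
        b = _table(["v1", "v2", "v3"], "G", "A", [0.1, -0.2, 0.3], eaf=0.7, trait="t2")
        panel = harmonise([a, b], min_maf=0.0, min_info=0.0)
        again = harmonise(panel.to_sumstats(), min_maf=0.0, min_info=0.0)
        pd.testing.assert_frame_equal(panel.beta, again.beta)
        pd.testing.assert_frame_equal(panel.se, again.se)

    def test_strand_ambiguous_flag(self):
        a = _table(["v1", "v2"], ["A", "A"], ["T", "G"], [0.1, 0.2], trait="t1")
        panel = harmonise([a], min_maf=0.0, min_info=0.0, drop_ambiguous=True)
        assert panel.variant_ids == ["v2"]


def _loading_frame(P, K, value=0.8):
    L = np.zeros((P, K))
    for i in range(P):
        L[i, i % K] = value
    idx = [f"T{i+1}" for i in range(P)]
    return LoadingMatrix(
        loadings=pd.DataFrame(L, index=idx, columns=[f"ML{k+1}" for k in range(K)]),
        uniquenesses=pd.Series(1 - value**2, index=idx),
    )


def _cohort(n=800, P=6, K=2, V=100, seed=0, effect=0.25):
    G = simulate_genotypes(n, V, np.full(V, 0.3), rho=0.5, seed=seed)
    Ldf = pd.DataFrame(
        _loading_frame(P, K).values,
        index=[f"T{i+1}" for i in range(P)],
        columns=[f"F{k+1}" for k in range(K)],
    )
    causal = {"F1": {"rs10": effect}}
    Y, truth = simulate_factor_traits(G, Ldf, causal, 1.0, 0.6, seed=seed + 1)
    Ystd = (Y - Y.mean()) / Y.std()
    return G, Ystd, truth


class TestLatentSumStats:
    def test_single_trait_identity(self):
        lm = LoadingMatrix(
            loadings=pd.DataFrame([[1.0]], index=["T1"], columns=["ML1"]),
            uniquenesses=pd.Series([0.0], index=["T1"]),
        )
        a = _table(["v1", "v2"], "A", "G", [0.1, -0.2], trait="T1")
        panel = harmonise([a], min_maf=0.0, min_info=0.0)
        latent = latent_sumstats_from_traits(panel, lm, np.array([[1.0]]))
        assert np.allclose(latent[0].table["BETA"], [0.1, -0.2])
        assert np.allclose(latent[0].table["SE"], 0.05)

    def test_orthonormal_loadings_reduce_to_projection(self):
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        lm = LoadingMatrix(
            loadings=pd.DataFrame(Q, index=[f"T{i+1}" for i in range(4)],
                                  columns=["ML1", "ML2"]),
            uniquenesses=pd.Series(0.5, index=[f"T{i+1}" for i in range(4)]),
        )
        tables = [
            _table(["v1", "v2"], "A", "G", rng.normal(0, 0.1, 2), trait=f"T{i+1}")
            for i in range(4)
        ]
        panel = harmonise(tables, min_maf=0.0, min_info=0.0)
        latent = latent_sumstats_from_traits(panel, lm, np.eye(4))
        expected = panel.beta.to_numpy() @ Q
        got = np.column_stack([latent[k].table["BETA"] for k in range(2)])
        assert np.allclose(got, expected, atol=1e-12)

    def test_equivalence_with_individual_level_scores(self):
        """Summary-stat path betas equal OLS on factor scores exactly."""
        G, Y, _ = _cohort()
        res = FactorModel.from_traits(Y).fit(n_factors=2)
        tables = [gwas_ols(G, Y[c].to_numpy(), trait=c) for c in Y.columns]
        panel = harmonise(tables, min_maf=0.0, min_info=0.0)
        latent = latent_sumstats_from_traits(panel, res.loading_matrix, Y.cov())
        F = res.scores(Y)
        for k, fname in enumerate(res.loading_matrix.factor_names):
            direct = gwas_ols(G, F[fname].to_numpy(), trait=fname)
            b1 = latent[k].table.set_index("SNPID")["BETA"]
            b2 = direct.table.set_index("SNPID")["BETA"]
            assert np.max(np.abs(b1 - b2)) < 1e-10
            s1 = latent[k].table.set_index("SNPID")["SE"]
            s2 = direct.table.set_index("SNPID")["SE"]
            assert np.max(np.abs(s1 / s2 - 1)) < 0.02

    def test_sign_equivariance(self):
        G, Y, _ = _cohort(seed=30)
        res = FactorModel.from_traits(Y).fit(n_factors=2)
        tables = [gwas_ols(G, Y[c].to_numpy(), trait=c) for c in Y.columns]
        panel = harmonise(tables, min_maf=0.0, min_info=0.0)
        base = latent_sumstats_from_traits(panel, res.loading_matrix, Y.cov())

        flipped_panel = harmonise(tables, min_maf=0.0, min_info=0.0)
        flip_trait = flipped_panel.trait_names[0]
        flipped_panel.beta[flip_trait] = -flipped_panel.beta[flip_trait]
        lm = res.loading_matrix
        flipped_load = lm.loadings.copy()
        flipped_load.loc[flip_trait] = -flipped_load.loc[flip_trait]
        cov = Y.cov()  # marginal covariance unchanged by a sign flip of one trait
        cov2 = cov.copy()
        cov2.loc[flip_trait, :] *= -1
        cov2.loc[:, flip_trait] *= -1
        flipped_lm = LoadingMatrix(loadings=flipped_load, uniquenesses=lm.uniquenesses)
        out = latent_sumstats_from_traits(flipped_panel, flipped_lm, cov2)
        for k in range(2):
            assert np.allclose(
                out[k].table["BETA"], base[k].table["BETA"], atol=1e-12
            )
            assert np.allclose(out[k].table["SE"], base[k].table["SE"], atol=1e-12)

    def test_trait_order_mismatch_rejected(self):
        G, Y, _ = _cohort(seed=40)
        res = FactorModel.from_traits(Y).fit(n_factors=2)
        tables = [gwas_ols(G, Y[c].to_numpy(), trait=c) for c in reversed(Y.columns)]
        panel = harmonise(tables, min_maf=0.0, min_info=0.0)
        with pytest.raises(ValueError, match="trait order"):
            latent_sumstats_from_traits(panel, res.loading_matrix, Y.cov())

    def test_nonunit_cov_diagonal_warns(self):
        lm = LoadingMatrix(
            loadings=pd.DataFrame([[1.0]], index=["T1"], columns=["ML1"]),
            uniquenesses=pd.Series([0.0], index=["T1"]),
        )
        a = _table(["v1"], "A", "G", [0.1], trait="T1")
        panel = harmonise([a], min_maf=0.0, min_info=0.0)
        with pytest.warns(UserWarning, match="standardized"):
            latent_sumstats_from_traits(panel, lm, np.array([[4.0]]))
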