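"""Factor machinery: parallel analysis, ML fit, varimax, scores, contributions."""

import numpy as np
import pandas as pd
import pytest

from latentfm.factor import (
    FactorModel,
    LoadingMatrix,
    _profile_objective,
    factor_contributions,
    factor_scores,
    fit_ml_factors,
    ml_degrees_of_freedom,
    parallel_analysis,
    varimax,
)
from latentfm.simulate import simulate_factor_traits, simulate_genotypes


def _simple_structure(P=12, K=3, rng=None):
    """One dominant loading per trait, grouped by factor."""
    rng = rng or np.random.default_rng(0)
    L = np.zeros((P, K))
    for i in range(P):
        L[i, i % K] = rng.uniform(0.6, 0.9) * rng.choice([-1, 1])
    return L


def _as_loading(L):
    P, K = L.shape
    return LoadingMatrix(
        loadings=pd.DataFrame(L, index=[f"T{i+1}" for i in range(P)],
                              columns=[f"ML{k+1}" for k in range(K)]),
        uniquenesses=pd.Series(1 - (L**2).sum(axis=1), index=[f"T{i+1}" for i in range(P)]),
    )


def _planted_corr(L, psi=None):
    P = L.shape[0]
    psi = 1 - (L**2).sum(axis=1) if psi is None else psi
    return L @ L.T + np.diag(psi)


class TestParallelAnalysis:
    def test_identity_correlation_gives_zero_factors(self):
        assert parallel_analysis(np.eye(10), n_obs=500, seed=1) == 0

    def test_two_strongly_correlated_traits_give_one_factor(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert parallel_analysis(corr, n_obs=1000, seed=2) == 1

    def test_planted_three_factor_structure_recovered(self):
        L = _simple_structure(P=12, K=3, rng=np.random.default_rng(3))
        corr = _planted_corr(L)
        assert parallel_analysis(corr, n_obs=5000, seed=4) == 3

    def test_monotone_in_generating_factors(self):
        rng = np.random.default_rng(5)
        ks = []
        for K in (1, 2, 3):
            L = _simple_structure(P=12, K=K, rng=rng)
            ks.append(parallel_analysis(_planted_corr(L), n_obs=5000, seed=6))
        assert ks == sorted(ks)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            parallel_analysis(np.array([[1.0, 0.5], [0.2, 1.0]]), n_obs=100)
        with pytest.raises(ValueError):
            parallel_analysis(np.eye(3), n_obs=2)


class TestMLFactors:
    def test_identity_correlation_gives_null_loadings(self):
        fit = fit_ml_factors(np.eye(6), K=1)
        assert np.max(np.abs(fit.values)) < 1e-4
        assert np.all(fit.uniquenesses > 0.99)

    def test_exact_model_recovery(self):
        L = _simple_structure(P=8, K=2, rng=np.random.default_rng(7))
        corr = _planted_corr(L)
        fit = fit_ml_factors(corr, K=2)
        true_comm = (L**2).sum(axis=1)
        assert np.max(np.abs(fit.communalities().to_numpy() - true_comm)) < 1e-4
        sigma = fit.values @ fit.values.T + np.diag(fit.uniquenesses.to_numpy())
        resid = sigma - corr
        np.fill_diagonal(resid, 0.0)
        assert np.max(np.abs(resid)) < 1e-6

    def test_discrepancy_is_optimal_against_perturbations(self):
        L = _simple_structure(P=8, K=2, rng=np.random.default_rng(8))
        corr = _planted_corr(L)
        fit = fit_ml_factors(corr, K=2)
        rng = np.random.default_rng(9)
        log_psi_opt = np.log(fit.uniquenesses.to_numpy())
        best = _profile_objective(log_psi_opt, corr, 2)
        for _ in range(100):
            trial = _profile_objective(
                np.clip(log_psi_opt + rng.normal(0, 0.3, 8), np.log(0.005), 0.0),
                corr, 2,
            )
            assert trial >= best - 1e-9

    def test_objective_history_non_increasing(self):
        L = _simple_structure(P=10, K=2, rng=np.random.default_rng(10))
        fit = fit_ml_factors(_planted_corr(L), K=2)
        hist = np.array(fit.history)
        assert len(hist) >= 1 and hist[-1] <= hist[0] + 1e-12

    def test_identifiability_guard(self):
        assert ml_degrees_of_freedom(5, 3) < 0
        with pytest.raises(ValueError):
            fit_ml_factors(np.eye(5), K=3)


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.abs(_simple_structure(P=9, K=3, rng=np.random.default_rng(11)))
        rotated = varimax(_as_loading(L))
        # equal up to column permutation/sign
        cost = np.abs(rotated.values.T @ L)
        matched = sorted(np.argmax(cost, axis=1))
        assert matched == [0, 1, 2]
        for k in range(3):
            j = np.argmax(np.abs(rotated.values.T @ L)[k])
            col = rotated.values[:, k] * np.sign(rotated.values[:, k] @ L[:, j])
            assert np.max(np.abs(col - L[:, j])) < 1e-8

    def test_recovers_randomly_rotated_simple_structure(self):
        rng = np.random.default_rng(12)
        L = _simple_structure(P=12, K=3, rng=rng)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        mixed = L @ Q
        rec = varimax(_as_loading(mixed)).values
        for k in range(3):
            j = int(np.argmax(np.abs(rec.T @ L)[k]))
            col = rec[:, k] * np.sign(rec[:, k] @ L[:, j])
            assert np.max(np.abs(col - L[:, j])) < 1e-6

    def test_preserves_communalities_and_llt(self):
        rng = np.random.default_rng(13)
        L = rng.normal(0, 0.4, (10, 3))
        lm = _as_loading(L)
        rot = varimax(lm)
        comm_before = (L**2).sum(axis=1)
        comm_after = rot.communalities().to_numpy()
        assert np.max(np.abs(comm_before - comm_after)) < 1e-10
        assert np.max(np.abs(rot.values @ rot.values.T - L @ L.T)) < 1e-8

    def test_single_factor_returned_unchanged(self):
        L = _as_loading(np.array([[0.5], [-0.7], [0.2]]))
        assert varimax(L) is L

    def test_column_conventions(self):
        rng = np.random.default_rng(14)
        L = rng.normal(0, 0.4, (10, 3))
        rot = varimax(_as_loading(L)).values
        ss = (rot**2).sum(axis=0)
        assert np.all(np.diff(ss) <= 1e-12)
        for k in range(3):
            assert rot[np.argmax(np.abs(rot[:, k])), k] > 0


class TestFactorScores:
    def test_noiseless_scores_recovered_exactly(self):
        rng = np.random.default_rng(15)
        L = _simple_structure(P=6, K=2, rng=rng)
        F = rng.standard_normal((50, 2))
        Y = pd.DataFrame(F @ L.T, columns=[f"T{i+1}" for i in range(6)])
        scores = factor_scores(Y, _as_loading(L))
        assert np.allclose(scores.to_numpy(), F - F.mean(axis=0), atol=1e-10)

    def test_orthonormal_loadings_shortcut(self):
        rng = np.random.default_rng(16)
        Q, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        Y = pd.DataFrame(rng.standard_normal((40, 6)), columns=[f"T{i+1}" for i in range(6)])
        lm = _as_loading(Q * 0.999)  # keep communality < 1
        scores = factor_scores(Y, lm)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        expected = np.linalg.solve((0.999 * Q).T @ (0.999 * Q), (0.999 * Q).T @ Yc.T).T
        assert np.allclose(scores.to_numpy(), expected, atol=1e-12)
        assert np.max(np.abs(scores.mean(axis=0))) < 1e-8

    def test_missing_data_rejected_with_guidance(self):
        Y = pd.DataFrame(np.ones((5, 2)), columns=["T1", "T2"])
        Y.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="summary-statistics"):
            factor_scores(Y, _as_loading(np.array([[0.7, 0.0], [0.0, 0.7]])))

    def test_scores_track_truth_on_simulated_cohort(self):
        rng = np.random.default_rng(17)
        P, K, n = 20, 4, 2000
        L = np.zeros((P, K))
        for i in range(P):
            L[i, i % K] = np.sqrt(0.7)
        Ldf = pd.DataFrame(L, index=[f"T{i+1}" for i in range(P)],
                           columns=[f"F{k+1}" for k in range(K)])
        G = simulate_genotypes(n, 2, np.full(2, 0.3), rho=0.0, seed=18)
        Y, truth = simulate_factor_traits(G, Ldf, {}, 1.0, np.sqrt(0.3), seed=19)
        model = FactorModel.from_traits(Y)
        res = model.fit(n_factors=K)
        scores = res.scores(Y)
        F = truth.factor_scores.to_numpy()
        best = np.abs(np.corrcoef(scores.to_numpy().T, F.T)[:K, K:]).max(axis=1)
        assert np.all(best > 0.9)

    def test_scores_uncorrelated_under_orthogonal_model(self):
        rng = np.random.default_rng(20)
        P, K, n = 12, 3, 10_000
        L = _simple_structure(P, K, rng=rng)
        F = rng.standard_normal((n, K))
        Y = pd.DataFrame(
            F @ L.T + rng.standard_normal((n, P)) * 0.5,
            columns=[f"T{i+1}" for i in range(P)],
        )
        fit = varimax(fit_ml_factors(Y.corr().to_numpy(), K=K,
                                     trait_names=list(Y.columns)))
        corr = np.corrcoef(factor_scores(Y, fit).to_numpy(), rowvar=False)
        off = corr[np.triu_indices(K, 1)]
        assert np.max(np.abs(off)) < 0.05


class TestContributions:
    def test_hand_computed_row(self):
        L = _as_loading(np.array([[0.6, 0.3], [0.0, 0.5]]))
        C = factor_contributions(L).contributions.to_numpy()
        assert np.allclose(C[0], [0.8, 0.2], atol=1e-12)
        assert np.allclose(C[1], [0.0, 1.0], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(21)
        L = _as_loading(rng.normal(0, 0.4, (15, 4)))
        C = factor_contributions(L).contributions
        assert np.allclose(C.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_flagged_with_warning(self):
        L = _as_loading(np.array([[0.7, 0.0], [0.0, 0.0], [0.0, 0.6]]))
        with pytest.warns(UserWarning):
            cm = factor_contributions(L)
        assert cm.zero_rows == ["T2"]
        assert np.allclose(cm.contributions.loc["T2"], 0.0)

    def test_trait_order_groups_by_top_factor(self):
        L = _as_loading(np.array([[0.2, 0.7], [0.8, 0.1], [0.1, 0.9]]))
        cm = factor_contributions(L)
        assert cm.trait_order == ["T2", "T3", "T1"]


def test_model_results_summary_and_sklearn_crosscheck():
    """Loading subspace agrees with an independent EM-based factor fit."""
    from sklearn.decomposition import FactorAnalysis as SkFA

    rng = np.random.default_rng(22)
    L = _simple_structure(P=10, K=2, rng=rng)
    F = rng.standard_normal((5000, 2))
    Y = F @ L.T + rng.standard_normal((5000, 10)) * np.sqrt(
        np.clip(1 - (L**2).sum(axis=1), 0.05, None)
    )
    Y = (Y - Y.mean(0)) / Y.std(0)
    Ydf = pd.DataFrame(Y, columns=[f"T{i+1}" for i in range(10)])
    res = FactorModel.from_traits(Ydf).fit(n_factors=2)
    sk = SkFA(n_components=2, random_state=0).fit(Y)
    ours = res.loadings.to_numpy()
    theirs = sk.components_.T
    # compare the spanned subspaces via projection operators
    def proj(M):
        q, _ = np.linalg.qr(M)
        return q @ q.T
    assert np.max(np.abs(proj(ours) - proj(theirs))) < 0.05
    text = res.summary()
    assert "factors: 2" in text and "ML1" in text
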