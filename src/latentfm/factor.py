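"""Latent factor analysis: Horn's parallel analysis, ML loadings, varimax, scores.

The factor model for P traits and K < P factors is Y = M + L F + eps with
orthogonal factor scores F and independent errors.  On a correlation matrix S
the ML estimate minimizes the discrepancy

    D(L, Psi) = log|Sigma| + tr(S Sigma^-1) - log|S| - P,   Sigma = L L' + Psi,

profiled over L: for fixed uniquenesses Psi the optimal loadings come from the
top-K eigenpairs of Psi^{-1/2} S Psi^{-1/2}, leaving a smooth objective in Psi
alone which we minimize by quasi-Newton on log-uniquenesses.

Varimax rotation keeps factors orthogonal (hence uncorrelated scores) while
driving loadings toward simple structure; scaled squared loadings
C_ij = L_ij^2 / sum_k L_ik^2 express each factor's contribution to each trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "LoadingMatrix",
    "ContributionMatrix",
    "parallel_analysis",
    "fit_ml_factors",
    "varimax",
    "factor_scores",
    "factor_contributions",
    "pairwise_complete_corr",
    "FactorModel",
    "FactorResults",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LoadingMatrix:
    """P x K factor loadings with per-trait uniquenesses."""

    loadings: pd.DataFrame  # traits x factors
    uniquenesses: pd.Series
    discrepancy: float | None = None
    n_iter: int | None = None
    history: list = field(default_factory=list, repr=False)

    @property
    def trait_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def values(self) -> np.ndarray:
        return self.loadings.to_numpy()

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


@dataclass
class ContributionMatrix:
    """Row-normalized squared loadings C_ij with the loading signs."""

    contributions: pd.DataFrame
    signs: pd.DataFrame
    trait_order: list[str]
    zero_rows: list[str]


def _check_corr(corr: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=tol):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    return 0.5 * (corr + corr.T)


def parallel_analysis(
    corr,
    n_obs: int,
    n_sims: int = 20,
    seed=0,
    rule: str = "mean",
) -> int:
    """Horn's parallel analysis: number of factors supported by the data.

    Compares the ordered eigenvalues of ``corr`` with the mean (or a quantile,
    via ``rule='q95'``) of eigenvalues from ``n_sims`` simulated P x n_obs
    standard-normal datasets; returns the length of the leading run of
    observed eigenvalues strictly exceeding their simulated counterpart.
    """
    corr = _check_corr(np.asarray(corr, float))
    if n_obs < 3:
        raise ValueError("n_obs must be at least 3")
    P = corr.shape[0]
    rng = np.random.default_rng(seed)
    obs = np.sort(np.linalg.eigvalsh(corr))[::-1]
    sims = np.empty((n_sims, P))
    for s in range(n_sims):
        data = rng.standard_normal((n_obs, P))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(data, rowvar=False)))[::-1]
    if rule == "mean":
        ref = sims.mean(axis=0)
    elif rule == "q95":
        ref = np.quantile(sims, 0.95, axis=0)
    else:
        raise ValueError("rule must be 'mean' or 'q95'")
    k = 0
    while k < P and obs[k] > ref[k]:
        k += 1
    return k


def _profile_objective(log_psi: np.ndarray, S: np.ndarray, K: int) -> float:
    psi = np.exp(log_psi)
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    vals = np.linalg.eigvalsh(Sstar)[::-1]
    tail = np.clip(vals[K:], 1e-12, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _profile_gradient(log_psi: np.ndarray, S: np.ndarray, K: int) -> np.ndarray:
    psi = np.exp(log_psi)
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    vals, vecs = np.linalg.eigh(Sstar)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    top = np.clip(vals[:K] - 1.0, 0.0, None)
    load = np.sqrt(psi)[:, None] * vecs[:, :K] * np.sqrt(top)
    resid = load @ load.T + np.diag(psi) - S
    dpsi = np.diag(resid) / psi**2
    return dpsi * psi  # chain rule d/dlog psi


def _loadings_given_psi(S: np.ndarray, psi: np.ndarray, K: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    vals, vecs = np.linalg.eigh(Sstar)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    top = np.clip(vals[:K] - 1.0, 0.0, None)
    return np.sqrt(psi)[:, None] * vecs[:, :K] * np.sqrt(top)


def ml_degrees_of_freedom(P: int, K: int) -> float:
    return ((P - K) ** 2 - P - K) / 2


def fit_ml_factors(
    corr,
    K: int,
    n_obs: int | None = None,
    floor: float = 0.005,
    tol: float = 1e-8,
    max_iter: int = 1000,
    trait_names=None,
) -> LoadingMatrix:
    """Maximum-likelihood factor analysis of a correlation matrix (unrotated).

    ``floor`` bounds the uniquenesses away from zero to contain Heywood
    cases.  Raises :class:`ConvergenceError` if the optimizer fails, reporting
    the final gradient norm.
    """
    S = _check_corr(np.asarray(corr, float))
    P = S.shape[0]
    if not 1 <= K < P:
        raise ValueError("K must satisfy 1 <= K < P")
    if ml_degrees_of_freedom(P, K) < 0:
        raise ValueError(f"K={K} is not identifiable for P={P} traits")
    if trait_names is None:
        trait_names = (
            list(corr.index) if isinstance(corr, pd.DataFrame) else [f"T{i+1}" for i in range(P)]
        )

    try:
        psi0 = 1.0 / np.diag(np.linalg.inv(S))
    except np.linalg.LinAlgError:
        psi0 = np.full(P, 0.5)
    psi0 = np.clip(psi0, max(floor, 1e-3), 1.0)

    history: list[float] = []

    def cb(xk):
        history.append(_profile_objective(xk, S, K))

    res = minimize(
        _profile_objective,
        np.log(psi0),
        args=(S, K),
        jac=_profile_gradient,
        method="L-BFGS-B",
        bounds=[(np.log(floor), 0.0)] * P,
        callback=cb,
        options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-10},
    )
    grad_norm = float(np.linalg.norm(_profile_gradient(res.x, S, K)))
    if not res.success and grad_norm > 1e-4:
        raise ConvergenceError(
            f"ML factor analysis did not converge in {max_iter} iterations "
            f"(final gradient norm {grad_norm:.3e}): {res.message}"
        )
    psi = np.exp(res.x)
    load = _loadings_given_psi(S, psi, K)

    Sigma = load @ load.T + np.diag(psi)
    sign_det, logdet_Sigma = np.linalg.slogdet(Sigma)
    sign_S, logdet_S = np.linalg.slogdet(S)
    disc = float(logdet_Sigma + np.trace(np.linalg.solve(Sigma, S)) - logdet_S - P)

    loadings = pd.DataFrame(load, index=trait_names, columns=[f"ML{k+1}" for k in range(K)])
    return LoadingMatrix(
        loadings=loadings,
        uniquenesses=pd.Series(psi, index=trait_names),
        discrepancy=disc,
        n_iter=int(res.nit),
        history=history,
    )


def _canonical_columns(load: np.ndarray) -> np.ndarray:
    """Sign-fix (largest-|loading| entry positive) and order by SS loadings."""
    load = load.copy()
    for k in range(load.shape[1]):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] = -load[:, k]
    ss = (load**2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    return load[:, order]


def varimax(
    L: LoadingMatrix,
    tol: float = 1e-10,
    kaiser_normalize: bool = True,
    max_iter: int = 1000,
) -> LoadingMatrix:
    """Varimax rotation of a loading matrix (orthogonal; preserves LL').

    Maximizes sum_k [ sum_i l_ik^4 - (sum_i l_ik^2)^2 / P ] over orthogonal
    rotations, with optional Kaiser row-normalization.  Columns of the result
    are sign-fixed (largest-magnitude loading positive) and ordered by
    decreasing sum of squared loadings.  K = 1 inputs are returned unchanged.
    """
    A = L.values
    P, K = A.shape
    if K < 2:
        return L

    if kaiser_normalize:
        h = np.sqrt((A**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        X = A / h[:, None]
    else:
        h = None
        X = A.copy()

    R = np.eye(K)
    d = 0.0
    for _ in range(max_iter):
        Z = X @ R
        B = X.T @ (Z**3 - Z * (Z**2).sum(axis=0) / P)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        d_new = s.sum()
        if d_new < d * (1 + tol) and d > 0:
            break
        d = d_new
    if not np.allclose(R.T @ R, np.eye(K), atol=1e-8):
        raise ConvergenceError("varimax rotation matrix is not orthogonal")

    rotated = (X @ R) * (h[:, None] if h is not None else 1.0)
    rotated = _canonical_columns(rotated)
    loadings = pd.DataFrame(rotated, index=L.trait_names, columns=[f"ML{k+1}" for k in range(K)])
    return LoadingMatrix(
        loadings=loadings,
        uniquenesses=L.uniquenesses.copy(),
        discrepancy=L.discrepancy,
        n_iter=L.n_iter,
    )


def factor_scores(Y: pd.DataFrame, L: LoadingMatrix) -> pd.DataFrame:
    """Least-squares factor scores F = (L'L)^-1 L'(Y - Ybar).

    Requires complete trait data; with missingness, derive latent summary
    statistics from the observed-trait GWAS instead (see
    :func:`latentfm.gwas.latent_sumstats_from_traits`).
    """
    if not isinstance(Y, pd.DataFrame):
        Y = pd.DataFrame(Y, columns=L.trait_names)
    if Y.isna().any().any():
        raise ValueError(
            "factor scores require complete trait data; use the "
            "summary-statistics path for incomplete cohorts"
        )
    if list(Y.columns) != L.trait_names:
        Y = Y[L.trait_names]
    A = L.values
    gram = A.T @ A
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("L'L is singular; loadings are rank-deficient")
    Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
    scores = np.linalg.solve(gram, A.T @ Yc.T).T
    return pd.DataFrame(scores, index=Y.index, columns=L.factor_names)


def factor_contributions(L: LoadingMatrix) -> ContributionMatrix:
    """Scaled loadings C_ij = L_ij^2 / sum_k L_ik^2 plus loading signs.

    Also orders traits by their maximum-contributing factor (grouped by
    factor, by decreasing contribution within group).  All-zero loading rows
    yield an all-zero contribution row and a warning.
    """
    A = L.values
    sq = A**2
    row = sq.sum(axis=1)
    zero_rows = [t for t, r in zip(L.trait_names, row) if r == 0]
    if zero_rows:
        warnings.warn(f"all-zero loading rows: {zero_rows}", stacklevel=2)
    denom = np.where(row > 0, row, 1.0)
    C = sq / denom[:, None]
    C[row == 0] = 0.0
    contributions = pd.DataFrame(C, index=L.trait_names, columns=L.factor_names)
    signs = pd.DataFrame(
        np.where(A >= 0, 1, -1), index=L.trait_names, columns=L.factor_names
    )

    top = contributions.to_numpy().argmax(axis=1)
    order = sorted(
        range(len(L.trait_names)),
        key=lambda i: (top[i], -contributions.iloc[i, top[i]]),
    )
    trait_order = [L.trait_names[i] for i in order]
    return ContributionMatrix(contributions, signs, trait_order, zero_rows)


def pairwise_complete_corr(Y: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Pairwise-complete Pearson correlations and the median pair count."""
    corr = Y.corr(method="pearson", min_periods=2)
    notna = Y.notna().to_numpy().astype(int)
    counts = notna.T @ notna
    iu = np.triu_indices_from(counts, k=1)
    median_n = int(np.median(counts[iu])) if iu[0].size else int(counts[0, 0])
    return corr, median_n


class FactorModel:
    """Latent factor model of a trait panel, statsmodels-style.

    Construct from a correlation matrix (plus ``n_obs``) or from an
    individual-level trait DataFrame via :meth:`from_traits` (pairwise-complete
    correlations; ``n_obs`` defaults to the median pairwise-complete count).
    ``fit`` chooses K by Horn's parallel analysis when not given, runs ML
    factor analysis and varimax, and returns a :class:`FactorResults`.
    """

    def __init__(self, corr, n_obs: int, trait_names=None):
        if isinstance(corr, pd.DataFrame):
            trait_names = list(corr.index)
            corr = corr.to_numpy()
        self.corr = _check_corr(np.asarray(corr, float))
        self.n_obs = int(n_obs)
        P = self.corr.shape[0]
        self.trait_names = list(trait_names) if trait_names is not None else [
            f"T{i+1}" for i in range(P)
        ]
        self._traits: pd.DataFrame | None = None

    @classmethod
    def from_traits(cls, Y: pd.DataFrame, n_obs: int | None = None) -> "FactorModel":
        corr, median_n = pairwise_complete_corr(Y)
        model = cls(corr, n_obs if n_obs is not None else median_n)
        model._traits = Y
        return model

    def select_n_factors(self, n_sims: int = 20, seed=0) -> int:
        return parallel_analysis(self.corr, self.n_obs, n_sims=n_sims, seed=seed)

    def fit(
        self,
        n_factors: int | None = None,
        rotate: str = "varimax",
        n_sims: int = 20,
        seed=0,
        **ml_kwargs,
    ) -> "FactorResults":
        if n_factors is None:
            n_factors = self.select_n_factors(n_sims=n_sims, seed=seed)
            if n_factors < 1:
                raise ValueError("parallel analysis found no common factors")
        fit = fit_ml_factors(self.corr, n_factors, self.n_obs,
                             trait_names=self.trait_names, **ml_kwargs)
        if rotate == "varimax":
            fit = varimax(fit)
        elif rotate not in (None, "none"):
            raise ValueError("rotate must be 'varimax' or None")
        return FactorResults(self, fit)


class FactorResults:
    """Fitted factor model: loadings, uniquenesses, contributions, scores."""

    def __init__(self, model: FactorModel, fit: LoadingMatrix):
        self.model = model
        self.loading_matrix = fit
        self.loadings = fit.loadings
        self.uniquenesses = fit.uniquenesses
        self.discrepancy = fit.discrepancy
        self._contrib: ContributionMatrix | None = None

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def contributions(self) -> ContributionMatrix:
        if self._contrib is None:
            self._contrib = factor_contributions(self.loading_matrix)
        return self._contrib

    def scores(self, Y: pd.DataFrame | None = None) -> pd.DataFrame:
        if Y is None:
            Y = self.model._traits
        if Y is None:
            raise ValueError("no trait data attached; pass Y explicitly")
        return factor_scores(Y, self.loading_matrix)

    def summary(self) -> str:
        comm = self.loading_matrix.communalities()
        lines = [
            "Latent factor model (maximum likelihood, varimax)",
            f"  traits: {len(self.model.trait_names)}   factors: {self.n_factors}"
            f"   n_obs: {self.model.n_obs}",
            f"  discrepancy: {self.discrepancy:.6g}",
            f"  communality range: [{comm.min():.3f}, {comm.max():.3f}]",
            "",
            self.loadings.round(3).to_string(),
        ]
        return "\n".join(lines)
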