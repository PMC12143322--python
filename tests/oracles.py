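"""Independent reference implementations used as test oracles.

Everything here is deliberately written along a different code path from the
package: explicit loops, scipy density calls, and exhaustive enumeration
instead of the package's vectorized conjugate algebra.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.special import ndtri
from scipy.stats import multivariate_normal


def mc_adjacent_dosage_corr(maf: float, rho: float, ndraws: int, seed: int) -> float:
    """Monte-Carlo adjacent-variant dosage correlation for the thresholding scheme."""
    rng = np.random.default_rng(seed)
    thr = ndtri(maf)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    d = np.zeros((ndraws, 2))
    for _ in range(2):
        z = rng.standard_normal((ndraws, 2)) @ chol.T
        d += z < thr
    return float(np.corrcoef(d[:, 0], d[:, 1])[0, 1])


def naive_model_logbf(z: np.ndarray, R: np.ndarray, se: np.ndarray,
                      model: tuple[int, ...], prior_var: float) -> float:
    """log BF via explicit multivariate-normal densities (no conjugate algebra)."""
    if not model:
        return 0.0
    idx = list(model)
    zg, Rg = z[idx], R[np.ix_(idx, idx)]
    phi = np.diag(prior_var / se[idx] ** 2)
    alt = multivariate_normal.logpdf(zg, mean=np.zeros(len(idx)), cov=Rg + Rg @ phi @ Rg)
    null = multivariate_normal.logpdf(zg, mean=np.zeros(len(idx)), cov=Rg)
    return float(alt - null)


def naive_enumerate(z, R, se, cmax, snp_prior, prior_var):
    """Exhaustive model posterior via the density-based BF; returns models, pp, mpp."""
    p = len(z)
    models, logw = [], []
    for s in range(cmax + 1):
        for m in itertools.combinations(range(p), s):
            lp = s * np.log(snp_prior) + (p - s) * np.log(1 - snp_prior)
            models.append(m)
            logw.append(lp + naive_model_logbf(z, R, se, m, prior_var))
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    pp = w / w.sum()
    mpp = np.zeros(p)
    for m, wgt in zip(models, pp):
        for i in m:
            mpp[i] += wgt
    return models, pp, mpp


def tau_ref(p, kappa, s1, s2):
    q = 1.0 - comb(p - s1, s2) / comb(p, s2)
    return 1.0 / (1.0 - q + kappa * q)


def joint_adjust_bruteforce(model_lists, pp_lists, p, kappa):
    """Trait-adjusted posteriors by explicit enumeration over model tuples.

    For each focal trait, sums the joint weight PP_i * prod_u PP_{j_u} *
    kappa^{overlap(i, j_u)} tau(|i|, |j_u|) over all partner model
    combinations (pairwise focal-partner sharing factors).
    """
    M = len(model_lists)
    out = []
    for t in range(M):
        partners = [u for u in range(M) if u != t]
        weights = []
        for i, m_i in enumerate(model_lists[t]):
            set_i = set(m_i)
            total = 0.0
            for combo in itertools.product(*[range(len(model_lists[u])) for u in partners]):
                w = pp_lists[t][i]
                for u, j in zip(partners, combo):
                    m_j = model_lists[u][j]
                    tau = tau_ref(p, kappa, len(m_i), len(m_j))
                    shared = bool(set_i & set(m_j))
                    w *= pp_lists[u][j] * (kappa if shared else 1.0) * tau
                total += w
            weights.append(total)
        weights = np.array(weights)
        out.append(weights / weights.sum())
    return out


def trend_chi2_by_expansion(table: np.ndarray) -> float:
    """Cochran-Armitage trend chi-square via the N * r^2 identity."""
    table = np.asarray(table, dtype=float)
    ys, xs = [], []
    for j in range(table.shape[1]):
        ys += [1] * int(table[0, j]) + [0] * int(table[1, j])
        xs += [j] * int(table[0, j] + table[1, j])
    ys, xs = np.array(ys, float), np.array(xs, float)
    if ys.std() == 0 or xs.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(len(ys) * r**2)


def merge_intervals_reference(intervals):
    """Sort-and-sweep interval union; intervals as (chr, start, end)."""
    out = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def random_correlation(p: int, rng) -> np.ndarray:
    """Random well-conditioned correlation matrix."""
    A = rng.standard_normal((p, p + 5))
    S = A @ A.T + 0.5 * p * np.eye(p)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R
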