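"""Per-variant association, GWAS harmonisation, and latent-factor summary stats.

The central identity of this module: with complete data, least-squares factor
scores are a fixed linear map of the traits (F = (L'L)^-1 L' (Y - Ybar)), so a
GWAS on the scores has coefficients beta* = (L'L)^-1 L' beta where beta stacks
the per-trait GWAS coefficients at the same variant.  beta* is therefore
computable from observed-trait summary statistics alone.  Its covariance is
approximated with the marginal trait covariance,

    Var(beta*) = (L'L)^-1 L' V L (L'L)^-1,  V_ij = Cov(Y_i, Y_j) se_i se_j,

and association is assessed by Z_k = beta*_k / sqrt([Var(beta*)]_kk) with
normal p-values (large-n GWAS convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata, t as t_dist

from .factor import LoadingMatrix
from .simulate import GenotypeMatrix

__all__ = [
    "SumStats",
    "HarmonisedPanel",
    "LatentSumStats",
    "rank_inverse_normal",
    "gwas_ols",
    "harmonise",
    "latent_sumstats_from_traits",
]

SUMSTATS_COLUMNS = ["SNPID", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "INFO", "N"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SumStats:
    """GWAS summary statistics for one trait or latent factor."""

    table: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats missing columns: {missing}")
        if self.table["SNPID"].duplicated().any():
            raise ValueError("duplicate variant ids in sumstats")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["SNPID"])

    def z(self) -> np.ndarray:
        return self.table["BETA"].to_numpy() / self.table["SE"].to_numpy()

    def subset(self, ids) -> "SumStats":
        tab = self.table.set_index("SNPID").loc[list(ids)].reset_index()
        return SumStats(tab[SUMSTATS_COLUMNS], self.trait)


@dataclass
class HarmonisedPanel:
    """Variant-by-trait beta/SE matrices on a common effect allele."""

    variants: pd.DataFrame  # SNPID CHR BP EA OA EAF INFO N (reference alignment)
    beta: pd.DataFrame  # variants x traits
    se: pd.DataFrame  # variants x traits
    filter_log: dict[str, int] = field(default_factory=dict)

    @property
    def trait_names(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["SNPID"])

    def to_sumstats(self) -> list[SumStats]:
        """Re-expand into one per-trait table (used for idempotence checks)."""
        out = []
        n = self.variants["N"]
        for trait in self.trait_names:
            beta = self.beta[trait].to_numpy()
            se = self.se[trait].to_numpy()
            z = beta / se
            tab = self.variants[["SNPID", "CHR", "BP", "EA", "OA", "EAF", "INFO"]].copy()
            tab["BETA"] = beta
            tab["SE"] = se
            tab["P"] = 2 * ndtr(-np.abs(z))
            tab["N"] = n.to_numpy()
            out.append(SumStats(tab[SUMSTATS_COLUMNS], trait))
        return out


@dataclass
class LatentSumStats:
    """Per-factor summary statistics plus per-variant Var(beta*) diagonals."""

    factors: list[SumStats]
    covariances: np.ndarray | None = None  # variants x K x K
    clipped_variants: int = 0

    def __getitem__(self, k) -> SumStats:
        return self.factors[k]

    @property
    def factor_names(self) -> list[str]:
        return [s.trait for s in self.factors]


def rank_inverse_normal(values) -> np.ndarray:
    """Blom rank inverse-normal transform Phi^-1((r - 3/8)/(n + 1/4)).

    Ties get average ranks; missing entries are preserved as NaN.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    x = values[mask]
    if x.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks are degenerate")
    ranks = rankdata(x, method="average")
    out = np.full(values.shape, np.nan)
    out[mask] = ndtri((ranks - 0.375) / (x.size + 0.25))
    return out


def gwas_ols(G: GenotypeMatrix, y, trait: str = "trait") -> SumStats:
    """Per-variant simple linear regression of a trait on dosage.

    Uses pairwise-complete individuals per variant; two-sided p-values from
    the t distribution with n - 2 df.  Variants with constant dosage are
    skipped (recorded in ``table.attrs['skipped']``).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != G.n_individuals:
        raise ValueError("trait length does not match genotypes")
    X = G.dosages
    ok_y = np.isfinite(y)
    if ok_y.sum() < 3:
        raise ValueError("need at least 3 individuals with non-missing trait")

    has_missing_x = not np.all(np.isfinite(X))
    skipped: list[str] = []
    rows = []
    if not has_missing_x:
        Xc = X[ok_y]
        yc = y[ok_y]
        n = yc.size
        mx = Xc.mean(axis=0)
        my = yc.mean()
        dx = Xc - mx
        dy = yc - my
        sxx = (dx**2).sum(axis=0)
        sxy = dx.T @ dy
        syy = (dy**2).sum()
        keep = sxx > 1e-12
        beta = np.where(keep, sxy / np.where(keep, sxx, 1.0), np.nan)
        rss = syy - beta * sxy
        sigma2 = np.clip(rss, 0, None) / max(n - 2, 1)
        se = np.sqrt(np.where(keep, sigma2 / np.where(keep, sxx, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        p = 2 * t_dist.sf(np.abs(tstat), n - 2)
        eaf = mx / 2
        nvec = np.full(X.shape[1], n)
    else:
        p_list, beta_list, se_list, eaf_list, n_list, keep = [], [], [], [], [], []
        for j in range(X.shape[1]):
            ok = ok_y & np.isfinite(X[:, j])
            xj, yj = X[ok, j], y[ok]
            nj = xj.size
            if nj < 3 or np.ptp(xj) == 0:
                keep.append(False)
                beta_list.append(np.nan); se_list.append(np.nan)
                p_list.append(np.nan); eaf_list.append(np.nan); n_list.append(nj)
                continue
            dx = xj - xj.mean()
            dy = yj - yj.mean()
            sxx = (dx**2).sum()
            b = dx @ dy / sxx
            rss = (dy**2).sum() - b * (dx @ dy)
            s = np.sqrt(max(rss, 0) / (nj - 2) / sxx)
            keep.append(True)
            beta_list.append(b); se_list.append(s)
            p_list.append(2 * t_dist.sf(abs(b / s), nj - 2) if s > 0 else 0.0)
            eaf_list.append(xj.mean() / 2); n_list.append(nj)
        beta, se = np.array(beta_list), np.array(se_list)
        p, eaf, nvec = np.array(p_list), np.array(eaf_list), np.array(n_list)
        keep = np.array(keep)

    meta = G.variants
    tab = pd.DataFrame(
        {
            "SNPID": meta["id"].to_numpy(),
            "CHR": meta["chr"].to_numpy(),
            "BP": meta["bp"].to_numpy(),
            "EA": meta["effect_allele"].to_numpy(),
            "OA": meta["other_allele"].to_numpy(),
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.nextafter(0, 1), 1.0),
            "INFO": meta["info"].to_numpy(),
            "N": nvec,
        }
    )
    skipped = list(meta.loc[~np.asarray(keep), "id"])
    tab = tab[np.asarray(keep)].reset_index(drop=True)
    tab.attrs["skipped"] = skipped
    return SumStats(tab, trait)


def harmonise(
    tables: list[SumStats],
    min_maf: float = 0.005,
    min_info: float = 0.4,
    drop_ambiguous: bool = False,
) -> HarmonisedPanel:
    """Align betas to a common effect allele and apply MAF/INFO filters.

    Variants are kept only when present in every table, with
    ``min(EAF, 1 - EAF) > min_maf`` and ``INFO > min_info`` in every table.
    Tables whose alleles are swapped relative to the first (reference) table
    have beta negated and EAF flipped; other allele mismatches are dropped.
    ``drop_ambiguous`` additionally removes strand-ambiguous (A/T, C/G)
    variants for cross-study use.
    """
    if not tables:
        raise ValueError("at least one sumstats table required")
    log: dict[str, int] = {}
    ref = tables[0].table.set_index("SNPID")
    common = set(ref.index)
    for tab in tables[1:]:
        common &= set(tab.table["SNPID"])
    log["absent_from_some_table"] = len(ref.index) - len(common)

    ids = [v for v in tables[0].table["SNPID"] if v in common]  # reference order
    aligned_beta: dict[str, pd.Series] = {}
    aligned_se: dict[str, pd.Series] = {}
    mism: set[str] = set()
    fail_maf: set[str] = set()
    fail_info: set[str] = set()
    for tab in tables:
        sub = tab.table.set_index("SNPID").loc[ids]
        ea, oa = sub["EA"].to_numpy(), sub["OA"].to_numpy()
        rea, roa = ref.loc[ids, "EA"].to_numpy(), ref.loc[ids, "OA"].to_numpy()
        same = (ea == rea) & (oa == roa)
        swap = (ea == roa) & (oa == rea)
        bad = ~(same | swap)
        mism.update(np.asarray(ids)[bad])
        beta = np.where(swap, -sub["BETA"].to_numpy(), sub["BETA"].to_numpy())
        eaf = np.where(swap, 1 - sub["EAF"].to_numpy(), sub["EAF"].to_numpy())
        maf = np.minimum(eaf, 1 - eaf)
        fail_maf.update(np.asarray(ids)[~(maf > min_maf)])
        fail_info.update(np.asarray(ids)[~(sub["INFO"].to_numpy() > min_info)])
        aligned_beta[tab.trait] = pd.Series(beta, index=ids)
        aligned_se[tab.trait] = pd.Series(sub["SE"].to_numpy(), index=ids)
    log["allele_mismatch"] = len(mism)
    log["below_min_maf"] = len(fail_maf - mism)
    log["below_min_info"] = len(fail_info - mism - fail_maf)
    drop = mism | fail_maf | fail_info
    if drop_ambiguous:
        amb = {
            v for v, ea, oa in zip(ids, ref.loc[ids, "EA"], ref.loc[ids, "OA"])
            if (str(ea).upper(), str(oa).upper()) in _AMBIGUOUS
        }
        log["strand_ambiguous"] = len(amb - drop)
        drop |= amb
    keep = [v for v in ids if v not in drop]
    if not keep:
        raise ValueError(f"empty variant intersection after harmonisation: {log}")

    variants = ref.loc[keep].reset_index()[
        ["SNPID", "CHR", "BP", "EA", "OA", "EAF", "INFO", "N"]
    ]
    beta = pd.DataFrame({t: s.loc[keep].to_numpy() for t, s in aligned_beta.items()},
                        index=keep)
    se = pd.DataFrame({t: s.loc[keep].to_numpy() for t, s in aligned_se.items()},
                      index=keep)
    return HarmonisedPanel(variants, beta, se, log)


def latent_sumstats_from_traits(
    panel: HarmonisedPanel,
    L: LoadingMatrix,
    trait_cov,
    keep_covariances: bool = False,
) -> LatentSumStats:
    """Latent-factor GWAS summary statistics from observed-trait statistics.

    Per variant, beta* = (L'L)^-1 L' beta and Var(beta*) as in the module
    docstring; SEs are the square roots of the Var(beta*) diagonal and
    p-values come from the normal approximation.  Per-variant covariance
    matrices with negative eigenvalues (possible with inconsistent inputs)
    are clipped to PSD and counted in ``clipped_variants``.
    """
    traits = panel.trait_names
    if L.trait_names != traits:
        raise ValueError("panel and loading matrix trait order disagree")
    C = np.asarray(
        trait_cov.loc[traits, traits] if isinstance(trait_cov, pd.DataFrame) else trait_cov,
        dtype=float,
    )
    if C.shape != (len(traits), len(traits)):
        raise ValueError("trait_cov has wrong shape")
    if not np.allclose(np.diag(C), 1.0, atol=0.1):
        warnings.warn(
            "trait_cov diagonal departs from 1; Var(beta*) assumes traits on "
            "a standardized scale", stacklevel=2
        )

    A_load = L.values  # P x K
    gram = A_load.T @ A_load
    A = np.linalg.solve(gram, A_load.T)  # K x P map beta -> beta*
    beta = panel.beta.to_numpy()  # V x P
    se = panel.se.to_numpy()
    beta_star = beta @ A.T  # V x K

    # Var(beta*)_v = (A * se_v) C (A * se_v)'
    B = A[None, :, :] * se[:, None, :]  # V x K x P
    covs = np.einsum("vkp,pq,vlq->vkl", B, C, B)
    diag = np.einsum("vkk->vk", covs).copy()
    clipped = 0
    bad = np.where(np.any(diag <= 0, axis=1))[0]
    for v in bad:
        vals, vecs = np.linalg.eigh(covs[v])
        covs[v] = (vecs * np.clip(vals, 0, None)) @ vecs.T
        diag[v] = np.clip(np.diag(covs[v]), 1e-300, None)
        clipped += 1
    se_star = np.sqrt(diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta_star / se_star
    p = np.clip(2 * ndtr(-np.abs(z)), np.nextafter(0, 1), 1.0)

    n = panel.variants["N"].to_numpy()
    out = []
    for k, fname in enumerate(L.factor_names):
        tab = panel.variants[["SNPID", "CHR", "BP", "EA", "OA", "EAF", "INFO"]].copy()
        tab["BETA"] = beta_star[:, k]
        tab["SE"] = se_star[:, k]
        tab["P"] = p[:, k]
        tab["N"] = n
        out.append(SumStats(tab[SUMSTATS_COLUMNS].reset_index(drop=True), fname))
    return LatentSumStats(
        factors=out,
        covariances=covs if keep_covariances else None,
        clipped_variants=clipped,
    )
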