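"""Single-trait Bayesian fine-mapping from summary statistics and LD.

Models are subsets of region variants assumed jointly causal.  Each model is
scored with a conjugate multivariate-normal Bayes factor computed from
z-scores and the LD matrix R: writing Phi = diag(W / se_j^2) for per-SNP
prior effect variance W on the standardized-beta scale, the marginal z-scores
satisfy z_gamma ~ N(0, R_gamma) under the null and
z_gamma ~ N(0, R_gamma + R_gamma Phi_gamma R_gamma) under the model, so

  log BF(gamma) = 1/2 [ z' R^-1 z  -  z' (R + R Phi R)^-1 z
                        - log det(I + Phi R) ]              (gamma-restricted)

which reduces exactly to Wakefield's approximate Bayes factor for single-SNP
models.  Models of size 0..cmax are enumerated exhaustively with an
independent-Bernoulli model-space prior; the dynamic rule grows cmax while
the posterior still places appreciable mass on the largest model size.
Outputs are model posterior probabilities (PP), per-variant marginal
posterior probabilities (MPP), 99% credible sets, and LD-based variant
groups.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .gwas import SumStats
from .simulate import GenotypeMatrix

__all__ = [
    "RegionData",
    "ModelPosteriors",
    "CredibleSet",
    "VariantGroups",
    "model_logbf",
    "enumerate_models",
    "dynamic_cmax",
    "credible_set",
    "group_variants",
    "best_guess_ld",
    "FineMapModel",
    "FineMapResults",
]

DEFAULT_PRIOR_VAR = 0.04**2  # prior SD 0.04 on standardized per-allele effects
ENUMERATION_GUARD = 5_000_000
LD_RIDGE = 1e-6


@dataclass
class RegionData:
    """Summary statistics and LD for one region, in a common variant order."""

    sumstats: SumStats
    ld: np.ndarray
    n: int
    trait_var: float = 1.0

    def __post_init__(self) -> None:
        self.ld = np.asarray(self.ld, dtype=float)
        p = len(self.sumstats.table)
        if self.ld.shape != (p, p):
            raise ValueError("LD matrix does not match sumstats variants")
        if not np.allclose(self.ld, self.ld.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.ld), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.ld).min() < -1e-6:
            raise ValueError("LD matrix is not positive semi-definite")
        self.ld = 0.5 * (self.ld + self.ld.T)

    @property
    def p(self) -> int:
        return self.ld.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return self.sumstats.variant_ids

    @property
    def bp(self) -> np.ndarray:
        return self.sumstats.table["BP"].to_numpy()

    def z(self) -> np.ndarray:
        return self.sumstats.z()

    def phi(self, prior_var: float) -> np.ndarray:
        """Per-SNP prior variance on the z scale: W / se^2."""
        se = self.sumstats.table["SE"].to_numpy()
        return prior_var / se**2


@dataclass
class ModelPosteriors:
    """Discrete posterior over multi-SNP causal configurations."""

    models: list[tuple[int, ...]]
    logbf: np.ndarray
    log_prior: np.ndarray
    pp: np.ndarray
    mpp: np.ndarray
    variant_ids: list[str]
    bp: np.ndarray
    cmax_used: int

    def __post_init__(self) -> None:
        if abs(self.pp.sum() - 1.0) > 1e-8:
            raise ValueError("model PPs must sum to 1")
        self._sizes: np.ndarray | None = None

    @property
    def sizes(self) -> np.ndarray:
        if self._sizes is None:
            if isinstance(self.models, ModelSequence):
                self._sizes = self.models.part_sizes()
            else:
                self._sizes = np.array([len(m) for m in self.models])
        return self._sizes

    def top_models(self, k: int = 5) -> pd.DataFrame:
        order = np.argsort(-self.pp)[:k]
        return pd.DataFrame(
            {
                "model": [
                    ",".join(self.variant_ids[i] for i in self.models[j]) or "(null)"
                    for j in order
                ],
                "size": [len(self.models[j]) for j in order],
                "logBF": self.logbf[order],
                "PP": self.pp[order],
            }
        )

    def mpp_series(self) -> pd.Series:
        return pd.Series(self.mpp, index=self.variant_ids)

    def replace_pp(self, pp: np.ndarray) -> "ModelPosteriors":
        mpp = _mpp_from_models(self.models, pp, len(self.variant_ids))
        return ModelPosteriors(
            models=self.models,
            logbf=self.logbf,
            log_prior=self.log_prior,
            pp=pp,
            mpp=mpp,
            variant_ids=self.variant_ids,
            bp=self.bp,
            cmax_used=self.cmax_used,
        )


@dataclass
class CredibleSet:
    variant_ids: list[str]
    cumulative_mpp: np.ndarray
    level: float
    attained: bool = True

    @property
    def size(self) -> int:
        return len(self.variant_ids)


@dataclass
class VariantGroups:
    labels: pd.Series  # variant id -> group label ("0" = unassigned)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for vid, lab in self.labels.items():
            out.setdefault(lab, []).append(vid)
        return out


def _mpp_from_models(models, pp, p) -> np.ndarray:
    mpp = np.zeros(p)
    for m, w in zip(models, pp):
        for i in m:
            mpp[i] += w
    return mpp


def _chol_or_ridge(R: np.ndarray):
    try:
        return cho_factor(R, lower=True), False
    except np.linalg.LinAlgError:
        return cho_factor(R + LD_RIDGE * np.eye(R.shape[0]), lower=True), True


def model_logbf(region: RegionData, model, prior_var: float = DEFAULT_PRIOR_VAR) -> float:
    """log Bayes factor of a causal configuration vs. the null model."""
    idx = tuple(sorted(model))
    if not idx:
        return 0.0
    z = region.z()[list(idx)]
    phi = region.phi(prior_var)[list(idx)]
    R = region.ld[np.ix_(idx, idx)]
    c, _ = _chol_or_ridge(R)
    a = cho_solve(c, z)  # R^-1 z
    M = np.eye(len(idx)) + phi[:, None] * R  # I + Phi R
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("I + Phi R not positive definite")
    # z'(R + R Phi R)^-1 z = z' M^-1 R^-1 z with M = I + Phi R
    quad_alt = z @ np.linalg.solve(M, a)
    return float(0.5 * (z @ a - quad_alt - logdet))


def _logbf_singletons(region: RegionData, prior_var: float) -> np.ndarray:
    z = region.z()
    phi = region.phi(prior_var)
    return 0.5 * (z**2 * phi / (1 + phi) - np.log1p(phi))


def _logbf_pairs(region: RegionData, pairs: np.ndarray, prior_var: float) -> np.ndarray:
    """Closed-form 2-SNP log BFs, vectorized over an array of index pairs."""
    z = region.z()
    phi = region.phi(prior_var)
    i, j = pairs[:, 0], pairs[:, 1]
    r = region.ld[i, j]
    zi, zj, fi, fj = z[i], z[j], phi[i], phi[j]
    det_r = 1 - r**2
    near_singular = det_r < 1e-9
    det_r = np.where(near_singular, det_r + LD_RIDGE, det_r)
    ai = (zi - r * zj) / det_r
    aj = (zj - r * zi) / det_r
    quad_null = zi * ai + zj * aj
    det_m = (1 + fi) * (1 + fj) - fi * fj * r**2
    # M^-1 a with M = I + Phi R
    mi = ((1 + fj) * ai - fi * r * aj) / det_m
    mj = (-fj * r * ai + (1 + fi) * aj) / det_m
    quad_alt = zi * mi + zj * mj
    out = 0.5 * (quad_null - quad_alt - np.log(det_m))
    if near_singular.any():  # fall back to the generic ridge path
        for k in np.where(near_singular)[0]:
            out[k] = model_logbf(region, (int(i[k]), int(j[k])), prior_var)
    return out


def _logbf_batch(
    region: RegionData,
    combos: np.ndarray,
    prior_var: float,
    chunk: int = 100_000,
) -> np.ndarray:
    """Batched log BFs for all models in ``combos`` (m x s index array)."""
    z = region.z()
    phi = region.phi(prior_var)
    R = region.ld
    m, s = combos.shape
    out = np.empty(m)
    eye = np.eye(s)
    for lo in range(0, m, chunk):
        c = combos[lo : lo + chunk]
        z_g = z[c]  # b x s
        phi_g = phi[c]
        R_g = R[c[:, :, None], c[:, None, :]]  # b x s x s
        try:
            a = np.linalg.solve(R_g, z_g[..., None])[..., 0]
            M = eye + phi_g[:, :, None] * R_g
            sign_M, logdet_M = np.linalg.slogdet(M)
            quad_null = (z_g * a).sum(axis=1)
            quad_alt = (z_g * np.linalg.solve(M, a[..., None])[..., 0]).sum(axis=1)
            vals = 0.5 * (quad_null - quad_alt - logdet_M)
            vals[sign_M <= 0] = np.nan
        except np.linalg.LinAlgError:
            vals = np.full(len(c), np.nan)
        bad = ~np.isfinite(vals)
        if bad.any():  # singular submatrices: generic ridge path per model
            for i in np.where(bad)[0]:
                vals[i] = model_logbf(region, tuple(c[i]), prior_var)
        out[lo : lo + len(c)] = vals
    return out


@lru_cache(maxsize=8)
def _combos_for_size(p: int, s: int) -> np.ndarray:
    """All index combinations of size s as a read-only (m, s) array (cached)."""
    if s == 0:
        out = np.zeros((1, 0), dtype=int)
    elif s == 1:
        out = np.arange(p, dtype=int).reshape(-1, 1)
    else:
        out = np.array(list(itertools.combinations(range(p), s)), dtype=int)
    out.setflags(write=False)
    return out


class ModelSequence(Sequence):
    """Lazy sequence of model index tuples backed by per-size combo arrays."""

    def __init__(self, parts: list[np.ndarray]):
        self._parts = parts
        self._offsets = np.cumsum([0] + [c.shape[0] for c in parts])

    def __len__(self) -> int:
        return int(self._offsets[-1])

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        if i < 0:
            i += len(self)
        if not 0 <= i < len(self):
            raise IndexError(i)
        part = int(np.searchsorted(self._offsets, i, side="right") - 1)
        return tuple(self._parts[part][i - self._offsets[part]])

    def __iter__(self):
        for part in self._parts:
            yield from map(tuple, part)

    def index(self, value):
        value = tuple(value)
        for part_idx, part in enumerate(self._parts):
            if part.shape[1] != len(value):
                continue
            hits = np.where((part == np.array(value, dtype=int)).all(axis=1))[0]
            if hits.size:
                return int(self._offsets[part_idx] + hits[0])
        raise ValueError(f"{value} not found")

    def part_sizes(self) -> np.ndarray:
        return np.repeat(
            [c.shape[1] for c in self._parts], [c.shape[0] for c in self._parts]
        )


def _logbf_for_combos(region: RegionData, combos: np.ndarray, prior_var: float):
    s = combos.shape[1]
    if s == 0:
        return np.zeros(1)
    if s == 1:
        return _logbf_singletons(region, prior_var)
    if s == 2:
        return _logbf_pairs(region, combos, prior_var)
    return _logbf_batch(region, combos, prior_var)


def _posteriors_from_combo_parts(region, combo_parts, logbf_parts, snp_prior, cmax):
    p = region.p
    logbf = np.concatenate(logbf_parts)
    sizes = np.concatenate(
        [np.full(c.shape[0], c.shape[1], dtype=int) for c in combo_parts]
    )
    log_prior = sizes * np.log(snp_prior) + (p - sizes) * np.log1p(-snp_prior)
    logpost = log_prior + logbf
    pp = np.exp(logpost - logsumexp(logpost))
    pp /= pp.sum()
    mpp = np.zeros(p)
    offset = 0
    for c in combo_parts:
        block = pp[offset : offset + c.shape[0]]
        if c.shape[1]:
            np.add.at(mpp, c.ravel(), np.repeat(block, c.shape[1]))
        offset += c.shape[0]
    return ModelPosteriors(
        models=ModelSequence(combo_parts),
        logbf=logbf,
        log_prior=log_prior,
        pp=pp,
        mpp=mpp,
        variant_ids=region.variant_ids,
        bp=region.bp,
        cmax_used=cmax,
    )


def enumerate_models(
    region: RegionData,
    cmax: int,
    snp_prior: float | None = None,
    prior_var: float = DEFAULT_PRIOR_VAR,
) -> ModelPosteriors:
    """Score all causal configurations of size 0..cmax.

    Model prior: independent Bernoulli per SNP,
    ``snp_prior^|gamma| (1 - snp_prior)^(p - |gamma|)``; ``snp_prior``
    defaults to 1/p (one causal variant expected per region).
    """
    p = region.p
    if snp_prior is None:
        snp_prior = 1.0 / p
    cmax = min(cmax, p)
    n_models = sum(comb(p, s) for s in range(cmax + 1))
    if n_models > ENUMERATION_GUARD:
        raise ValueError(
            f"{n_models} models exceed the enumeration guard; thin the region "
            f"or reduce cmax={cmax}"
        )
    combo_parts = [_combos_for_size(p, s) for s in range(cmax + 1)]
    logbf_parts = [_logbf_for_combos(region, c, prior_var) for c in combo_parts]
    return _posteriors_from_combo_parts(region, combo_parts, logbf_parts,
                                        snp_prior, cmax)


def dynamic_cmax(
    region: RegionData,
    snp_prior: float | None = None,
    prior_var: float = DEFAULT_PRIOR_VAR,
    growth_threshold: float = 0.05,
    hard_cmax: int = 10,
) -> ModelPosteriors:
    """Enumerate with a data-driven maximum model size.

    Starts at cmax = 1 and increments while the posterior mass on models of
    the current maximum size exceeds ``growth_threshold`` (and cmax < 10),
    mirroring dynamic selection of the number of causal variants.  Scored
    model sizes are reused as cmax grows.
    """
    p = region.p
    if snp_prior is None:
        snp_prior = 1.0 / p
    log_odds = np.log(snp_prior) - np.log1p(-snp_prior)
    combo_parts = [_combos_for_size(p, s) for s in (0, 1)]
    logbf_parts = [_logbf_for_combos(region, c, prior_var) for c in combo_parts]
    cmax = 1
    while True:
        # posterior mass at the current maximum size, without building the
        # full posterior object at every step
        logw = [
            lbf + c.shape[1] * log_odds
            for c, lbf in zip(combo_parts, logbf_parts)
        ]
        flat = np.concatenate(logw)
        total = logsumexp(flat)
        mass_at_max = float(np.exp(logsumexp(logw[-1]) - total))
        if (
            mass_at_max <= growth_threshold
            or cmax >= min(hard_cmax, p)
        ):
            break
        if sum(c.shape[0] for c in combo_parts) + comb(p, cmax + 1) > ENUMERATION_GUARD:
            warnings.warn(
                f"dynamic growth stopped at cmax={cmax}: enumerating size "
                f"{cmax + 1} would exceed the model guard", stacklevel=2
            )
            break
        cmax += 1
        c = _combos_for_size(p, cmax)
        combo_parts.append(c)
        logbf_parts.append(_logbf_for_combos(region, c, prior_var))
    return _posteriors_from_combo_parts(region, combo_parts, logbf_parts,
                                        snp_prior, cmax)


def credible_set(mp: ModelPosteriors, level: float = 0.99) -> CredibleSet:
    """Smallest MPP-ranked variant set with cumulative MPP >= level.

    Variants are ranked by decreasing MPP with ties broken by ascending bp.
    If total MPP cannot reach the level, all variants are returned with
    ``attained=False`` and a warning.
    """
    order = sorted(
        range(len(mp.variant_ids)), key=lambda i: (-mp.mpp[i], mp.bp[i])
    )
    cum = np.cumsum(mp.mpp[np.array(order)])
    if cum[-1] < level:
        warnings.warn(
            f"total MPP {cum[-1]:.4f} below credible level {level}", stacklevel=2
        )
        return CredibleSet([mp.variant_ids[i] for i in order], cum, level, False)
    k = int(np.searchsorted(cum, level) + 1)
    chosen = order[:k]
    return CredibleSet([mp.variant_ids[i] for i in chosen], cum[:k], level, True)


def group_variants(
    mp: ModelPosteriors,
    ld: np.ndarray,
    mpp_min: float = 0.01,
    r2_min: float = 0.8,
) -> VariantGroups:
    """Single-linkage grouping of MPP > mpp_min variants with r^2 > r2_min.

    Groups are labeled "1", "2", ... by decreasing maximum member MPP;
    variants below mpp_min get label "0".
    """
    p = len(mp.variant_ids)
    sel = [i for i in range(p) if mp.mpp[i] > mpp_min]
    parent = {i: i for i in sel}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    r2 = np.asarray(ld) ** 2
    for a_pos, i in enumerate(sel):
        for j in sel[a_pos + 1:]:
            if r2[i, j] > r2_min:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in sel:
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda c: -max(mp.mpp[i] for i in c))
    labels = pd.Series("0", index=mp.variant_ids, dtype=object)
    for g, members in enumerate(ordered, start=1):
        for i in members:
            labels.iloc[i] = str(g)
    return VariantGroups(labels)


def best_guess_ld(
    G: GenotypeMatrix,
    certainty: float = 0.2,
    min_nonmissing: float = 0.8,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete LD from best-guess genotypes.

    A fractional dosage maps to the hard call g in {0, 1, 2} when
    ``|dosage - g| <= certainty`` and is otherwise treated as missing.
    Variants whose non-missing proportion falls below ``min_nonmissing`` are
    excluded (returned in the second element).  Correlations use
    pairwise-complete individuals.
    """
    d = G.dosages
    g = np.rint(d)
    best = np.where(np.abs(d - g) <= certainty, g, np.nan)
    nonmiss = np.isfinite(best).mean(axis=0)
    keep = nonmiss >= min_nonmissing
    excluded = [vid for vid, k in zip(G.variant_ids, keep) if not k]
    frame = pd.DataFrame(best[:, keep], columns=[v for v, k in zip(G.variant_ids, keep) if k])
    corr = frame.corr(method="pearson", min_periods=2)
    return corr, excluded


class FineMapModel:
    """Fine-mapping model for one region, statsmodels-style."""

    def __init__(
        self,
        region: RegionData,
        snp_prior: float | None = None,
        prior_var: float = DEFAULT_PRIOR_VAR,
    ):
        self.region = region
        self.snp_prior = snp_prior
        self.prior_var = prior_var

    def fit(self, cmax: int | None = None, growth_threshold: float = 0.05) -> "FineMapResults":
        if cmax is None:
            mp = dynamic_cmax(self.region, self.snp_prior, self.prior_var, growth_threshold)
        else:
            mp = enumerate_models(self.region, cmax, self.snp_prior, self.prior_var)
        return FineMapResults(self, mp)


class FineMapResults:
    """Posterior summaries for a fine-mapped region."""

    def __init__(self, model: FineMapModel, posteriors: ModelPosteriors):
        self.model = model
        self.posteriors = posteriors
        self.mpp = posteriors.mpp_series()

    def credible_set(self, level: float = 0.99) -> CredibleSet:
        return credible_set(self.posteriors, level)

    def variant_groups(self, mpp_min: float = 0.01, r2_min: float = 0.8) -> VariantGroups:
        return group_variants(self.posteriors, self.model.region.ld, mpp_min, r2_min)

    def summary(self, level: float = 0.99) -> str:
        cs = self.credible_set(level)
        top = self.mpp.idxmax()
        lines = [
            f"Fine-mapping of {self.model.region.sumstats.trait or 'trait'}: "
            f"p={self.model.region.p} variants, n={self.model.region.n}",
            f"  cmax used: {self.posteriors.cmax_used}",
            f"  top variant: {top} (MPP {self.mpp.max():.3f})",
            f"  CS{int(level * 100)}: {cs.size} variants",
            "",
            self.posteriors.top_models().round(4).to_string(index=False),
        ]
        return "\n".join(lines)
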