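"""Joint fine-mapping of uncorrelated traits with a sharing-upweighted prior.

For M uncorrelated traits (latent factors from a varimax rotation), the joint
Bayes factor factorizes into the product of the marginal ones, so only the
model-space prior couples the traits.  The joint prior for models M_i, M_j of
two traits is

    p_i p_j kappa^{1{M_i \\cap M_j != 0}} tau(|M_i|, |M_j|),

where kappa >= 1 upweights configurations sharing at least one causal
variant and tau is the correction keeping the prior over model-size pairs
invariant to kappa.  With q(s1, s2) = 1 - C(p - s1, s2) / C(p, s2) the
probability that two uniformly chosen models of sizes s1, s2 overlap,

    tau(s1, s2) = 1 / (1 - q + kappa q)

satisfies that consistency exactly under uniform-within-size model priors.
The trait-adjusted posterior for model i of trait t multiplies its marginal
PP by one overlap-weighted partner sum per other trait and renormalizes; the
factorization across partners is exact because the traits are uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .finemap import (
    DEFAULT_PRIOR_VAR,
    CredibleSet,
    ModelPosteriors,
    RegionData,
    VariantGroups,
    credible_set,
    dynamic_cmax,
    group_variants,
)

__all__ = [
    "compute_tau",
    "overlap_probability",
    "flashfm_zero",
    "flashfm_zero_with_finemap",
    "AdjustedPosteriors",
    "FlashfmZeroModel",
    "JointFineMapResults",
]

DEFAULT_KAPPA = 4.0


def overlap_probability(p: int, s1: int, s2: int) -> float:
    """P(two uniformly random models of sizes s1, s2 over p variants overlap)."""
    if s1 < 0 or s2 < 0 or s1 > p or s2 > p:
        raise ValueError("model sizes must lie in [0, p]")
    denom = comb(p, s2)
    if denom == 0:
        raise ValueError(f"C({p}, {s2}) = 0")
    return 1.0 - comb(p - s1, s2) / denom


def compute_tau(p: int, kappa: float, size_pair: tuple[int, int]) -> float:
    """Sharing correction tau(s1, s2) = 1 / (1 - q + kappa q)."""
    s1, s2 = size_pair
    q = overlap_probability(p, s1, s2)
    return 1.0 / (1.0 - q + kappa * q)


@dataclass
class AdjustedPosteriors:
    """Per-trait model posteriors after multi-trait adjustment."""

    posteriors: list[ModelPosteriors]
    kappa: float
    trait_names: list[str] = field(default_factory=list)

    def __getitem__(self, t) -> ModelPosteriors:
        return self.posteriors[t]

    def __len__(self) -> int:
        return len(self.posteriors)


def _membership(models, variant_universe: int) -> np.ndarray:
    """Dense model-by-variant 0/1 membership matrix (for BLAS overlap counts)."""
    memb = np.zeros((len(models), variant_universe))
    for m_idx, m in enumerate(models):
        memb[m_idx, list(m)] = 1.0
    return memb


def _prune(mp: ModelPosteriors, max_models: int) -> ModelPosteriors:
    """Keep the top models by PP (at least covering all but 1e-12 of mass)."""
    if len(mp.models) <= max_models:
        return mp
    order = np.argsort(-mp.pp)[:max_models]
    order.sort()
    pp = mp.pp[order]
    pp = pp / pp.sum()
    return ModelPosteriors(
        models=[mp.models[i] for i in order],
        logbf=mp.logbf[order],
        log_prior=mp.log_prior[order],
        pp=pp,
        mpp=None,  # filled by replace_pp below
        variant_ids=mp.variant_ids,
        bp=mp.bp,
        cmax_used=mp.cmax_used,
    ).replace_pp(pp)


def flashfm_zero(
    inputs: list[ModelPosteriors],
    p: int | None = None,
    kappa: float = DEFAULT_KAPPA,
    max_models: int | None = None,
) -> AdjustedPosteriors:
    """Trait-adjusted model posteriors for M >= 2 uncorrelated traits.

    For trait t's model i, the adjusted posterior is proportional to

        PP_i^(t) * prod_{u != t} sum_j PP_j^(u) kappa^{overlap(i,j)} tau(|i|,|j|)

    normalized within trait t.  ``p`` is the number of variants in the shared
    universe (default: size of the common variant list).  ``max_models``
    optionally prunes each trait's model list to its top-PP models before
    adjustment (renormalized), trading exactness for speed on huge model
    spaces.  kappa = 1 reproduces the inputs exactly.
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if len(inputs) < 2:
        return AdjustedPosteriors(list(inputs), kappa)
    universe = inputs[0].variant_ids
    for mp in inputs[1:]:
        if mp.variant_ids != universe:
            raise ValueError("all inputs must share the same variant universe")
    if p is None:
        p = len(universe)
    if max_models is not None:
        inputs = [_prune(mp, max_models) for mp in inputs]

    max_size = max(int(mp.sizes.max()) for mp in inputs)
    tau = np.ones((max_size + 1, max_size + 1))
    for s1 in range(max_size + 1):
        for s2 in range(max_size + 1):
            tau[s1, s2] = compute_tau(p, kappa, (s1, s2))

    n_vars = len(universe)
    memb = [_membership(mp.models, n_vars) for mp in inputs]
    sizes = [mp.sizes for mp in inputs]

    adjusted: list[ModelPosteriors] = []
    for t, mp in enumerate(inputs):
        log_adj = np.log(np.clip(mp.pp, 1e-300, None))
        tau_t = tau[sizes[t]]  # n_models_t x (max_size + 1)
        for u, mp_u in enumerate(inputs):
            if u == t:
                continue
            pp_u, sizes_u = mp_u.pp, sizes[u]
            # base term: sum_j pp_j tau(s_i, s_j), grouped by partner size
            mass_by_size = np.bincount(sizes_u, weights=pp_u, minlength=max_size + 1)
            factors = tau_t @ mass_by_size
            # sharing term: (kappa - 1) sum_{j overlapping i} pp_j tau(s_i, s_j)
            size_cols = [np.where(sizes_u == s)[0] for s in range(max_size + 1)]
            chunk = max(1, 40_000_000 // max(1, len(mp_u.models) * 8))
            for lo in range(0, len(mp.models), chunk):
                shared = memb[t][lo : lo + chunk] @ memb[u].T  # overlap counts
                overlap = shared > 0.5
                extra = np.zeros(overlap.shape[0])
                for s, cols in enumerate(size_cols):
                    if cols.size:
                        extra += tau_t[lo : lo + chunk, s] * (
                            overlap[:, cols] @ pp_u[cols]
                        )
                factors[lo : lo + chunk] += (kappa - 1.0) * extra
            log_adj += np.log(factors)
        pp_new = np.exp(log_adj - log_adj.max())
        pp_new /= pp_new.sum()
        adjusted.append(mp.replace_pp(pp_new))
    return AdjustedPosteriors(adjusted, kappa)


def flashfm_zero_with_finemap(
    regions: list[RegionData],
    kappa: float = DEFAULT_KAPPA,
    snp_prior: float | None = None,
    prior_var: float = DEFAULT_PRIOR_VAR,
    growth_threshold: float = 0.05,
    cs_level: float = 0.99,
    group_mpp_min: float = 0.01,
    group_r2_min: float = 0.8,
    max_models: int | None = 4000,
) -> "JointFineMapResults":
    """Dynamic single-trait fine-mapping followed by flashfmZero adjustment.

    ``regions`` hold the same variants and LD but one factor's summary
    statistics each.  Returns per-factor single-trait and adjusted posteriors
    with credible sets, variant groups, and a summary table.
    """
    if len(regions) < 2:
        raise ValueError("joint fine-mapping requires at least 2 factors")
    single = [
        dynamic_cmax(r, snp_prior, prior_var, growth_threshold) for r in regions
    ]
    adjusted = flashfm_zero(single, p=regions[0].p, kappa=kappa, max_models=max_models)
    return JointFineMapResults(
        regions=regions,
        single=single,
        adjusted=adjusted,
        cs_level=cs_level,
        group_mpp_min=group_mpp_min,
        group_r2_min=group_r2_min,
    )


class FlashfmZeroModel:
    """Joint fine-mapping model over uncorrelated factors, statsmodels-style.

    Construct either from per-factor :class:`RegionData` (single-trait
    fine-mapping is run inside ``fit``) or from precomputed
    :class:`ModelPosteriors` via :meth:`from_posteriors`.
    """

    def __init__(self, regions: list[RegionData], kappa: float = DEFAULT_KAPPA, **config):
        self.regions = regions
        self.kappa = kappa
        self.config = config
        self._posteriors: list[ModelPosteriors] | None = None

    @classmethod
    def from_posteriors(
        cls, posteriors: list[ModelPosteriors], p: int | None = None,
        kappa: float = DEFAULT_KAPPA,
    ) -> "FlashfmZeroModel":
        model = cls.__new__(cls)
        model.regions = []
        model.kappa = kappa
        model.config = {"p": p}
        model._posteriors = posteriors
        return model

    def fit(self) -> "JointFineMapResults | AdjustedPosteriors":
        if self._posteriors is not None:
            return flashfm_zero(
                self._posteriors, p=self.config.get("p"), kappa=self.kappa
            )
        return flashfm_zero_with_finemap(self.regions, kappa=self.kappa, **self.config)


class JointFineMapResults:
    """Single-factor and flashfmZero-adjusted fine-mapping results."""

    def __init__(self, regions, single, adjusted, cs_level=0.99,
                 group_mpp_min=0.01, group_r2_min=0.8):
        self.regions = regions
        self.single = single
        self.adjusted = adjusted
        self.cs_level = cs_level
        self.factor_names = [r.sumstats.trait for r in regions]
        self._group_args = (group_mpp_min, group_r2_min)

    def credible_sets(self, adjusted: bool = True) -> list[CredibleSet]:
        src = self.adjusted.posteriors if adjusted else self.single
        return [credible_set(mp, self.cs_level) for mp in src]

    def variant_groups(self, adjusted: bool = True) -> list[VariantGroups]:
        src = self.adjusted.posteriors if adjusted else self.single
        return [
            group_variants(mp, r.ld, *self._group_args)
            for mp, r in zip(src, self.regions)
        ]

    def summary_table(self) -> pd.DataFrame:
        """Per-factor FM summary: CS99 size, top variant, MPP (both methods)."""
        rows = []
        cs_single = self.credible_sets(adjusted=False)
        cs_joint = self.credible_sets(adjusted=True)
        for name, mp_s, mp_a, c_s, c_a, region in zip(
            self.factor_names, self.single, self.adjusted.posteriors,
            cs_single, cs_joint, self.regions,
        ):
            top_s = int(np.argmax(mp_s.mpp))
            top_a = int(np.argmax(mp_a.mpp))
            rows.append(
                {
                    "factor": name,
                    "cmax_used": mp_s.cmax_used,
                    "single_top_variant": region.variant_ids[top_s],
                    "single_top_mpp": mp_s.mpp[top_s],
                    "single_cs_size": c_s.size,
                    "joint_top_variant": region.variant_ids[top_a],
                    "joint_top_mpp": mp_a.mpp[top_a],
                    "joint_cs_size": c_a.size,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.summary_table()
        return (
            f"flashfmZero joint fine-mapping of {len(self.factor_names)} factors "
            f"(kappa={self.adjusted.kappa}, CS level {self.cs_level})\n\n"
            + tab.round(4).to_string(index=False)
        )
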