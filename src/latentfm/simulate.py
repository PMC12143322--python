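"""Synthetic cohort generation: LD-structured genotypes and factor-model traits.

Genotypes are produced by thresholding two latent standard-normal "haplotype"
processes per individual.  Each process follows an AR(1) correlation across
variants (parameter ``rho``), and a variant's alternate allele is carried when
the latent value falls below the allele-frequency quantile.  Summing the two
haplotype indicators gives a dosage in {0, 1, 2} with Hardy-Weinberg genotype
frequencies and tunable adjacent-variant LD.

Traits follow the latent-factor model Y = M + L F + eps: factor scores are
genotype-driven (per-factor causal variants with additive effects plus
Gaussian noise) and observed traits are noisy linear combinations of the
factors through a loading matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "GenotypeMatrix",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_factor_traits",
    "add_dosage_jitter",
    "inject_missingness",
]

VARIANT_COLUMNS = ["id", "chr", "bp", "effect_allele", "other_allele", "maf", "info"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants) with per-variant metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("variant ids must be unique")
        for _, grp in self.variants.groupby("chr", sort=False):
            if not grp["bp"].is_monotonic_increasing or grp["bp"].duplicated().any():
                raise ValueError("bp must be strictly increasing within chr")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["id"])

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.variant_ids)


@dataclass
class TruthRecord:
    """Simulation ground truth: causal configuration, loadings, factor scores."""

    causal_map: dict[str, dict[str, float]]
    loadings: pd.DataFrame  # traits x factors
    factor_scores: pd.DataFrame  # individuals x factors
    factor_noise_sd: np.ndarray
    trait_noise_sd: np.ndarray

    def causal_ids(self, factor: str) -> list[str]:
        return list(self.causal_map.get(factor, {}))


def simulate_genotypes(
    n: int,
    p: int,
    mafs,
    rho: float,
    seed,
    chrom: str = "1",
    bp_start: int = 1_000_000,
    bp_step: int = 2_000,
) -> GenotypeMatrix:
    """Simulate hard-call dosages with AR(1) haplotype LD.

    Parameters
    ----------
    n, p
        Numbers of individuals and variants.
    mafs
        Per-variant minor allele frequencies, each in (0, 0.5].
    rho
        AR(1) correlation of the latent haplotype process across adjacent
        variants, in [0, 1).  Larger values give stronger pairwise LD.
    seed
        Integer seed or :class:`numpy.random.Generator`; output is
        deterministic for a given seed.
    """
    if n <= 0 or p <= 0:
        raise ValueError("n and p must be positive")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (p,):
        raise ValueError(f"mafs must have length p={p}")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("each maf must lie in (0, 0.5]")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    thresholds = ndtri(mafs)  # allele carried iff latent z < Phi^-1(maf)
    dosages = np.zeros((n, p))
    scale = np.sqrt(1.0 - rho**2)
    for _ in range(2):  # two haplotypes per individual
        z = rng.standard_normal((n, p))
        h = np.empty((n, p))
        h[:, 0] = z[:, 0]
        for j in range(1, p):
            h[:, j] = rho * h[:, j - 1] + scale * z[:, j]
        dosages += h < thresholds

    variants = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(p)],
            "chr": chrom,
            "bp": bp_start + bp_step * np.arange(p),
            "effect_allele": "A",
            "other_allele": "G",
            "maf": mafs,
            "info": 1.0,
        }
    )
    return GenotypeMatrix(dosages, variants)


def simulate_factor_traits(
    G: GenotypeMatrix,
    L: pd.DataFrame,
    causal_map: dict[str, dict[str, float]],
    factor_noise_sd,
    trait_noise_sd,
    seed,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate traits from genotype-driven latent factors.

    Factor k is ``sum_c effect_c * dosage_c + N(0, factor_noise_sd_k)`` over
    its causal variants; traits are ``Y = F L' + diag(trait_noise_sd) * white
    noise`` with independent individuals.

    Parameters
    ----------
    L
        Loading matrix as a traits x factors DataFrame.
    causal_map
        ``{factor_name: {variant_id: effect}}``; factors absent from the map
        are purely stochastic.

    Returns
    -------
    (TraitMatrix, TruthRecord)
        Traits as an individuals x traits DataFrame plus ground truth.
    """
    if not isinstance(L, pd.DataFrame):
        raise TypeError("L must be a traits x factors DataFrame")
    factor_names = list(L.columns)
    trait_names = list(L.index)
    K, P = len(factor_names), len(trait_names)
    factor_noise_sd = np.broadcast_to(np.asarray(factor_noise_sd, float), (K,)).copy()
    trait_noise_sd = np.broadcast_to(np.asarray(trait_noise_sd, float), (P,)).copy()
    if np.any(factor_noise_sd < 0) or np.any(trait_noise_sd < 0):
        raise ValueError("noise SDs must be non-negative")
    unknown = {f for f in causal_map if f not in factor_names}
    if unknown:
        raise ValueError(f"causal_map refers to unknown factors: {sorted(unknown)}")

    id_index = {vid: j for j, vid in enumerate(G.variant_ids)}
    rng = np.random.default_rng(seed)
    n = G.n_individuals

    F = np.zeros((n, K))
    for k, fname in enumerate(factor_names):
        for vid, effect in causal_map.get(fname, {}).items():
            if vid not in id_index:
                raise ValueError(f"unknown causal variant id: {vid}")
            F[:, k] += effect * G.dosages[:, id_index[vid]]
    F += rng.standard_normal((n, K)) * factor_noise_sd

    Y = F @ L.to_numpy().T + rng.standard_normal((n, P)) * trait_noise_sd
    traits = pd.DataFrame(Y, columns=trait_names)
    truth = TruthRecord(
        causal_map={f: dict(c) for f, c in causal_map.items()},
        loadings=L.copy(),
        factor_scores=pd.DataFrame(F, columns=factor_names),
        factor_noise_sd=factor_noise_sd,
        trait_noise_sd=trait_noise_sd,
    )
    return traits, truth


def add_dosage_jitter(G: GenotypeMatrix, amount: float, seed) -> GenotypeMatrix:
    """Blur hard-call dosages with Uniform(-amount, amount) noise, clipped to [0, 2].

    Emulates imputation uncertainty; INFO is recomputed as
    ``var(dosage) / (2 maf (1 - maf))`` so that downstream INFO filters have
    something to act on.
    """
    rng = np.random.default_rng(seed)
    noisy = np.clip(G.dosages + rng.uniform(-amount, amount, G.dosages.shape), 0, 2)
    variants = G.variants.copy()
    maf = variants["maf"].to_numpy()
    with np.errstate(invalid="ignore"):
        info = np.var(noisy, axis=0) / (2 * maf * (1 - maf))
    variants["info"] = np.clip(info, 0.0, 1.0)
    return GenotypeMatrix(noisy, variants)


def inject_missingness(traits: pd.DataFrame, rate, seed) -> pd.DataFrame:
    """Mask trait entries with per-trait Bernoulli(rate) missingness."""
    rng = np.random.default_rng(seed)
    rate = np.broadcast_to(np.asarray(rate, float), (traits.shape[1],))
    out = traits.copy()
    mask = rng.random(traits.shape) < rate
    out[:] = np.where(mask, np.nan, traits.to_numpy())
    return out


def write_genotypes(G: GenotypeMatrix, dosage_path, variants_path) -> None:
    """Write dosages (variants x individuals TSV) and variant metadata TSV."""
    frame = pd.DataFrame(
        G.dosages.T,
        index=G.variant_ids,
        columns=[f"I{i + 1}" for i in range(G.n_individuals)],
    )
    frame.index.name = "id"
    frame.to_csv(dosage_path, sep="\t")
    G.variants.to_csv(variants_path, sep="\t", index=False)


def read_genotypes(dosage_path, variants_path) -> GenotypeMatrix:
    frame = pd.read_csv(dosage_path, sep="\t", index_col=0)
    variants = pd.read_csv(variants_path, sep="\t")
    variants["chr"] = variants["chr"].astype(str)
    if list(frame.index) != list(variants["id"]):
        raise ValueError("dosage rows and variant metadata disagree")
    return GenotypeMatrix(frame.to_numpy().T, variants)
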