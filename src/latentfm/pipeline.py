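"""End-to-end pipeline: harmonise -> latent GWAS -> fine-map -> flashfmZero.

The pipeline consumes per-trait summary-statistics TSVs, a trait covariance
(or correlation) TSV, and either an LD matrix TSV or a dosage TSV from which
best-guess LD is computed.  A factor loading matrix may be supplied or fitted
from the trait covariance.  Every filter is logged with before/after counts
and a single global seed is expanded into per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import glob as globlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lfio
from .factor import FactorModel, LoadingMatrix
from .finemap import RegionData, best_guess_ld
from .flashfm import DEFAULT_KAPPA, flashfm_zero_with_finemap
from .gwas import harmonise, latent_sumstats_from_traits
from .regions import GWS_P
from .simulate import read_genotypes

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "ConfigError", "DataError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the analysis constants."""

    sumstats_glob: str = ""
    trait_cov_path: str = ""
    ld_path: str = ""  # square LD TSV; or use dosage_path
    dosage_path: str = ""
    dosage_variants_path: str = ""
    loadings_path: str = ""  # optional: precomputed loading matrix
    out_dir: str = "latentfm_out"
    n_factors: int = 0  # 0 = choose by parallel analysis
    n_obs: int = 0  # 0 = infer (required when fitting from covariance)
    min_maf: float = 0.005
    min_info: float = 0.4
    gws_p: float = GWS_P
    clump_r2: float = 0.6
    contribution_min: float = 0.20
    cs_level: float = 0.99
    mpp_high: float = 0.90
    kappa: float = DEFAULT_KAPPA
    prior_var: float = 0.04**2
    snp_prior: float = 0.0  # 0 = 1/p per region
    growth_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_info", "gws_p", "clump_r2",
                     "contribution_min", "cs_level", "mpp_high", "growth_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name}={v} must lie in (0, 1)")
        if self.kappa < 1:
            raise ConfigError("kappa must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _substreams(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write artifacts; returns the output directory.

    Stages: read + harmonise trait sumstats, fit or load the loading matrix,
    derive latent-factor sumstats, detect GWS factors, fine-map each factor,
    adjust jointly with flashfmZero, and write summary tables plus a
    structured JSON log of every filter count.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    streams = _substreams(config.seed, 4)

    stage = "harmonise"
    try:
        paths = sorted(globlib.glob(config.sumstats_glob))
        if not paths:
            raise DataError(f"no sumstats match {config.sumstats_glob!r}")
        tables = [lfio.read_sumstats(p, trait=Path(p).stem) for p in paths]
        n_before = len(tables[0].table)
        panel = harmonise(tables, min_maf=config.min_maf, min_info=config.min_info)
        log["stages"][stage] = {
            "traits": len(tables),
            "variants_before": n_before,
            "variants_after": len(panel.variant_ids),
            **panel.filter_log,
        }
    except Exception as exc:  # noqa: BLE001 - stage provenance
        raise PipelineError(stage, str(exc)) from exc

    stage = "factor_model"
    try:
        trait_cov = pd.read_csv(config.trait_cov_path, sep="\t", index_col=0)
        trait_cov = trait_cov.loc[panel.trait_names, panel.trait_names]
        if config.loadings_path:
            L = lfio.read_loadings(config.loadings_path)
        else:
            n_obs = config.n_obs
            if n_obs <= 0:
                n_obs = int(panel.variants["N"].median())
            d = np.sqrt(np.diag(trait_cov.to_numpy()))
            corr = trait_cov.to_numpy() / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
            model = FactorModel(pd.DataFrame(corr, index=trait_cov.index,
                                             columns=trait_cov.columns), n_obs)
            k = config.n_factors or None
            results = model.fit(n_factors=k, seed=streams[0])
            L = results.loading_matrix
        lfio.write_loadings(L, out / "loadings.tsv")
        log["stages"][stage] = {"n_factors": len(L.factor_names)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    stage = "latent_gwas"
    try:
        d = np.sqrt(np.diag(trait_cov.to_numpy()))
        corr = trait_cov.to_numpy() / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        latent = latent_sumstats_from_traits(panel, L, corr)
        for ss in latent.factors:
            lfio.write_sumstats(ss, out / f"latent_{ss.trait}.tsv")
        log["stages"][stage] = {
            "factors": latent.factor_names,
            "clipped_variants": latent.clipped_variants,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    stage = "ld"
    try:
        if config.ld_path:
            ld = lfio.read_ld(config.ld_path)
            ld_log = {"source": "matrix_file"}
        elif config.dosage_path:
            G = read_genotypes(config.dosage_path, config.dosage_variants_path)
            ld, excluded = best_guess_ld(G)
            ld_log = {"source": "best_guess_dosages", "excluded_variants": len(excluded)}
        else:
            raise DataError("provide ld_path or dosage_path")
        common = [v for v in panel.variant_ids if v in set(ld.index)]
        if not common:
            raise DataError("no overlap between harmonised variants and LD")
        ld = ld.loc[common, common]
        log["stages"][stage] = {**ld_log, "variants_with_ld": len(common)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    stage = "finemap"
    try:
        gws_factors = []
        for ss in latent.factors:
            sub = ss.subset(common)
            if (sub.table["P"] < config.gws_p).any():
                gws_factors.append(sub)
        log["stages"][stage] = {
            "factors_with_gws_signal": [s.trait for s in gws_factors]
        }
        if len(gws_factors) < 2:
            log["stages"][stage]["note"] = (
                "fewer than 2 factors genome-wide significant; joint step skipped"
            )
            (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
            return out
        n = int(panel.variants["N"].median())
        regions = [
            RegionData(sub, ld.to_numpy(), n=n) for sub in gws_factors
        ]
        joint = flashfm_zero_with_finemap(
            regions,
            kappa=config.kappa,
            snp_prior=config.snp_prior or None,
            prior_var=config.prior_var,
            growth_threshold=config.growth_threshold,
            cs_level=config.cs_level,
        )
        summary = joint.summary_table()
        summary.to_csv(out / "fm_summary.tsv", sep="\t", index=False)
        for name, mp, cs in zip(
            joint.factor_names, joint.adjusted.posteriors, joint.credible_sets()
        ):
            mp.mpp_series().rename("MPP").to_csv(out / f"mpp_{name}.tsv", sep="\t")
            pd.DataFrame({"SNPID": cs.variant_ids, "cum_mpp": cs.cumulative_mpp}).to_csv(
                out / f"cs99_{name}.tsv", sep="\t", index=False
            )
        log["stages"][stage]["summary_rows"] = len(summary)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
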