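"""Plain-TSV readers and writers for summary statistics, LD, and loadings.

Summary-statistics dialect: tab-separated, one header line, columns
``SNPID CHR BP EA OA EAF BETA SE P INFO N``.  The reader tolerates extra
columns and common header aliases (CHROM, POS, ...); the writer emits the
canonical column order.  Malformed rows (non-numeric beta/se, SE <= 0) are
rejected with their line numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gwas import SUMSTATS_COLUMNS, SumStats

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "read_loadings",
    "write_loadings",
]

HEADER_ALIASES = {
    "CHROM": "CHR",
    "CHROMOSOME": "CHR",
    "POS": "BP",
    "POSITION": "BP",
    "ID": "SNPID",
    "SNP": "SNPID",
    "RSID": "SNPID",
    "EFFECT_ALLELE": "EA",
    "OTHER_ALLELE": "OA",
    "ALLELE1": "EA",
    "ALLELE0": "OA",
    "A1": "EA",
    "A2": "OA",
    "FREQ": "EAF",
    "A1FREQ": "EAF",
    "EFFECT": "BETA",
    "B": "BETA",
    "STDERR": "SE",
    "PVAL": "P",
    "P_VALUE": "P",
    "PVALUE": "P",
    "INFO_SCORE": "INFO",
    "NSAMPLES": "N",
}

_NUMERIC = ["BP", "EAF", "BETA", "SE", "P", "INFO", "N"]


class MalformedRowError(ValueError):
    pass


def read_sumstats(path, trait: str | None = None, strict: bool = True) -> SumStats:
    """Read a summary-statistics TSV; see module docstring for the dialect.

    With ``strict=True`` malformed rows raise :class:`MalformedRowError`
    listing 1-based data line numbers; otherwise they are dropped and logged
    in ``table.attrs['rejected_lines']``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [HEADER_ALIASES.get(c.strip().upper(), c.strip().upper()) for c in df.columns]
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[SUMSTATS_COLUMNS].copy()
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        df[_NUMERIC].isna().any(axis=1)
        | (df["SE"] <= 0)
        | (df["P"] <= 0)
        | (df["P"] > 1)
    )
    if bad.any():
        lines = [int(i) + 2 for i in np.where(bad)[0]]  # +2: header + 1-basing
        if strict:
            raise MalformedRowError(f"{path}: malformed rows at lines {lines[:20]}")
        df = df[~bad]
    df["BP"] = df["BP"].astype(int)
    df["N"] = df["N"].astype(int)
    df["CHR"] = df["CHR"].astype(str)
    df = df.reset_index(drop=True)
    df.attrs["rejected_lines"] = [] if not bad.any() else lines
    if trait is None:
        trait = str(path)
    return SumStats(df, trait)


def write_sumstats(ss: SumStats, path) -> None:
    ss.table[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ld(path) -> pd.DataFrame:
    """Read a square whitespace-delimited LD matrix with a variant-id header."""
    mat = pd.read_csv(path, sep=r"\s+")
    mat.index = list(mat.columns)
    arr = mat.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("LD matrix must be square")
    return mat


def write_ld(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", index=False)


def read_loadings(path):
    """Read a loadings TSV (trait rows, factor columns) into a LoadingMatrix."""
    from .factor import LoadingMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if "uniqueness" in df.columns:
        uniq = df.pop("uniqueness")
    else:
        uniq = pd.Series(1.0 - (df**2).sum(axis=1), index=df.index)
    return LoadingMatrix(loadings=df, uniquenesses=uniq)


def write_loadings(L, path) -> None:
    df = L.loadings.copy()
    df["uniqueness"] = L.uniquenesses
    df.index.name = "trait"
    df.to_csv(path, sep="\t")


def write_scree(observed, simulated_mean, path) -> None:
    """Scree-plot source data: observed vs. mean simulated eigenvalues."""
    pd.DataFrame(
        {
            "rank": np.arange(1, len(observed) + 1),
            "observed": observed,
            "simulated_mean": simulated_mean,
        }
    ).to_csv(path, sep="\t", index=False)
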