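"""Signal bookkeeping: LD clumping, region construction, conditional stats.

Conventions: genome-wide significance p < 5e-8, suggestive band up to 1e-6,
LD clumping at r^2 > 0.6, fine-mapping regions built by flanking
distance-clumped lead variants by +/-250 kb and merging overlaps.  All
coordinates are 1-based inclusive except inside the BED writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gwas import SumStats

__all__ = [
    "Clump",
    "Region",
    "ld_clump",
    "build_regions",
    "conditional_sumstats",
    "clump_trait_crosstab",
    "cochran_armitage_trend",
]

GWS_P = 5e-8
SUGGESTIVE_P = 1e-6
CLUMP_R2 = 0.6
REGION_FLANK = 250_000
CONTRIBUTION_GWAS_MIN = 0.01  # factor-trait linkage for GWAS lookups
CONTRIBUTION_FINEMAP_MIN = 0.20  # factor-trait linkage for fine-mapping


@dataclass
class Clump:
    lead: str
    members: list[str]
    lead_p: float
    traits: list[str] = field(default_factory=list)


@dataclass
class Region:
    chr: str
    start: int  # 1-based inclusive
    end: int
    leads: list[tuple[str, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.chr == other.chr and self.start <= other.end and other.start <= self.end


def ld_clump(
    ss: SumStats,
    ld: pd.DataFrame,
    p_thresh: float = GWS_P,
    r2: float = CLUMP_R2,
) -> list[Clump]:
    """Greedy min-p LD clumping of significant variants.

    Repeatedly takes the smallest-p unassigned significant variant as lead
    and absorbs all unassigned significant variants with r^2 > ``r2`` against
    it (single round per lead, no transitive closure).
    """
    tab = ss.table
    sig = tab[tab["P"] < p_thresh].sort_values(["P", "BP"])
    if sig.empty:
        return []
    missing = set(sig["SNPID"]) - set(ld.index)
    if missing:
        raise ValueError(f"LD matrix missing significant variants: {sorted(missing)[:5]}")
    r2mat = ld**2
    unassigned = list(sig["SNPID"])
    pvals = dict(zip(sig["SNPID"], sig["P"]))
    clumps = []
    while unassigned:
        lead = unassigned[0]
        r2_lead = r2mat.loc[lead]
        members = [v for v in unassigned if r2_lead[v] > r2 or v == lead]
        clumps.append(Clump(lead=lead, members=members, lead_p=pvals[lead]))
        unassigned = [v for v in unassigned if v not in set(members)]
    return clumps


def distance_clump_leads(
    leads: list[tuple[str, int, float]], min_separation: int = REGION_FLANK
) -> list[tuple[str, int]]:
    """Thin leads so no two on a chromosome are closer than min_separation.

    Smaller-p leads win: accepted in ascending p order, a candidate is
    dropped if an accepted lead on the same chromosome is within the window.
    """
    accepted: list[tuple[str, int]] = []
    for chrom, bp, _ in sorted(leads, key=lambda x: (x[2], x[0], x[1])):
        if all(c != chrom or abs(bp - b) >= min_separation for c, b in accepted):
            accepted.append((chrom, int(bp)))
    return accepted


def build_regions(
    leads,
    min_separation: int = REGION_FLANK,
    flank: int = REGION_FLANK,
    extra_regions: list[Region] | None = None,
) -> list[Region]:
    """Flank distance-clumped leads by +/-flank and merge overlapping spans.

    ``leads`` are (chr, bp) or (chr, bp, p) tuples; without p, position order
    is used for distance clumping.  ``extra_regions`` (e.g. externally
    defined fine-mapping regions) are unioned in before merging.
    """
    triples = [
        (str(c), int(b), float(rest[0]) if rest else 0.0)
        for c, b, *rest in leads
    ]
    thinned = distance_clump_leads(triples, min_separation)
    spans = [
        Region(chrom, max(1, bp - flank), bp + flank, leads=[(f"{chrom}:{bp}", bp)])
        for chrom, bp in thinned
    ]
    spans.extend(extra_regions or [])

    merged: list[Region] = []
    for reg in sorted(spans, key=lambda r: (r.chr, r.start, r.end)):
        if merged and merged[-1].overlaps(reg):
            last = merged[-1]
            last.end = max(last.end, reg.end)
            last.leads.extend(reg.leads)
        else:
            merged.append(Region(reg.chr, reg.start, reg.end, list(reg.leads)))
    return merged


def conditional_sumstats(
    ss: SumStats,
    ld: pd.DataFrame,
    condition_ids: list[str],
    ridge: float = 1e-6,
) -> SumStats:
    """Summary-statistic conditional analysis on a set of lead variants.

    On the z scale, z_cond = (z_t - R_tC R_CC^-1 z_C) / sqrt(1 - R_tC R_CC^-1
    R_Ct); betas and SEs are rescaled accordingly so that the conditional
    beta approximates the joint-regression coefficient of the target given
    the conditioning set.  Conditioned variants are reported with beta 0.
    An empty conditioning set returns the input unchanged.
    """
    tab = ss.table.copy()
    if not condition_ids:
        return SumStats(tab, ss.trait)
    missing = set(condition_ids) - set(ld.index)
    if missing:
        raise ValueError(f"conditioning variants absent from LD: {sorted(missing)}")
    ids = list(tab["SNPID"])
    R = ld.loc[ids, ids].to_numpy()
    pos = {v: i for i, v in enumerate(ids)}
    cidx = np.array([pos[v] for v in condition_ids])
    z = tab["BETA"].to_numpy() / tab["SE"].to_numpy()
    Rcc = R[np.ix_(cidx, cidx)]
    try:
        Rcc_inv = np.linalg.inv(Rcc)
    except np.linalg.LinAlgError:
        Rcc_inv = np.linalg.inv(Rcc + ridge * np.eye(len(cidx)))
    Rtc = R[:, cidx]  # all x C
    A = Rtc @ Rcc_inv
    z_adj = z - A @ z[cidx]
    denom2 = np.clip(1.0 - np.einsum("ij,ij->i", A, Rtc), 1e-12, None)
    denom = np.sqrt(denom2)
    se = tab["SE"].to_numpy()
    beta_cond = se * z_adj / denom2
    se_cond = se / denom
    z_cond = z_adj / denom
    cond_mask = np.zeros(len(ids), dtype=bool)
    cond_mask[cidx] = True
    beta_cond[cond_mask] = 0.0
    z_cond[cond_mask] = 0.0
    se_cond[cond_mask] = se[cond_mask]
    from scipy.special import ndtr

    tab["BETA"] = beta_cond
    tab["SE"] = se_cond
    tab["P"] = np.clip(2 * ndtr(-np.abs(z_cond)), np.nextafter(0, 1), 1.0)
    return SumStats(tab, ss.trait)


def cochran_armitage_trend(table: np.ndarray, scores=None) -> tuple[float, float]:
    """Cochran-Armitage trend chi-square for a 2 x k table.

    Rows are the two outcome groups, columns ordered categories.  Returns
    (statistic, two-sided p).  Degenerate tables (zero variance) give
    statistic 0, p 1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("need a 2 x k table with k >= 2")
    k = table.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, float)
    a = table[0]  # "successes"
    n = table.sum(axis=0)
    N = n.sum()
    A = a.sum()
    if N == 0 or A == 0 or A == N:
        return 0.0, 1.0
    pbar = A / N
    U = float(s @ a - pbar * (s @ n))
    sxx = float(s**2 @ n - (s @ n) ** 2 / N)
    if sxx <= 0:
        return 0.0, 1.0
    stat = U**2 / (pbar * (1 - pbar) * sxx)
    return stat, float(chi2.sf(stat, 1))


def clump_trait_crosstab(
    clumps_by_trait: dict[str, list[Clump]],
    latent_clumps: list[Clump],
) -> tuple[pd.DataFrame, float, float]:
    """Cross-tabulate trait clumps by trait count and latent-factor sharing.

    Each clump of GWS variants for the observed traits is annotated with the
    number of distinct traits significant in it and whether any member
    variant is GWS for a latent factor (member of a latent clump).  Returns
    the stacked-bar source table (columns: n_traits, shared, not_shared) plus
    the Cochran-Armitage trend statistic and p over the 2 x k table; with
    fewer than 2 trait-count categories the test is reported as NaN.
    """
    latent_members = set()
    for cl in latent_clumps:
        latent_members.update(cl.members)

    # collapse clumps sharing variants across traits into distinct signals
    all_clumps: list[tuple[set[str], set[str]]] = []  # (members, traits)
    for trait, clumps in clumps_by_trait.items():
        for cl in clumps:
            members = set(cl.members)
            traits = set(cl.traits) if cl.traits else {trait}
            for existing_members, existing_traits in all_clumps:
                if members & existing_members:
                    existing_members |= members
                    existing_traits |= traits
                    break
            else:
                all_clumps.append((members, traits))

    records = [
        {"n_traits": len(traits), "shared": bool(members & latent_members)}
        for members, traits in all_clumps
    ]
    if not records:
        return pd.DataFrame(columns=["n_traits", "shared", "not_shared"]), np.nan, np.nan
    df = pd.DataFrame(records)
    counts = (
        df.groupby("n_traits")["shared"]
        .agg(shared="sum", total="count")
        .reset_index()
    )
    counts["not_shared"] = counts["total"] - counts["shared"]
    out = counts[["n_traits", "shared", "not_shared"]]
    if len(out) < 2:
        return out, np.nan, np.nan
    stat, pval = cochran_armitage_trend(out[["shared", "not_shared"]].to_numpy().T)
    return out, stat, pval


def regions_to_bed(regions: list[Region], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chr}\t{r.start - 1}\t{r.end}\n")
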